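# Methods

This note documents the models, estimators and numerical choices behind
`chromosteer`, the assumptions they rest on, and what the synthetic-data
conditions used by the test suite do and do not demonstrate.

## Contact calling

### Background model

Cis contact counts at fixed genomic distance δ (in 100 kb bins) are
treated as i.i.d. draws from a zero-inflated negative binomial
ZiNB(π, θ, μ): a point mass at zero with probability π on top of a
negative binomial with dispersion θ and mean μ. The NB is parametrized
internally by (θ, μ) for numerical stability; the alternative "probability
of not having a 3D contact" p = θ/(θ+μ) is reported alongside. Structural
zeros between unmasked bins are data, not missing values, and enter both
the fit and the multiple-testing family.

Per-distance fitting assumes enough observations per δ; distances are
pooled outward into geometrically growing groups until a group holds at
least 50 observations with at least 10 nonzero (status `pooled`). Groups
that still end up with fewer than 3 nonzero counts are flagged
`degenerate` and excluded from testing.

### Robustness choices

Two estimation steps must not be contaminated by the very signal the test
is designed to find, which matters at desk scale where enriched pairs can
be several percent of all pairs:

* **Tail-censored MLE.** The top 15% of nonzero observations in a group
  enter the likelihood only through their exceedance probability
  P(X ≥ c) at the censoring point c (the largest retained value). This
  caps the leverage of any single large count: a fold-50 enriched pair
  contributes no more than "at least as large as the background maximum",
  which is true of it. On enrichment-free data censored MLE is a
  consistent estimator and agrees with the plain MLE. The 15% level is a
  breakdown-point choice: roughly twice the enrichment density of the
  synthetic study conditions (200 planted pairs among ~4,950, i.e. ~6.5%
  of nonzero counts); false-discovery control was verified to be
  insensitive to this level across 5–20%.

* **Signal- and noise-robust bias estimation.** The pure equal-marginal
  iterative correction (`ice_normalize`) is exposed and satisfies the
  equal-marginal contract (coefficient of variation of corrected
  marginals < 1e-4 at convergence; note that matrices whose zero pattern
  lacks total support — e.g. a bin touching only one other — admit no
  exactly balanced scaling and trigger a `ConvergenceWarning`). The
  calling pipeline, however, estimates biases with (i) hotspot-trimmed
  marginals, each row's top 5% of entries held out so enriched contacts
  do not masquerade as high-visibility bins, and (ii) shrinkage of the
  log-biases toward zero by λ = max(0, 1 − v_noise/v_total), where the
  noise floor v_noise is measured by re-balancing surrogate matrices
  whose entries are permuted within each diagonal (preserving the per-δ
  distributions, destroying genuine row structure). On a small unbiased
  matrix λ collapses to ~0 and the correction is a no-op — which is
  exactly right, since at a few hundred bins the marginal of a row is too
  noisy to estimate a per-bin bias; genuine strong biases survive the
  shrinkage.

### Testing

The upper-tail p-value of an entry x is P(X ≥ x) = 1 − CDF(x − 1) under
the group's fitted ZiNB (exactly 1 at x = 0). Bias-corrected counts are
real-valued; they are rounded to the nearest integer before fitting and
testing so the discrete model's support is preserved. Benjamini–Hochberg
step-up at α = 0.01 is applied separately within each distance group (the
correction assumes entries at fixed δ are exchangeable and approximately
independent); q-values are the BH-adjusted p-values, ties broken by
p-value rank then (i, j) order. Adjacent bins (δ = 1) are tested;
self-interactions never are.

## Synthetic data

The generator emulates the statistical structure the caller assumes:
sparse cis matrices whose background at distance δ is
ZiNB(π, θ, μ_δ) with a power-law mean decay μ_δ = c·δ^(−1). Defaults —
c = 100 corrected reads at 100 kb separation, θ = 2, π = 0.4 — were
chosen once as representative of bias-corrected cis Hi-C counts at this
resolution: strongly over-dispersed, zero-rich, with a contact
probability falling roughly inversely with distance. Planted enriched
pairs are drawn from the same family with the mean multiplied by the fold
enrichment (default 50) and zero-inflation suppressed, at separations
from 200 kb up to half the chromosome, mimicking a mixture of local and
non-local target contacts.

What the generator does **not** model: trans contacts,
restriction-fragment-level biases, distance-dependent changes in π and θ,
correlated enrichment (TAD-like blocks rather than isolated peaks), and
per-bin visibility biases (tests of bias *recovery* construct those
explicitly). Passing the FDR/power tests therefore shows the estimator
chain is correct and robust under the assumed sampling model, not that
real Hi-C maps satisfy that model.

Annotation tracks are laid block-wise with a configurable gene-density
gradient; LADs, H3K9me3 and positive Giemsa bands occupy gene-poor
blocks, H3K4me3 and negative bands gene-rich ones; radial placement
targets put LAD-heavy chromosomes peripheral. These tracks exist to make
the radial-enrichment analyses testable, not to mimic any genome.

## Polymer model

Kremer–Grest chains in reduced Lennard-Jones units (σ = 30 nm,
ε = k_BT, m = 1, τ_LJ = σ√(m/ε)):

| term | form | default | why |
|---|---|---|---|
| bond | FENE | K = 30 ε/σ², R₀ = 1.5 σ | canonical non-crossing bead-spring choice |
| excluded volume | WCA | ε = 1, cutoff 2^(1/6) σ | purely repulsive |
| bending | κ(1 − cos θ) | κ = 5 ε | targets l_p ≈ 5 σ = 150 nm |
| centromere | cut-shifted LJ | depth 1 ε, cutoff 1.5 σ, same chain only | compacts centromeres during relaxation |
| wall | harmonic, force-capped | k = 100 ε/σ², cap 20 ε/σ | impenetrable nucleus, stable for deep protrusions |
| integrator | BAOAB Langevin | γ = 0.5 τ⁻¹, Δt = 0.012 τ | reduces to velocity Verlet at γ = 0 |

The discrete Kratky–Porod relation l_p/σ = −1/ln(coth κ − 1/κ) gives
≈ 4.5 σ at κ = 5; excluded volume swells this slightly, and the measured
effective persistence length of a free 1,000-bead chain is ≈ 135–140 nm,
within the 150 nm ± 15% target band.

Numerical guards: per-step displacement above σ, FENE extension reaching
R₀, and neighbour-list overflow abort the run with a typed error. Forces
with a distance cap (wall, restraints) switch from harmonic to constant
beyond the cap with a continuous energy, so they remain exact negative
gradients. The kinetic temperature carries the usual O((ω Δt)²) BAOAB
artifact (~2.5% at Δt = 0.012 on the stiff bonds); configurational
sampling is unaffected, and thermostat correctness is verified at
Δt = 0.006.

## Initial conformations and placement

Rosette rods are built from hairpin petals radiating around the rod axis
(n_loop beads per petal, default 101; 12 petals per turn; 2 σ rise per
turn); the inner radius is solved so that *every* consecutive-bead
distance is exactly σ, including petal junctions. Placement inserts rods
longest-first with steric-clash rejection; the phenomenological mode
confines midpoints to the equal-volume radial shell (of six) containing
each chromosome's target and keeps the best of N trials by summed
absolute radial residual. Equal-volume shells were chosen over
equal-thickness so a uniform prior puts equal mass in each shell.
Protrusions are driven inside by a brief compressive Langevin run using a
softened, capped wall and raised friction — deep protrusions fold in
gently instead of catapulting.

For desk-scale steering experiments a fully relaxed (decondensed) start
is needed, but relaxing a rod-like start takes Rouse times far beyond toy
budgets; `grow_random_coil` therefore grows a persistent self-avoiding
walk with the target stiffness directly inside the nucleus. The
production path (rosette → compression → relaxation) remains the
default pipeline; the grown coil is an initialization for toy systems and
tests.

## Steering and recondensation

One restraint per significant contact per homolog copy (cis only, never
cross-homolog) between the COMs of the two 33-bead regions. The initial
spring constant k_init = 3 k_BT/(2 l_p L), the entropic spring constant
of a worm-like segment of contour length L = s σ, "just counteracts the
entropic recoil" of the intervening chain; separations below 66 beads are
clamped. Constants ramp linearly to k_max = 0.1 k_BT/nm² (strong enough
that k d²/2 ≫ k_BT at the 480 nm criterion distance) with the restraint
force capped at 10 ε/σ (constant-force pulling at large distance), the
steering equilibrium distance is 0, and satisfaction is judged by the
analysis cutoffs rather than by the spring target.

Recondensation drops all steering restraints, couples single-bead anchors
at every 66 beads along each chain (the final bead joins as the last
anchor when not already one, so a 66-bead chain has exactly one pair),
with equal constant springs (1 k_BT/nm², force-capped) and an equilibrium
distance stepping 200, 170, 140, 110, 80, 50, 30 nm every 0.6 τ_LJ — the
last step is 20 nm so the schedule lands exactly on the bead size — then
holds at 30 nm to the total duration.

Durations: production values (1,200 τ compression, 120,000 τ relaxation,
6,000 τ steering, 600 τ additional steering, 300 τ recondensation) are
the configuration defaults; library calls take the duration as an
argument, and the toy systems in the test-suite use hundreds of τ, which
the satisfaction curves show is ample at those system sizes.

## Structural analyses

* Satisfaction: COM distance and closest-bead distance per restraint at
  120/240/480 nm; closest-bead ≥ COM at equal cutoff by construction.
* Distance matrices: beads averaged per 100 kb bin, then Euclidean
  distances; Kendall τ-b (tie-corrected) against Hi-C counts over
  upper-triangle entries above a sweep of separation floors (exact
  p-value enumeration only for small tie-free samples).
* Radial profiles: 15 equal-thickness shells over [0, R_nuc]; per shell,
  the percentage of its beads carrying each feature, aggregated over
  replicates; per-bead radial mean and standard deviation across
  replicates. Empty shells are flagged, not imputed.
* Macrodomains: the dissimilarity is the replicate-mean distance where
  below 750 nm and 1,000 nm otherwise (the asymmetric gap is deliberate
  and kept literal); sequence-contiguous K-medoids is solved *exactly* by
  dynamic programming over block boundaries (contiguity makes the global
  optimum tractable), ties broken toward the earliest boundary. Overlap q
  between two partitions is the fraction of segments whose sequentially
  numbered domain labels agree (centromeric segments excludable); its
  significance compares q against random sequence-continuous subdivisions
  drawn uniformly over boundary placements (stars-and-bars), with the
  add-one permutation p-value, which is super-uniform under the null.
* Procrustes RMSD: Kabsch superimposition with proper rotations only
  (reflections excluded); optional uniform scaling.
* MDS reconstruction: distances x^(−α) (α = 1 by default), completed to a
  metric by Floyd–Warshall shortest paths, then classical MDS from the
  top three eigenvectors of the double-centred squared-distance matrix.
  Disconnected contact graphs are an error, not silently embedded.

## Known limitations

* The nucleus is a sphere; flattened ellipsoidal geometries are out of
  scope.
* Contact calling treats entries at fixed δ as independent; correlated
  enrichment would make BH anti-conservative in a way the synthetic
  conditions do not probe.
* The bias-shrinkage estimator deliberately under-corrects when bias
  variance is comparable to marginal noise; at genome scale (tens of
  thousands of bins) λ → 1 and it coincides with ICE.
* Desk-scale dynamics establish compliance and ordering properties
  (satisfaction rises, compliance similar across starting states,
  segregation preserved), not production-scale ensemble averages.
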