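"""Build the bead system: discretization, rosette rods, nuclear placement.

Chromosomes are discretized into 3,030 bp (30 nm) beads, prepared as
rod-like stacks of rosette petals, placed inside the spherical nucleus
(randomly or matching phenomenological radial targets), and finally driven
fully inside the nuclear boundary by a brief compressive Langevin run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .engine import ForceFieldParams, Simulation
from .errors import FormatError, PlacementError, RangeError
from .genome import GenomeSpec
from .system import BEAD_BP, BeadSystem, Chain

__all__ = [
    "GenomeDiscretization", "discretize_genome", "build_rosette",
    "build_system", "place_chromosomes", "compress_protrusions",
]


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class GenomeDiscretization:
    """Bead counts and genomic <-> bead maps for one genome spec."""

    spec: GenomeSpec
    bead_bp: int = BEAD_BP
    n_beads: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.n_beads = {c.name: -(-c.length_bp // self.bead_bp)
                        for c in self.spec.chromosomes}

    def beads_per_bin(self, resolution: int) -> int:
        """Beads spanned by one matrix bin (33 for 100 kb at 3,030 bp)."""
        return resolution // self.bead_bp

    def bin_to_beads(self, chrom: str, bin_index: int,
                     resolution: int) -> tuple[int, int]:
        """Half-open chain-local bead range covered by a matrix bin."""
        n = self.n_beads[chrom]
        span = self.beads_per_bin(resolution)
        start = int(round(bin_index * resolution / self.bead_bp))
        if start >= n or bin_index < 0:
            raise RangeError(f"bin {bin_index} outside {chrom}")
        return start, min(start + span, n)

    def centromere_beads(self, chrom: str) -> tuple[int, int]:
        c = self.spec.chromosome(chrom)
        b0 = c.centromere[0] // self.bead_bp
        b1 = -(-c.centromere[1] // self.bead_bp)
        return b0, min(b1, self.n_beads[chrom])

    def track_flags(self, chrom: str, track: str,
                    min_overlap: float = 0.5) -> np.ndarray:
        """Per-bead boolean flags: a bead carries a feature when intervals
        of the track cover at least ``min_overlap`` of the bead."""
        n = self.n_beads[chrom]
        cover = np.zeros(n + 1)
        for iv in self.spec.tracks.get(track, []):
            if iv.chrom != chrom:
                continue
            # accumulate bp coverage per bead via a difference trick on
            # fractional bead coordinates
            b0 = iv.start / self.bead_bp
            b1 = iv.end / self.bead_bp
            lo, hi = int(b0), min(int(math.ceil(b1)), n)
            for b in range(lo, hi):
                ov = min(b + 1, b1) - max(b, b0)
                if ov > 0:
                    cover[b] += ov
        return cover[:n] >= min_overlap


def discretize_genome(spec: GenomeSpec, bead_bp: int = BEAD_BP) -> GenomeDiscretization:
    return GenomeDiscretization(spec, bead_bp)


# ---------------------------------------------------------------------------
# rosette initial conformation
# ---------------------------------------------------------------------------

def _petal_geometry(n_loop: int, petals_per_turn: int, pitch_per_turn: float):
    """Solve the rosette geometry so every bond is exactly one bead long.

    Returns (m, w, a, dz, r0): out-row length, row offset, turn-bead axial
    offset, per-petal rise and inner radius, all in bead-diameter units.
    """
    m = max(1, (n_loop - 1) // 2)
    w = 1.0
    a = math.sqrt(1.0 - 0.25 * w * w)
    dz = pitch_per_turn / petals_per_turn
    psi = 2.0 * math.pi / petals_per_turn
    u0 = np.array([1.0, 0.0])
    u1 = np.array([math.cos(psi), math.sin(psi)])
    v0 = np.array([0.0, 1.0])
    v1 = np.array([-math.sin(psi), math.cos(psi)])

    def gap(r0):
        # horizontal distance between petal-k exit and petal-(k+1) entry
        e = r0 * u0 + 0.5 * w * v0
        b = r0 * u1 - 0.5 * w * v1
        h2 = float(np.sum((e - b) ** 2))
        return math.sqrt(h2 + dz * dz) - 1.0

    if dz >= 1.0:
        raise FormatError("rosette pitch per petal must be < 1 bead")
    lo = 0.0
    hi = 2.0 / psi
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise FormatError("rosette geometry does not close")
    r0 = brentq(gap, lo, hi, xtol=1e-12)
    return m, w, a, dz, r0


def build_rosette(n_beads: int, n_loop: int = 101, petals_per_turn: int = 12,
                  pitch_per_turn: float = 2.0, sigma: float = 30.0,
                  seed: int | None = None) -> np.ndarray:
    """Rod-like initial conformation of stacked rosette petals.

    Each petal is a hairpin loop of ``n_loop`` beads (out-row, turn bead,
    back-row) radiating from the rod axis at azimuths stepping by
    ``2 pi / petals_per_turn``; each full turn of petals rises by
    ``pitch_per_turn`` bead diameters. Every consecutive-bead distance is
    exactly one bead diameter by construction. Returns (n_beads, 3) nm
    coordinates centred on the origin, rod axis along z.
    """
    if n_beads < 1:
        raise FormatError("n_beads must be >= 1")
    m, w, a, dz, r0 = _petal_geometry(n_loop, petals_per_turn, pitch_per_turn)
    coords = np.empty((n_beads, 3))
    petal = 0
    k = 0
    while k < n_beads:
        phi = 2.0 * math.pi * (petal % petals_per_turn) / petals_per_turn
        u = np.array([math.cos(phi), math.sin(phi), 0.0])
        v = np.array([-math.sin(phi), math.cos(phi), 0.0])
        z = np.array([0.0, 0.0, petal * dz])
        s = r0 * u + z
        # out-row
        for j in range(m):
            if k >= n_beads:
                break
            coords[k] = s + j * u - 0.5 * w * v
            k += 1
        # turn bead
        if k < n_beads:
            coords[k] = s + ((m - 1) + a) * u
            k += 1
        # back-row
        for j in range(m - 1, -1, -1):
            if k >= n_beads:
                break
            coords[k] = s + j * u + 0.5 * w * v
            k += 1
        petal += 1
    coords -= coords.mean(axis=0)
    return coords * sigma


def build_system(spec: GenomeSpec, disc: GenomeDiscretization | None = None,
                 n_loop: int = 101, petals_per_turn: int = 12,
                 pitch_per_turn: float = 2.0) -> BeadSystem:
    """Assemble the diploid bead system with rosette-rod chains at the
    origin (placement comes next). Centromere and annotation flags are set
    from the spec."""
    disc = disc or discretize_genome(spec)
    chains: list[Chain] = []
    offset = 0
    for rec in spec.chromosomes:
        n = disc.n_beads[rec.name]
        for copy in range(rec.copy_number):
            chains.append(Chain(rec.name, copy, offset, n))
            offset += n
    coords = np.zeros((offset, 3))
    cen = np.zeros(offset, dtype=bool)
    flags = {t: np.zeros(offset, dtype=bool) for t in spec.tracks}
    for c in chains:
        coords[c.slice] = build_rosette(
            c.n_beads, n_loop, petals_per_turn, pitch_per_turn)
        b0, b1 = disc.centromere_beads(c.name)
        cen[c.start + b0:c.start + b1] = True
        for t in spec.tracks:
            flags[t][c.slice] = disc.track_flags(c.name, t)
    return BeadSystem(chains, coords, cen, flags,
                      bead_bp=disc.bead_bp,
                      nucleus_radius=spec.nucleus_radius)


def grow_random_coil(n_beads: int, nucleus_radius: float, seed: int = 0,
                     sigma: float = 30.0, lp_beads: float = 5.0,
                     min_separation: float = 1.5,
                     start: np.ndarray | None = None,
                     avoid: np.ndarray | None = None) -> np.ndarray:
    """Grow a persistent self-avoiding walk inside the nuclear sphere.

    A desk-scale stand-in for a fully relaxed (decondensed) chain: the full
    relaxation of a rod-like start takes Rouse times far beyond toy-model
    budgets, while a directly grown coil with the target persistence length
    (``lp_beads`` bead diameters) is already decondensed. Steps keep every
    bead inside ``nucleus_radius`` and at least one diameter away from all
    earlier beads (and from ``avoid``, e.g. previously grown chains);
    ``min_separation`` (in bead diameters) sets the self-avoidance
    distance -- values above 1 produce swollen, well-spread coils.
    """
    rng = np.random.default_rng(seed)
    mu = math.exp(-1.0 / lp_beads)
    coords = np.empty((n_beads, 3))
    r_max = nucleus_radius - sigma
    if start is None:
        start = rng.standard_normal(3)
        start = start / np.linalg.norm(start) * 0.5 * r_max * rng.random()
    coords[0] = start
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    tree = None
    tree_size = 0
    avoid_tree = cKDTree(avoid) if avoid is not None and len(avoid) else None
    k = 1
    while k < n_beads:
        placed = False
        for _ in range(60):
            prop = mu * d + math.sqrt(1 - mu * mu) * rng.standard_normal(3)
            prop /= np.linalg.norm(prop)
            cand = coords[k - 1] + sigma * prop
            if np.linalg.norm(cand) > r_max:
                continue
            if tree is not None:
                dist, _ = tree.query(cand, k=1)
                if dist < min_separation * sigma:
                    continue
            # beads added since the last tree rebuild (excluding the
            # immediate predecessor, which sits at exactly one diameter)
            recent = coords[tree_size:k - 1]
            if len(recent) and np.min(
                    np.linalg.norm(recent - cand, axis=1)) < min_separation * sigma:
                continue
            if avoid_tree is not None:
                dist, _ = avoid_tree.query(cand, k=1)
                if dist < sigma:
                    continue
            coords[k] = cand
            d = prop
            placed = True
            break
        if not placed:
            # back up and try a different path
            k = max(1, k - 10)
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            tree_size = max(1, k - 2)
            tree = cKDTree(coords[:tree_size])
            continue
        k += 1
        if k % 50 == 0:
            tree_size = k - 2
            tree = cKDTree(coords[:tree_size])
    return coords


# ---------------------------------------------------------------------------
# nuclear placement
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _shell_edges(r_nuc: float, n_shells: int = 6) -> np.ndarray:
    """Equal-volume radial shell boundaries."""
    return r_nuc * (np.arange(n_shells + 1) / n_shells) ** (1.0 / 3.0)


def _sample_radius_in_shell(rng, r_lo: float, r_hi: float) -> float:
    u = rng.random()
    return (r_lo ** 3 + u * (r_hi ** 3 - r_lo ** 3)) ** (1.0 / 3.0)


def _try_place(rods, order, midpoints_radius, rng, sigma, r_nuc,
               max_redraws):
    """One placement attempt of all rods; returns coords list or None."""
    placed_pts = []
    tree = None
    out = [None] * len(rods)
    for idx in order:
        rod = rods[idx]
        for _ in range(max_redraws):
            rot = _random_rotation(rng)
            r = midpoints_radius(idx)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            centre = r * direction
            pts = rod @ rot.T + centre
            if tree is not None:
                d, _ = tree.query(pts, k=1,
                                  distance_upper_bound=sigma)
                if np.any(np.isfinite(d) & (d < sigma)):
                    continue
            out[idx] = pts
            placed_pts.append(pts)
            tree = cKDTree(np.concatenate(placed_pts))
            break
        else:
            return None
    return out


def place_chromosomes(system: BeadSystem, spec: GenomeSpec,
                      mode: str = "random", trials: int = 10_000,
                      seed: int = 0, max_redraws: int = 200):
    """Place rod-like chromosomes in the nucleus, longest first.

    ``random``: midpoints uniform in the nuclear volume, random axis
    orientation; any inter-rod bead pair closer than one bead diameter is a
    steric clash and the placement is redrawn. ``phenomenological``:
    midpoints are confined to the equal-volume radial shell (of six)
    containing each chromosome's target mean radial position; the best of
    ``trials`` clash-free placements minimizes the summed absolute deviation
    between achieved mean radial positions and the targets. Returns the
    achieved placement residual (nm, phenomenological) or 0.0 (random).
    """
    rng = np.random.default_rng(seed)
    sigma = system.bead_diameter
    r_nuc = system.nucleus_radius
    rods = [system.coords[c.slice] - system.coords[c.slice].mean(axis=0)
            for c in system.chains]
    order = sorted(range(len(rods)), key=lambda i: -rods[i].shape[0])

    if mode == "random":
        def mid_radius(idx):
            return r_nuc * rng.random() ** (1.0 / 3.0)
        for _ in range(max_redraws):
            placed = _try_place(rods, order, mid_radius, rng, sigma, r_nuc,
                                max_redraws)
            if placed is not None:
                for c, pts in zip(system.chains, placed):
                    system.coords[c.slice] = pts
                return 0.0
        raise PlacementError("could not place chromosomes without clashes; "
                             "lower the density or shorten the chains")

    if mode not in ("phenomenological", "pheno"):
        raise ValueError(f"unknown placement mode {mode!r}")

    edges = _shell_edges(r_nuc, 6)
    targets = [spec.radial_targets.get(c.name) for c in system.chains]
    if any(t is None for t in targets):
        raise FormatError("phenomenological placement needs a radial target "
                          "for every chromosome")
    shells = [max(0, min(5, int(np.searchsorted(edges, t, side="right")) - 1))
              for t in targets]

    best = None
    best_res = np.inf
    for _ in range(max(1, trials)):
        def mid_radius(idx):
            lo, hi = edges[shells[idx]], edges[shells[idx] + 1]
            return _sample_radius_in_shell(rng, lo, hi)
        placed = _try_place(rods, order, mid_radius, rng, sigma, r_nuc,
                            max_redraws)
        if placed is None:
            continue
        res = 0.0
        for pts, t in zip(placed, targets):
            res += abs(float(np.linalg.norm(pts, axis=1).mean()) - t)
        if res < best_res:
            best_res = res
            best = placed
    if best is None:
        raise PlacementError("no clash-free phenomenological placement found")
    for c, pts in zip(system.chains, best):
        system.coords[c.slice] = pts
    return float(best_res)


# ---------------------------------------------------------------------------
# protrusion compression
# ---------------------------------------------------------------------------

def compress_protrusions(system: BeadSystem,
                         params: ForceFieldParams | None = None,
                         duration_tau: float = 1200.0, seed: int = 0,
                         compress_force: float = 1.0) -> BeadSystem:
    """Drive any beads protruding beyond the nuclear sphere back inside.

    A brief Langevin run under an extra radial compressive force (reduced
    units, eps/sigma) acting on beads outside the boundary; stops as soon as
    every bead is strictly inside, extends once (with a warning) if the
    nominal duration does not suffice. No-op when already fully inside.
    """
    import dataclasses

    params = params or ForceFieldParams()
    if np.all(system.radial() < system.nucleus_radius):
        return system
    # deep protrusions are driven in gently: soft capped wall and strong
    # friction keep the folding rods overdamped and the bonds intact
    params = dataclasses.replace(params,
                                 wall_fmax=min(params.wall_fmax, 5.0),
                                 gamma=max(params.gamma, 2.0))
    sim = Simulation(system, params, seed=seed, confined=True,
                     compress_force=compress_force)
    chunk = max(duration_tau / 50.0, params.dt)
    for extension in range(2):
        t = 0.0
        while t < duration_tau - 1e-9:
            sim.run_tau(chunk)
            t += chunk
            if np.all(system.radial() < system.nucleus_radius):
                return system
        if extension == 0:
            warnings.warn("beads still outside the nucleus after the nominal "
                          "compression duration; extending the run")
    return system
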