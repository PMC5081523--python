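"""Post-simulation structural measurements.

Covers: target-satisfaction curves under the two contact criteria (COM
proximity, closest-bead proximity) at 120/240/480 nm; 100 kb coarse-grained
distance matrices and their Kendall association with Hi-C counts;
radial-shell enrichment of annotated beads (15 equal-thickness shells) and
per-bin radial variability across replicates; sequence-continuous K-medoids
macrodomain partitions with an overlap statistic and its random-subdivision
significance; Procrustes (rigid-body) RMSD; and classical MDS
reconstruction of chromosome coordinates from a Hi-C matrix completed to a
metric by the Floyd-Warshall algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import DegenerateDataError, FormatError, RangeError

DEFAULT_CUTOFFS = (120.0, 240.0, 480.0)  # nm


# ---------------------------------------------------------------------------
# satisfaction curves
# ---------------------------------------------------------------------------

def satisfaction_fractions(coords: np.ndarray, rset,
                           cutoffs=DEFAULT_CUTOFFS) -> dict:
    """Fraction of restraints satisfied in one conformation.

    Criteria: ``com`` (|COM_A - COM_B| <= cutoff) and ``closest`` (minimum
    bead-pair distance <= cutoff). Returns {(criterion, cutoff): fraction}.
    """
    out = {}
    n = len(rset.restraints)
    if n == 0:
        return {(c, co): np.nan for c in ("com", "closest") for co in cutoffs}
    com_d = np.empty(n)
    min_d = np.empty(n)
    for i, r in enumerate(rset.restraints):
        a = coords[r.beads_a[0]:r.beads_a[1]]
        b = coords[r.beads_b[0]:r.beads_b[1]]
        com_d[i] = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        min_d[i] = cdist(a, b).min()
    for co in cutoffs:
        out[("com", co)] = float(np.mean(com_d <= co))
        out[("closest", co)] = float(np.mean(min_d <= co))
    return out


def satisfaction_curve(trajectory, rset, cutoffs=DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Tidy satisfied-fraction table over a trajectory's snapshots."""
    rows = []
    for t, coords in zip(trajectory.times, trajectory.snapshots):
        fr = satisfaction_fractions(coords, rset, cutoffs)
        for (crit, co), val in fr.items():
            rows.append({"time": t, "criterion": crit,
                         "cutoff_nm": co, "fraction": val})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distance matrices and Kendall association with Hi-C
# ---------------------------------------------------------------------------

def bin_mean_positions(coords: np.ndarray, beads_per_bin: int) -> np.ndarray:
    """Average bead position of every ``beads_per_bin`` consecutive beads
    (the last bin may be shorter)."""
    n = coords.shape[0]
    n_bins = -(-n // beads_per_bin)
    out = np.empty((n_bins, 3))
    for b in range(n_bins):
        out[b] = coords[b * beads_per_bin:(b + 1) * beads_per_bin].mean(axis=0)
    return out


def distance_matrix(coords: np.ndarray, beads_per_bin: int = 33) -> np.ndarray:
    """Euclidean distance matrix between 100 kb bin mean positions."""
    return squareform(pdist(bin_mean_positions(coords, beads_per_bin)))


def kendall_vs_hic(distmat: np.ndarray, hic_dense: np.ndarray,
                   min_separations=None, min_pairs: int = 10) -> pd.DataFrame:
    """Kendall tau-b between distances and Hi-C counts vs separation floor.

    For each threshold (bins) the correlation runs over upper-triangle
    entries with |i - j| >= threshold. Expected sign is negative: closer in
    space means more reads. Thresholds with fewer than ``min_pairs`` pairs
    are flagged and get NaN.
    """
    n = distmat.shape[0]
    if hic_dense.shape != distmat.shape:
        raise FormatError("matrix shapes differ")
    if min_separations is None:
        min_separations = range(1, max(2, n // 2))
    iu, ju = np.triu_indices(n, k=1)
    sep = ju - iu
    rows = []
    for thr in min_separations:
        keep = sep >= thr
        d = distmat[iu[keep], ju[keep]]
        h = hic_dense[iu[keep], ju[keep]]
        if keep.sum() < min_pairs:
            rows.append({"min_separation": int(thr), "n_pairs": int(keep.sum()),
                         "tau": np.nan, "p_value": np.nan, "ok": False})
            continue
        method = "exact" if (keep.sum() < 30
                             and len(np.unique(d)) == keep.sum()
                             and len(np.unique(h)) == keep.sum()) else "asymptotic"
        res = stats.kendalltau(d, h, method=method)
        rows.append({"min_separation": int(thr), "n_pairs": int(keep.sum()),
                     "tau": float(res.statistic), "p_value": float(res.pvalue),
                     "ok": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# radial profiles
# ---------------------------------------------------------------------------

def radial_profiles(conformations: list[np.ndarray],
                    flags: dict[str, np.ndarray],
                    nucleus_radius: float, n_shells: int = 15):
    """Radial-shell feature enrichment aggregated over replicates.

    Shells are equal-thickness over [0, R_nuc] (~320 nm for 15 shells in a
    4,800 nm nucleus). For each shell and feature: the percentage of that
    shell's beads carrying the feature. Beads beyond R_nuc land in the
    outermost shell. Returns ``(profile, radial_stats)``: the per-shell
    table (NaN and flagged where a shell is empty) and the per-bead mean /
    standard deviation of radial position across replicates.
    """
    edges = np.linspace(0.0, nucleus_radius, n_shells + 1)
    radii = np.stack([np.linalg.norm(c, axis=1) for c in conformations])
    shell = np.clip(np.searchsorted(edges, radii, side="right") - 1,
                    0, n_shells - 1)
    rows = []
    for s in range(n_shells):
        in_shell = shell == s
        tot = int(in_shell.sum())
        row = {"shell": s, "r_lo_nm": edges[s], "r_hi_nm": edges[s + 1],
               "n_beads": tot, "is_empty": tot == 0}
        for name, fl in flags.items():
            if tot == 0:
                row[name] = np.nan
            else:
                row[name] = 100.0 * float(in_shell[:, fl].sum()) / tot
        rows.append(row)
    stats_df = pd.DataFrame({
        "bead": np.arange(radii.shape[1]),
        "radial_mean_nm": radii.mean(axis=0),
        "radial_std_nm": radii.std(axis=0),
    })
    return pd.DataFrame(rows), stats_df


# ---------------------------------------------------------------------------
# macrodomain partitioning
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    """Sequence-continuous domain assignment of one arm's segments."""

    arm: str
    boundaries: list[int]  # domain start indices; boundaries[0] == 0
    n_segments: int

    @property
    def n_domains(self) -> int:
        return len(self.boundaries)

    def labels(self) -> np.ndarray:
        lab = np.zeros(self.n_segments, dtype=np.int64)
        for d, b in enumerate(self.boundaries):
            lab[b:] = d
        return lab


def dissimilarity_from_distances(mean_dist: np.ndarray, d_cap: float = 750.0,
                                 d_fill: float = 1000.0) -> np.ndarray:
    """Dissimilarity rule: the mean distance where below 750 nm, otherwise
    the 1,000 nm fill value (the gap between the two is intentional)."""
    return np.where(mean_dist < d_cap, mean_dist, d_fill)


def _block_costs(delta: np.ndarray) -> np.ndarray:
    """cost[i, j]: best within-block medoid cost of segments i..j."""
    n = delta.shape[0]
    csum = np.vstack([np.zeros(n), np.cumsum(delta, axis=0)])  # (n+1, n)
    cost = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i, n):
            # sum over rows i..j for each candidate medoid column m in i..j
            sums = csum[j + 1, i:j + 1] - csum[i, i:j + 1]
            cost[i, j] = sums.min()
    return cost


def macrodomain_partition(mean_dist: np.ndarray, n_domains: int,
                          arm: str = "arm", d_cap: float = 750.0,
                          d_fill: float = 1000.0) -> Partition:
    """Optimal sequence-continuous K-medoids partition of one arm.

    Minimizes the total dissimilarity of segments to their domain medoid
    over all contiguous partitions into ``n_domains`` blocks (dynamic
    program over block boundaries -- the contiguity constraint makes the
    global optimum tractable). Ties break toward the earliest boundary.
    """
    n = mean_dist.shape[0]
    if n_domains < 1 or n_domains > n:
        raise RangeError(f"cannot cut {n} segments into {n_domains} domains")
    delta = dissimilarity_from_distances(mean_dist, d_cap, d_fill)
    cost = _block_costs(delta)
    best = np.full((n_domains + 1, n + 1), np.inf)
    back = np.zeros((n_domains + 1, n + 1), dtype=np.int64)
    best[0, 0] = 0.0
    for k in range(1, n_domains + 1):
        for j in range(k, n + 1):
            cands = best[k - 1, k - 1:j] + cost[k - 1:j, j - 1]
            arg = int(np.argmin(cands))
            best[k, j] = cands[arg]
            back[k, j] = arg + k - 1
    bounds = []
    j = n
    for k in range(n_domains, 0, -1):
        i = back[k, j]
        bounds.append(int(i))
        j = i
    return Partition(arm, sorted(bounds), n)


def partition_objective(delta: np.ndarray, partition: Partition) -> float:
    """Total within-domain dissimilarity to the best medoid (for testing)."""
    tot = 0.0
    bounds = partition.boundaries + [partition.n_segments]
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        block = delta[b0:b1, b0:b1]
        tot += float(block.sum(axis=0).min())
    return tot


def partition_overlap(part_a: Partition, part_b: Partition,
                      exclude: np.ndarray | None = None) -> float:
    """Overlap q: fraction of segments whose sequentially numbered domain
    label agrees between partitions (excluded segments, e.g. centromeric,
    are left out of the count)."""
    if part_a.n_segments != part_b.n_segments:
        raise FormatError("partitions cover different segment counts")
    la, lb = part_a.labels(), part_b.labels()
    keep = np.ones(part_a.n_segments, dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    if keep.sum() == 0:
        raise DegenerateDataError("no segments left to compare")
    return float(np.mean(la[keep] == lb[keep]))


def random_partition(n_segments: int, n_domains: int,
                     rng: np.random.Generator) -> Partition:
    """Uniform random sequence-continuous subdivision (stars and bars)."""
    cuts = rng.choice(n_segments - 1, size=n_domains - 1, replace=False) + 1
    return Partition("random", [0] + sorted(int(c) for c in cuts), n_segments)


def overlap_significance(part_a: Partition, part_b: Partition,
                         n_random: int = 1000, seed: int = 0,
                         exclude: np.ndarray | None = None):
    """Permutation p-value of the observed overlap.

    The observed q is compared against ``n_random`` random
    sequence-continuous subdivisions (same segment and domain counts)
    substituted for the first partition: p = (1 + #{q_rand >= q}) /
    (n_random + 1). Returns (q, p_value).
    """
    rng = np.random.default_rng(seed)
    q_obs = partition_overlap(part_a, part_b, exclude)
    count = 0
    for _ in range(n_random):
        q_r = partition_overlap(
            random_partition(part_a.n_segments, part_a.n_domains, rng),
            part_b, exclude)
        if q_r >= q_obs - 1e-12:
            count += 1
    return q_obs, (1 + count) / (n_random + 1)


# ---------------------------------------------------------------------------
# Procrustes RMSD
# ---------------------------------------------------------------------------

def procrustes_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                    scaling: bool = False) -> float:
    """RMSD after optimal rigid superimposition (Kabsch).

    Optimal translation and proper rotation of B onto A (optional uniform
    scaling). Reflections are excluded: the superimposition is rigid.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.shape[0] < 3:
        raise FormatError("need two equal point sets with >= 3 points")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    s_adj = s.copy()
    s_adj[-1] *= d
    if scaling:
        scale = s_adj.sum() / (b0 ** 2).sum()
    else:
        scale = 1.0
    diff = a0 - scale * b0 @ rot.T
    return float(np.sqrt((diff ** 2).sum() / a.shape[0]))


# ---------------------------------------------------------------------------
# MDS reconstruction
# ---------------------------------------------------------------------------

def mds_reconstruct(hic_dense: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Classical MDS model of a chromosome from its Hi-C matrix.

    Counts convert to distances d_ij = x_ij ** -alpha where x > 0; missing
    entries are completed to the shortest-path metric with the
    Floyd-Warshall algorithm; the top three eigenvectors of the
    double-centred squared-distance matrix give 3D coordinates.
    """
    x = np.asarray(hic_dense, dtype=float)
    n = x.shape[0]
    if x.shape != (n, n):
        raise FormatError("Hi-C matrix must be square")
    with np.errstate(divide="ignore"):
        d = np.where(x > 0, x ** -alpha, 0.0)
    np.fill_diagonal(d, 0.0)
    graph = csr_array(d)
    full = shortest_path(graph, method="FW", directed=False)
    if np.any(np.isinf(full)):
        raise DegenerateDataError("contact graph is disconnected")
    d2 = full ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:3]
    lam = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(lam)
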