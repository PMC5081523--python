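"""Steered dynamics: COM restraints from significant contacts, ramped
springs, and the pre-mitotic recondensation protocol.

Each significant cis contact becomes one harmonic restraint per homolog
copy between the centres of mass of the two 33-bead (100 kb) target
regions. Initial spring constants are set from the sequence separation of
the pair so as to just counteract the entropic recoil of the intervening
chain: for a worm-like segment of contour length L = s * sigma and
persistence length l_p, k_init = 3 k_B T / (2 l_p L). During steering the
spring constants ramp linearly from k_init to k_max; satisfaction of the
targets is tracked per snapshot under both contact criteria (COM proximity
and closest-bead proximity) at 120/240/480 nm cutoffs.

Recondensation replaces all steering restraints by single-bead anchor
couplings at a regular 200 kb (66-bead) spacing along every chain, with
equal constant spring constants and a stepped equilibrium-distance
schedule: 200 nm down to 30 nm in 30 nm decrements every 0.6 tau_LJ, then a
hold at 30 nm. This drives the chromosomes into a linear succession of
loops, the mitotic-like state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ForceFieldParams, Simulation
from .errors import RangeError
from .system import BeadSystem, PERSISTENCE_LENGTH, Trajectory

MIN_SEPARATION_BEADS = 66  # below the 100 kb region scale steering is moot
DEFAULT_K_MAX = 0.1        # k_B T / nm^2, steering plateau
RECONDENSATION_K = 1.0     # k_B T / nm^2, all equal and constant
STEERING_CUTOFFS = (120.0, 240.0, 480.0)  # nm


@dataclass
class Restraint:
    """COM harmonic restraint between two bead ranges of one chain."""

    chain: int               # chain index within the system
    beads_a: tuple[int, int]  # global half-open bead range
    beads_b: tuple[int, int]
    separation: int          # sequence separation in beads
    k_init: float            # k_B T / nm^2
    k_max: float
    d0: float = 0.0          # nm

    def groups(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.arange(*self.beads_a, dtype=np.int64),
                np.arange(*self.beads_b, dtype=np.int64))


@dataclass
class RestraintSet:
    """Restraints plus their schedule mode."""

    restraints: list[Restraint] = field(default_factory=list)
    mode: str = "steering"   # or "recondensation"

    def __len__(self) -> int:
        return len(self.restraints)

    def flatten(self):
        """(groups, pairs, k_init, k_max, d0) arrays for the engine."""
        groups, pairs = [], []
        for r in self.restraints:
            ga, gb = r.groups()
            pairs.append((len(groups), len(groups) + 1))
            groups.extend([ga, gb])
        return (groups, np.array(pairs, dtype=np.int64).reshape(-1, 2),
                np.array([r.k_init for r in self.restraints]),
                np.array([r.k_max for r in self.restraints]),
                np.array([r.d0 for r in self.restraints]))


def init_spring_constant(separation_beads: int,
                         sigma: float = 30.0,
                         persistence_length: float = PERSISTENCE_LENGTH,
                         temperature_kbt: float = 1.0) -> float:
    """Entropic spring constant of the chain segment between the targets.

    k = 3 k_B T / (2 l_p L) with contour length L = s * sigma; monotone
    decreasing in s, halving when s doubles. Separations below 66 beads are
    clamped (with a warning) to the minimum meaningful separation.
    """
    s = separation_beads
    if s < MIN_SEPARATION_BEADS:
        warnings.warn(f"separation {s} beads below minimum "
                      f"{MIN_SEPARATION_BEADS}; clamping")
        s = MIN_SEPARATION_BEADS
    contour = s * sigma
    return 3.0 * temperature_kbt / (2.0 * persistence_length * contour)


def build_restraints(contacts: pd.DataFrame, system: BeadSystem, disc,
                     resolution: int = 100_000,
                     k_max: float = DEFAULT_K_MAX) -> RestraintSet:
    """One restraint per significant contact per homolog copy.

    ``contacts`` needs columns [chrom, bin_i, bin_j]. A cis contact on a
    two-copy autosome yields one restraint in each copy, never
    cross-homolog; single-copy X yields one.
    """
    rset = RestraintSet(mode="steering")
    for row in contacts.itertuples(index=False):
        for ci, chain in enumerate(system.chains):
            if chain.name != row.chrom:
                continue
            a0, a1 = disc.bin_to_beads(row.chrom, int(row.bin_i), resolution)
            b0, b1 = disc.bin_to_beads(row.chrom, int(row.bin_j), resolution)
            if a1 > chain.n_beads or b1 > chain.n_beads:
                raise RangeError(
                    f"contact bin outside chromosome {row.chrom}")
            sep = abs(int(row.bin_j) - int(row.bin_i)) * disc.beads_per_bin(resolution)
            rset.restraints.append(Restraint(
                chain=ci,
                beads_a=(chain.start + a0, chain.start + a1),
                beads_b=(chain.start + b0, chain.start + b1),
                separation=sep,
                k_init=init_spring_constant(sep, system.bead_diameter),
                k_max=k_max,
            ))
    return rset


# ---------------------------------------------------------------------------
# steering runs
# ---------------------------------------------------------------------------

def _satisfaction_row(coords, rset: RestraintSet, t: float,
                      cutoffs=STEERING_CUTOFFS) -> list[dict]:
    from .analysis import satisfaction_fractions
    fr = satisfaction_fractions(coords, rset, cutoffs)
    rows = []
    for crit in ("com", "closest"):
        for co in cutoffs:
            rows.append({"time": t, "criterion": crit, "cutoff_nm": co,
                         "fraction": fr[(crit, co)]})
    return rows


def steer(system: BeadSystem, rset: RestraintSet,
          params: ForceFieldParams | None = None,
          duration_tau: float = 6000.0, seed: int = 0,
          n_chunks: int = 30, k_max: np.ndarray | None = None,
          sim: Simulation | None = None):
    """Run the steering phase with linearly ramped spring constants.

    Returns ``(trajectory, satisfaction)``: checkpoint trajectory and a
    tidy DataFrame of satisfied-fraction curves (criterion x cutoff x time).
    Production duration is at most 6,000 tau_LJ; desk-scale runs pass less.
    """
    params = params or ForceFieldParams()
    if sim is None:
        sim = Simulation(system, params, seed=seed, confined=True)
    groups, pairs, k_init, k_max_arr, d0 = rset.flatten()
    if k_max is not None:
        k_max_arr = np.broadcast_to(np.asarray(k_max, dtype=float),
                                    k_init.shape).copy()
    traj = Trajectory()
    traj.append(sim.time, system.coords)
    sat_rows = _satisfaction_row(system.coords, rset, sim.time)
    t0 = sim.time
    if len(rset):
        sim.set_restraints(groups, pairs, k_init, d0)
    for c in range(1, n_chunks + 1):
        frac = c / n_chunks
        if len(rset):
            k_now = k_init + frac * (k_max_arr - k_init)
            sim.update_restraints(k_nm=k_now)
        sim.run_tau(duration_tau / n_chunks)
        traj.append(sim.time, system.coords)
        sat_rows += _satisfaction_row(system.coords, rset, sim.time)
    return traj, pd.DataFrame(sat_rows)


def add_restraints_and_continue(system: BeadSystem, old: RestraintSet,
                                extra: RestraintSet,
                                params: ForceFieldParams | None = None,
                                duration_tau: float = 600.0, seed: int = 0,
                                n_chunks: int = 10,
                                cutoff_nm: float = 480.0,
                                criterion: str = "closest"):
    """Keep the old restraints at full strength, ramp in the new set.

    Returns ``(trajectory, report)`` where the report DataFrame tracks the
    maintained fraction of the old set and the established fraction of the
    new set over time (at ``cutoff_nm`` under ``criterion``).
    """
    from .analysis import satisfaction_fractions
    params = params or ForceFieldParams()
    sim = Simulation(system, params, seed=seed, confined=True)
    groups_o, pairs_o, _, kmax_o, d0_o = old.flatten()
    groups_n, pairs_n, kinit_n, kmax_n, d0_n = extra.flatten()
    groups = groups_o + groups_n
    off = len(groups_o)
    pairs = np.concatenate([pairs_o.reshape(-1, 2),
                            pairs_n.reshape(-1, 2) + off]) \
        if len(extra) else pairs_o
    kmax_o_arr = np.full(len(old), DEFAULT_K_MAX) if len(old) else np.zeros(0)
    for i, r in enumerate(old.restraints):
        kmax_o_arr[i] = r.k_max
    d0 = np.concatenate([d0_o, d0_n])
    traj = Trajectory()
    rows = []

    def record(t):
        traj.append(t, system.coords)
        fo = satisfaction_fractions(system.coords, old, (cutoff_nm,))
        fn = satisfaction_fractions(system.coords, extra, (cutoff_nm,))
        rows.append({"time": t,
                     "maintained": fo[(criterion, cutoff_nm)],
                     "established": fn[(criterion, cutoff_nm)]})

    record(sim.time)
    for c in range(1, n_chunks + 1):
        frac = c / n_chunks
        k_now = np.concatenate([
            kmax_o_arr,
            kinit_n + frac * (kmax_n - kinit_n) if len(extra) else np.zeros(0),
        ])
        sim.set_restraints(groups, pairs, k_now, d0)
        sim.run_tau(duration_tau / n_chunks)
        record(sim.time)
    return traj, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pre-mitotic recondensation
# ---------------------------------------------------------------------------

def recondensation_restraints(system: BeadSystem,
                              spacing_beads: int = 66,
                              k: float = RECONDENSATION_K) -> RestraintSet:
    """Single-bead anchor couplings every 200 kb (66 beads) along each chain.

    Anchors sit at beads 0, s, 2s, ...; the final bead joins as a last
    anchor when it is not already one. Consecutive anchors are paired.
    Chains shorter than the spacing contribute no anchors (warning).
    """
    rset = RestraintSet(mode="recondensation")
    for ci, chain in enumerate(system.chains):
        if chain.n_beads <= spacing_beads:
            if chain.n_beads < spacing_beads:
                warnings.warn(f"chain {chain.label} shorter than anchor "
                              "spacing; no recondensation anchors")
                continue
        anchors = list(range(0, chain.n_beads, spacing_beads))
        if anchors[-1] != chain.n_beads - 1:
            anchors.append(chain.n_beads - 1)
        for a, b in zip(anchors[:-1], anchors[1:]):
            rset.restraints.append(Restraint(
                chain=ci,
                beads_a=(chain.start + a, chain.start + a + 1),
                beads_b=(chain.start + b, chain.start + b + 1),
                separation=b - a,
                k_init=k, k_max=k, d0=200.0))
    return rset


def recondensation_schedule(d_start: float = 200.0, d_end: float = 30.0,
                            step: float = 30.0) -> list[float]:
    """Equilibrium-distance schedule 200 -> 30 nm in 30 nm steps, clamped
    so the final value lands exactly on the bead size."""
    sched = []
    d = d_start
    while d > d_end:
        sched.append(d)
        d -= step
    sched.append(d_end)
    return sched


def recondense(system: BeadSystem, params: ForceFieldParams | None = None,
               spacing_beads: int = 66, k: float = RECONDENSATION_K,
               step_tau: float = 0.6, total_tau: float = 300.0,
               seed: int = 0, n_hold_checkpoints: int = 10):
    """Run the recondensation protocol.

    All steering restraints are dropped; anchor pairs get equal constant
    springs whose equilibrium distance steps down 200 -> 30 nm every
    ``step_tau``, then the run extends to ``total_tau`` at 30 nm. Returns
    ``(trajectory, satisfaction, rset)``.
    """
    params = params or ForceFieldParams()
    rset = recondensation_restraints(system, spacing_beads, k)
    sim = Simulation(system, params, seed=seed, confined=True)
    groups, pairs, k_arr, _, d0 = rset.flatten()
    sched = recondensation_schedule()
    traj = Trajectory()
    sat_rows = _satisfaction_row(system.coords, rset, sim.time)
    traj.append(sim.time, system.coords)
    for d_eq in sched:
        if len(rset):
            sim.set_restraints(groups, pairs, k_arr,
                               np.full(len(rset), d_eq))
        sim.run_tau(step_tau)
    traj.append(sim.time, system.coords)
    sat_rows += _satisfaction_row(system.coords, rset, sim.time)
    remaining = total_tau - len(sched) * step_tau
    if remaining > 0:
        chunk = remaining / n_hold_checkpoints
        for _ in range(n_hold_checkpoints):
            sim.run_tau(chunk)
            traj.append(sim.time, system.coords)
            sat_rows += _satisfaction_row(system.coords, rset, sim.time)
    return traj, pd.DataFrame(sat_rows), rset
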