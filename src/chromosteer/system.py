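"""Diploid bead-chain system: topology, coordinates and per-bead annotation.

Chromosomes are discretized into 30 nm beads of 3,030 bp each, so that a
100 kb Hi-C bin spans 33 consecutive beads. Autosomes are present in two
copies (distinct chains, e.g. ``chr1_a`` / ``chr1_b``); chromosome X in one.
All coordinates are in nanometres, with the nuclear centre at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError
from .genome import DEFAULT_NUCLEUS_RADIUS

BEAD_BP = 3030       # bp of chromatin per 30 nm bead
BEAD_DIAMETER = 30.0  # nm
PERSISTENCE_LENGTH = 150.0  # nm, target stiffness of the chromatin fiber


@dataclass
class Chain:
    """One chromosome copy: a contiguous block of beads."""

    name: str       # chromosome name
    copy: int       # 0 or 1
    start: int      # global index of first bead
    n_beads: int

    @property
    def label(self) -> str:
        return f"{self.name}_{'ab'[self.copy]}"

    @property
    def end(self) -> int:
        return self.start + self.n_beads

    @property
    def slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass
class BeadSystem:
    """Bead-chain topology + coordinates inside a spherical nucleus."""

    chains: list[Chain]
    coords: np.ndarray  # (N, 3) nm
    centromere: np.ndarray  # (N,) bool
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    bead_bp: int = BEAD_BP
    nucleus_radius: float = DEFAULT_NUCLEUS_RADIUS
    bead_diameter: float = BEAD_DIAMETER

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        self.centromere = np.asarray(self.centromere, dtype=bool)
        n = sum(c.n_beads for c in self.chains)
        if self.coords.shape != (n, 3):
            raise FormatError(
                f"coords shape {self.coords.shape} != ({n}, 3)")
        if self.centromere.shape != (n,):
            raise FormatError("centromere flag length mismatch")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def chain_index(self) -> np.ndarray:
        """Per-bead chain id (int array)."""
        idx = np.empty(self.n_beads, dtype=np.int64)
        for k, c in enumerate(self.chains):
            idx[c.slice] = k
        return idx

    def bonds(self) -> np.ndarray:
        """(M, 2) consecutive-bead bonds within chains."""
        parts = []
        for c in self.chains:
            i = np.arange(c.start, c.end - 1)
            parts.append(np.stack([i, i + 1], axis=1))
        if not parts:
            return np.zeros((0, 2), dtype=np.int64)
        return np.concatenate(parts).astype(np.int64)

    def angle_centers(self) -> np.ndarray:
        """Indices of interior beads (centres of bending angles)."""
        parts = [np.arange(c.start + 1, c.end - 1) for c in self.chains
                 if c.n_beads >= 3]
        if not parts:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate(parts).astype(np.int64)

    def chains_of(self, name: str) -> list[Chain]:
        return [c for c in self.chains if c.name == name]

    def radial(self) -> np.ndarray:
        return np.linalg.norm(self.coords, axis=1)

    def copy(self) -> "BeadSystem":
        return BeadSystem(
            chains=[Chain(c.name, c.copy, c.start, c.n_beads)
                    for c in self.chains],
            coords=self.coords.copy(),
            centromere=self.centromere.copy(),
            flags={k: v.copy() for k, v in self.flags.items()},
            bead_bp=self.bead_bp,
            nucleus_radius=self.nucleus_radius,
            bead_diameter=self.bead_diameter,
        )


@dataclass
class Trajectory:
    """Sequence of coordinate snapshots with their times (tau_LJ)."""

    times: list[float] = field(default_factory=list)
    snapshots: list[np.ndarray] = field(default_factory=list)

    def append(self, t: float, coords: np.ndarray) -> None:
        self.times.append(float(t))
        self.snapshots.append(np.array(coords, copy=True))

    def __len__(self) -> int:
        return len(self.snapshots)

    @property
    def final(self) -> np.ndarray:
        return self.snapshots[-1]


# ---------------------------------------------------------------------------
# conformation text format
# ---------------------------------------------------------------------------

def write_conformation(system: BeadSystem, path) -> None:
    """Plain-text per-bead records: chain label, bead index within chain,
    genomic start (bp) and x, y, z in nm at 3 decimals."""
    if not np.all(np.isfinite(system.coords)):
        raise FormatError("non-finite coordinate in conformation")
    with open(path, "w") as fh:
        fh.write("#chain\tbead\tgenomic_start\tx_nm\ty_nm\tz_nm\n")
        for c in system.chains:
            xyz = system.coords[c.slice]
            for b in range(c.n_beads):
                gs = b * system.bead_bp
                x, y, z = xyz[b]
                fh.write(f"{c.label}\t{b}\t{gs}\t{x:.3f}\t{y:.3f}\t{z:.3f}\n")


def read_conformation(path):
    """Read coordinates written by :func:`write_conformation`.

    Returns ``(labels, coords)``: per-bead chain labels (list of str) and an
    (N, 3) array in nm, in file order.
    """
    labels, rows = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: expected 6 columns")
            try:
                xyz = [float(p) for p in parts[3:6]]
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: malformed coordinate") from exc
            if not all(np.isfinite(xyz)):
                raise FormatError(f"{path}:{ln}: non-finite coordinate")
            labels.append(parts[0])
            rows.append(xyz)
    return labels, np.array(rows, dtype=float).reshape(-1, 3)
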