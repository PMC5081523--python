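"""Cis Hi-C contact matrices at fixed bin resolution.

The canonical on-disk format is sparse triplet text, one chromosome per
file::

    chrom  bin_i  bin_j  value

Bins may equivalently be given as bp start coordinates (multiples of the
resolution). A matrix stores its upper triangle only (``i <= j``); the
symmetric value is implied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, RangeError


@dataclass
class ContactMatrix:
    """Symmetric sparse cis contact matrix (upper triangle stored)."""

    chrom: str
    resolution: int
    n_bins: int
    bin_i: np.ndarray  # int, i <= j canonical
    bin_j: np.ndarray
    values: np.ndarray  # float >= 0

    def __post_init__(self) -> None:
        self.bin_i = np.asarray(self.bin_i, dtype=np.int64)
        self.bin_j = np.asarray(self.bin_j, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (len(self.bin_i) == len(self.bin_j) == len(self.values)):
            raise FormatError("triplet arrays have mismatched lengths")
        if len(self.values) and not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite contact value")
        if len(self.values) and self.values.min() < 0:
            raise FormatError("negative contact value")
        if len(self.bin_i):
            if self.bin_i.min() < 0 or self.bin_j.max() >= self.n_bins:
                raise RangeError(
                    f"bin index outside [0, {self.n_bins}) for {self.chrom}"
                )
        self._canonicalize()

    def _canonicalize(self) -> None:
        """Enforce i <= j and sum duplicate entries."""
        i = np.minimum(self.bin_i, self.bin_j)
        j = np.maximum(self.bin_i, self.bin_j)
        key = i * self.n_bins + j
        order = np.argsort(key, kind="stable")
        key, i, j, v = key[order], i[order], j[order], self.values[order]
        if len(key):
            uniq, inverse = np.unique(key, return_inverse=True)
            vsum = np.zeros(len(uniq))
            np.add.at(vsum, inverse, v)
            self.bin_i = (uniq // self.n_bins).astype(np.int64)
            self.bin_j = (uniq % self.n_bins).astype(np.int64)
            self.values = vsum
        else:
            self.bin_i, self.bin_j, self.values = i, j, v

    @property
    def n_entries(self) -> int:
        return len(self.values)

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense matrix."""
        m = np.zeros((self.n_bins, self.n_bins))
        m[self.bin_i, self.bin_j] = self.values
        m[self.bin_j, self.bin_i] = self.values
        return m

    @classmethod
    def from_dense(cls, chrom: str, resolution: int, dense: np.ndarray,
                   tol: float = 0.0) -> "ContactMatrix":
        dense = np.asarray(dense, dtype=float)
        if dense.ndim != 2 or dense.shape[0] != dense.shape[1]:
            raise FormatError("dense matrix must be square")
        iu, ju = np.triu_indices(dense.shape[0])
        v = np.asarray((dense[iu, ju] + dense[ju, iu]) / 2.0)
        keep = v > tol
        return cls(chrom, resolution, dense.shape[0], iu[keep], ju[keep], v[keep])


def read_contact_matrix(path, resolution: int, n_bins: int | None = None,
                        coords: str = "auto") -> ContactMatrix:
    """Read a triplet-text contact matrix (one chromosome per file).

    ``coords`` selects whether columns 2-3 are bin indices (``"bins"``),
    bp starts (``"starts"``) or should be guessed (``"auto"``: bp starts when
    every coordinate is a multiple of the resolution and at least one
    coordinate reaches it). Duplicate and transposed entries are summed.
    """
    chroms, ii, jj, vv = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 'chrom i j value'")
            try:
                a, b = int(parts[1]), int(parts[2])
                v = float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: malformed triplet") from exc
            if v < 0:
                raise FormatError(f"{path}:{ln}: negative value")
            if a < 0 or b < 0:
                raise FormatError(f"{path}:{ln}: negative coordinate")
            chroms.append(parts[0])
            ii.append(a)
            jj.append(b)
            vv.append(v)
    if chroms and len(set(chroms)) != 1:
        raise FormatError(f"{path}: more than one chromosome in file")
    chrom = chroms[0] if chroms else "chr?"
    i = np.array(ii, dtype=np.int64)
    j = np.array(jj, dtype=np.int64)
    if coords == "auto":
        allc = np.concatenate([i, j]) if len(i) else np.zeros(0, dtype=np.int64)
        is_starts = (len(allc) > 0 and np.all(allc % resolution == 0)
                     and allc.max() >= resolution)
        coords = "starts" if is_starts else "bins"
    if coords == "starts":
        i, j = i // resolution, j // resolution
    elif coords != "bins":
        raise ValueError(f"unknown coords mode {coords!r}")
    inferred = int(max(i.max(), j.max()) + 1) if len(i) else 0
    if n_bins is None:
        n_bins = max(inferred, 1)
    elif inferred > n_bins:
        raise RangeError(f"{path}: bin index beyond n_bins={n_bins}")
    return ContactMatrix(chrom, resolution, n_bins, i, j, np.array(vv))


def write_contact_matrix(matrix: ContactMatrix, path,
                         precision: int = 12) -> None:
    """Write triplet text the paired reader parses back identically."""
    with open(path, "w") as fh:
        for i, j, v in zip(matrix.bin_i, matrix.bin_j, matrix.values):
            if v == int(v):
                fh.write(f"{matrix.chrom}\t{i}\t{j}\t{int(v)}\n")
            else:
                fh.write(f"{matrix.chrom}\t{i}\t{j}\t{v:.{precision}g}\n")
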