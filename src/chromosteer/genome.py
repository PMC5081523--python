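"""Genome description: chromosomes, annotation tracks, radial placement targets.

All genomic intervals in the package are 0-based, half-open ``[start, end)``
in base pairs. A :class:`GenomeSpec` bundles everything the modelling pipeline
needs to know about the genome being modelled: chromosome lengths and
centromeres, copy numbers (two per autosome, one for X), per-feature
annotation tracks (genes, LADs, histone marks, Giemsa bands, ...) and the
phenomenological radial-placement table giving each chromosome's preferred
mean distance from the nuclear centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, RangeError

DEFAULT_NUCLEUS_RADIUS = 4800.0  # nm


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval with an optional feature label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ChromosomeRecord:
    """One chromosome: name, length, centromere interval and copy number."""

    name: str
    length_bp: int
    centromere: tuple[int, int] = (0, 0)
    copy_number: int = 2

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise FormatError(f"chromosome {self.name}: non-positive length")
        c0, c1 = self.centromere
        if not (0 <= c0 <= c1 <= self.length_bp):
            raise RangeError(
                f"chromosome {self.name}: centromere {self.centromere} outside "
                f"[0, {self.length_bp}]"
            )
        if self.copy_number not in (1, 2):
            raise FormatError(f"chromosome {self.name}: copy_number must be 1 or 2")


@dataclass
class GenomeSpec:
    """Chromosomes + annotation tracks + radial placement table."""

    chromosomes: list[ChromosomeRecord]
    tracks: dict[str, list[Interval]] = field(default_factory=dict)
    radial_targets: dict[str, float] = field(default_factory=dict)
    nucleus_radius: float = DEFAULT_NUCLEUS_RADIUS

    def __post_init__(self) -> None:
        lengths = {c.name: c.length_bp for c in self.chromosomes}
        if len(lengths) != len(self.chromosomes):
            raise FormatError("duplicate chromosome names")
        for name, ivs in self.tracks.items():
            for iv in ivs:
                if iv.chrom in lengths and iv.end > lengths[iv.chrom]:
                    raise RangeError(
                        f"track {name}: interval {iv.chrom}:{iv.start}-{iv.end} "
                        f"exceeds chromosome length {lengths[iv.chrom]}"
                    )
        for name, r in self.radial_targets.items():
            if not (0.0 <= r <= self.nucleus_radius):
                raise RangeError(
                    f"radial target for {name} ({r} nm) outside "
                    f"[0, {self.nucleus_radius}]"
                )

    def chromosome(self, name: str) -> ChromosomeRecord:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected 'chrom length'")
            try:
                n = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer length") from exc
            if n <= 0:
                raise FormatError(f"{path}:{ln}: non-positive length")
            sizes[parts[0]] = n
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, n in sizes.items():
            fh.write(f"{name}\t{n}\n")


def read_bed(path) -> list[Interval]:
    """Read a BED3+ file into a list of half-open intervals.

    Overlapping intervals are permitted and preserved; the optional fourth
    column becomes the feature label.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise FormatError(f"{path}:{ln}: require 0 <= start < end")
            label = parts[3] if len(parts) > 3 else ""
            out.append(Interval(parts[0], start, end, label))
    return out


def write_bed(intervals: list[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_radial_table(path) -> dict[str, float]:
    """Read ``chrom<TAB>mean_radial_nm`` placement propensities."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "radial_nm"])
    try:
        vals = df["radial_nm"].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric radial position") from exc
    return dict(zip(df["chrom"].astype(str), vals))


def write_radial_table(targets: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        for name, r in targets.items():
            fh.write(f"{name}\t{r:.1f}\n")
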