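"""Genome binning containers: binned count tracks, log-ratio tracks, score tracks.

All coordinates are 0-based, half-open. Bin-space coordinates index bins on a
chromosome; base-pair coordinates are ``bin_index * bin_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeSpec",
    "BinnedTrack",
    "RatioTrack",
    "ScoreTrack",
    "Domain",
    "Interval",
    "AnnotationSet",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes with lengths expressed in bins of ``bin_size`` bp."""

    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_size: int

    def __post_init__(self) -> None:
        if len(self.chromosomes) != len(self.lengths):
            raise ValueError("chromosomes and lengths must have equal length")
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        if any(n < 1 for n in self.lengths):
            raise ValueError("chromosome lengths must be >= 1 bin")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1 bp")

    @property
    def n_bins(self) -> int:
        return int(sum(self.lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.chromosomes.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes


def _as_chrom_arrays(
    genome: GenomeSpec, data: Mapping[str, Sequence], dtype
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for chrom, n in zip(genome.chromosomes, genome.lengths):
        if chrom not in data:
            raise ValueError(f"missing data for chromosome {chrom!r}")
        arr = np.asarray(data[chrom], dtype=dtype)
        if arr.shape != (n,):
            raise ValueError(
                f"{chrom}: expected {n} bins, got shape {arr.shape}"
            )
        out[chrom] = arr
    return out


@dataclass
class BinnedTrack:
    """Non-negative integer read counts per genomic bin."""

    genome: GenomeSpec
    counts: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        self.counts = _as_chrom_arrays(self.genome, self.counts, np.int64)
        for chrom, arr in self.counts.items():
            if (arr < 0).any():
                raise ValueError(f"{chrom}: negative counts")

    def total(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in self.genome.chromosomes])

    @classmethod
    def from_flat(cls, genome: GenomeSpec, flat: np.ndarray) -> "BinnedTrack":
        flat = np.asarray(flat)
        if flat.shape != (genome.n_bins,):
            raise ValueError("flat array does not match genome size")
        counts, i = {}, 0
        for chrom, n in zip(genome.chromosomes, genome.lengths):
            counts[chrom] = flat[i : i + n]
            i += n
        return cls(genome, counts)


@dataclass
class RatioTrack:
    """Per-bin log2(ChIP/input) with a mask for bins undefined in both tracks."""

    genome: GenomeSpec
    ratio: Mapping[str, np.ndarray]
    mask: Mapping[str, np.ndarray]  # True => undefined

    def __post_init__(self) -> None:
        self.ratio = _as_chrom_arrays(self.genome, self.ratio, np.float64)
        self.mask = _as_chrom_arrays(self.genome, self.mask, bool)

    def unmasked_values(self) -> np.ndarray:
        vals = [
            self.ratio[c][~self.mask[c]] for c in self.genome.chromosomes
        ]
        return np.concatenate(vals) if vals else np.empty(0)


@dataclass
class ScoreTrack:
    """Discretised bin scores in {+1, -gap_penalty} for segment detection."""

    genome: GenomeSpec
    scores: Mapping[str, np.ndarray]
    threshold: float
    gap_penalty: float

    def __post_init__(self) -> None:
        if self.gap_penalty <= 0:
            raise ValueError("gap_penalty must be > 0")
        self.scores = _as_chrom_arrays(self.genome, self.scores, np.float64)


@dataclass
class Domain:
    """A called enriched domain in bin coordinates (half-open)."""

    chrom: str
    start_bin: int
    end_bin: int
    score: float
    p: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        if self.end_bin <= self.start_bin:
            raise ValueError("end_bin must exceed start_bin")

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    def to_bp(self, genome: GenomeSpec) -> tuple[str, int, int]:
        b = genome.bin_size
        return self.chrom, self.start_bin * b, self.end_bin * b


@dataclass(frozen=True)
class Interval:
    """A named bp-coordinate interval with BED semantics."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """Named bp intervals (e.g. Ig variable-gene clusters), 0-based half-open."""

    intervals: list[Interval] = field(default_factory=list)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def validate_against(self, genome: GenomeSpec) -> None:
        for iv in self.intervals:
            if iv.chrom not in genome:
                raise ValueError(f"annotation on unknown chromosome {iv.chrom!r}")
            limit = genome.length_of(iv.chrom) * genome.bin_size
            if iv.end > limit:
                raise ValueError(
                    f"annotation {iv.name} exceeds {iv.chrom} length {limit}"
                )

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out
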