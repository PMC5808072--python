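"""Differential Lamin B1 binding between two conditions.

Comparisons run on the bin-level log-ratio tracks rather than on domain
calls: a drop in binding inside an otherwise strengthened region (a canyon
inside a mesa) is visible to a bin-level delta but invisible to domain set
subtraction. Domain-level coverage deltas remain available as a secondary,
chromosome-scale view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import AnnotationSet, Domain, GenomeSpec, Interval, RatioTrack

__all__ = [
    "DifferentialRegion",
    "OverlapReport",
    "LocusFoldChange",
    "chromosome_binding_profile",
    "detect_canyons_mesas",
    "overlap_annotation",
    "locus_fold_change",
    "regions_jaccard",
]


@dataclass
class DifferentialRegion:
    """A canyon (binding loss) or mesa (binding gain) in bin coordinates."""

    chrom: str
    start_bin: int
    end_bin: int
    kind: str  # "canyon" | "mesa"
    mean_delta: float  # mean (condition B - condition A) log2 ratio

    def __post_init__(self) -> None:
        if self.kind not in ("canyon", "mesa"):
            raise ValueError("kind must be 'canyon' or 'mesa'")
        if self.end_bin <= self.start_bin:
            raise ValueError("end_bin must exceed start_bin")

    def to_bp(self, genome: GenomeSpec) -> Interval:
        b = genome.bin_size
        return Interval(self.chrom, self.start_bin * b, self.end_bin * b, self.kind)


@dataclass
class OverlapReport:
    """Observed vs expected overlap of regions with an annotation set."""

    overlap_bp: int
    jaccard: float
    per_annotation_bp: dict[str, int]
    enrichment: float | None  # observed / mean permuted overlap
    p_value: float | None


@dataclass
class LocusFoldChange:
    """Linear-scale binding fold change at one locus between conditions."""

    fold: float  # mean linear ratio A / mean linear ratio B
    n_bins: int
    defined: bool

    @property
    def description(self) -> str:
        if not self.defined:
            return "undefined (locus fully masked)"
        if self.fold >= 1:
            return f"{self.fold:.2f}-fold reduction"
        return f"{1 / self.fold:.2f}-fold increase"


def chromosome_binding_profile(
    domains: list[Domain], genome: GenomeSpec
) -> dict[str, float]:
    """Fraction of each chromosome's bins covered by called domains."""
    covered = {c: np.zeros(n, dtype=bool)
               for c, n in zip(genome.chromosomes, genome.lengths)}
    for d in domains:
        if d.chrom not in covered:
            raise ValueError(f"domain on unknown chromosome {d.chrom!r}")
        if d.end_bin > genome.length_of(d.chrom):
            raise ValueError(f"domain exceeds {d.chrom} length")
        covered[d.chrom][d.start_bin : d.end_bin] = True
    return {c: float(v.mean()) for c, v in covered.items()}


def binding_profile_delta(
    domains_a: list[Domain], domains_b: list[Domain], genome: GenomeSpec
) -> dict[str, float]:
    """Per-chromosome coverage fraction change, condition B minus A."""
    fa = chromosome_binding_profile(domains_a, genome)
    fb = chromosome_binding_profile(domains_b, genome)
    return {c: fb[c] - fa[c] for c in genome.chromosomes}


def detect_canyons_mesas(
    ratio_a: RatioTrack,
    ratio_b: RatioTrack,
    delta: float = 0.5,
    min_width: int = 3,
) -> list[DifferentialRegion]:
    """Maximal runs of bins whose log2-ratio delta crosses +-``delta``.

    The delta track is ratio_b - ratio_a, masked where either input is
    masked. Canyons are runs of at least ``min_width`` bins with delta <=
    -``delta``; mesas symmetric at >= +``delta``.
    """
    if ratio_a.genome != ratio_b.genome:
        raise ValueError("ratio tracks have different genome specifications")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    regions: list[DifferentialRegion] = []
    for chrom in ratio_a.genome.chromosomes:
        d = ratio_b.ratio[chrom] - ratio_a.ratio[chrom]
        masked = ratio_a.mask[chrom] | ratio_b.mask[chrom]
        for kind, hit in (
            ("canyon", (d <= -delta) & ~masked),
            ("mesa", (d >= delta) & ~masked),
        ):
            for start, end in _runs(hit):
                if end - start >= min_width:
                    regions.append(
                        DifferentialRegion(
                            chrom, start, end, kind,
                            mean_delta=float(d[start:end].mean()),
                        )
                    )
    regions.sort(key=lambda r: (ratio_a.genome.chromosomes.index(r.chrom),
                                r.start_bin))
    return regions


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal True runs."""
    padded = np.concatenate([[False], flags, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlap_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total overlap between two merged, sorted interval lists."""
    total, i, j = 0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _regions_to_bp(
    regions: list, genome: GenomeSpec
) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    bs = genome.bin_size
    for r in regions:
        if isinstance(r, Interval):
            out.setdefault(r.chrom, []).append((r.start, r.end))
        else:  # Domain or DifferentialRegion, bin coordinates
            out.setdefault(r.chrom, []).append(
                (r.start_bin * bs, r.end_bin * bs)
            )
    return {c: _merge(v) for c, v in out.items()}


def regions_jaccard(regions_a: list, regions_b: list, genome: GenomeSpec) -> float:
    """Jaccard index (bp) between two region sets."""
    a = _regions_to_bp(regions_a, genome)
    b = _regions_to_bp(regions_b, genome)
    inter = sum(_overlap_bp(a.get(c, []), b.get(c, [])) for c in genome.chromosomes)
    len_a = sum(e - s for ivs in a.values() for s, e in ivs)
    len_b = sum(e - s for ivs in b.values() for s, e in ivs)
    union = len_a + len_b - inter
    return inter / union if union else 0.0


def overlap_annotation(
    regions: list,
    annotation: AnnotationSet,
    genome: GenomeSpec,
    n_perm: int = 1000,
    seed: int = 0,
) -> OverlapReport:
    """Overlap of regions (domains or differential regions) with annotations.

    Enrichment is observed overlap divided by its expectation under circular
    permutation: region sets are rotated within each chromosome by uniform
    random offsets, preserving their lengths and spacing. The empirical
    p-value uses the usual (1 + #extreme)/(n_perm + 1) estimator.
    """
    annot_bp = _regions_to_bp(list(annotation), genome)
    region_bp = _regions_to_bp(regions, genome)
    if not annotation or not regions:
        return OverlapReport(0, 0.0, {}, None, None)

    observed = sum(
        _overlap_bp(region_bp.get(c, []), annot_bp.get(c, []))
        for c in genome.chromosomes
    )
    per_annot: dict[str, int] = {}
    for iv in annotation:
        ov = _overlap_bp(region_bp.get(iv.chrom, []), [(iv.start, iv.end)])
        per_annot[iv.name] = int(per_annot.get(iv.name, 0) + ov)
    jac = regions_jaccard(regions, list(annotation), genome)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chrom_len_bp = {
        c: n * genome.bin_size for c, n in zip(genome.chromosomes, genome.lengths)
    }
    perm_overlaps = np.zeros(n_perm)
    for k in range(n_perm):
        total = 0
        for chrom, ivs in region_bp.items():
            L = chrom_len_bp[chrom]
            shift = int(rng.integers(0, L))
            shifted: list[tuple[int, int]] = []
            for s, e in ivs:
                s2, e2 = (s + shift) % L, (e + shift) % L
                if s2 < e2:
                    shifted.append((s2, e2))
                else:  # wraps around the origin
                    shifted.append((s2, L))
                    shifted.append((0, e2))
            total += _overlap_bp(_merge(shifted), annot_bp.get(chrom, []))
        perm_overlaps[k] = total
    expected = float(perm_overlaps.mean())
    enrichment = observed / expected if expected > 0 else float("inf")
    p = (1 + int((perm_overlaps >= observed).sum())) / (n_perm + 1)
    return OverlapReport(int(observed), jac, per_annot, enrichment, p)


def locus_fold_change(
    ratio_a: RatioTrack, ratio_b: RatioTrack, interval: Interval
) -> LocusFoldChange:
    """Binding fold change over a bp interval: mean(2^a) / mean(2^b).

    Values above 1 are reductions in condition B relative to A. Masked bins
    are excluded; a fully masked interval yields an undefined (flagged)
    result.
    """
    if ratio_a.genome != ratio_b.genome:
        raise ValueError("ratio tracks have different genome specifications")
    genome = ratio_a.genome
    if interval.chrom not in genome:
        raise ValueError(f"unknown chromosome {interval.chrom!r}")
    bs = genome.bin_size
    start_bin = interval.start // bs
    end_bin = -(-interval.end // bs)  # ceil: include partially covered bins
    end_bin = min(end_bin, genome.length_of(interval.chrom))
    sl = slice(start_bin, end_bin)
    keep = ~(ratio_a.mask[interval.chrom][sl] | ratio_b.mask[interval.chrom][sl])
    n = int(keep.sum())
    if n == 0:
        return LocusFoldChange(float("nan"), 0, defined=False)
    lin_a = np.exp2(ratio_a.ratio[interval.chrom][sl][keep]).mean()
    lin_b = np.exp2(ratio_b.ratio[interval.chrom][sl][keep]).mean()
    return LocusFoldChange(float(lin_a / lin_b), n, defined=True)
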