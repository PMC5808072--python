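"""Somatic hypermutation quantification from clonal V-gene sequences.

Clones (Sanger-sequenced bacterial colonies of a PCR-amplified immunoglobulin
V-region) are globally aligned to the reference amplicon, substitutions are
called per aligned base-base column, and each substitution is classified
against the AID deamination hotspot motif: WRCY on the top strand (the mutated
base is the C) and its reverse complement RGYW (the mutated base is the G),
with W={A,T}, R={A,G}, Y={C,T}.

The headline statistic is mutations per base pair: substitutions divided by
the total number of aligned base pairs across all clones of a condition. A
condition passes QC only when at least 10,000 aligned base pairs were
assessed. Conditions are contrasted with an exact conditional binomial test
on the substitution counts, treating aligned base pairs as exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy import stats

__all__ = [
    "ReferenceSequence",
    "AlignScoring",
    "CloneAlignment",
    "Substitution",
    "MutationSummary",
    "FoldChangeResult",
    "align_clone",
    "call_substitutions",
    "classify_hotspot",
    "hotspot_labels",
    "summarize_condition",
    "compare_conditions",
    "substitution_spectrum",
    "qc_clones",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# IUPAC degenerate classes used by the AID hotspot motif
_W = frozenset("AT")
_R = frozenset("AG")
_Y = frozenset("CT")

MIN_ASSESSED_BP = 10_000  # QC rule: bp assessed per condition


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference amplicon: plain A/C/G/T, 0-based coordinates."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 4:
            raise ValueError("reference must be at least 4 bp")
        bad = set(self.seq) - set(BASES)
        if bad:
            raise ValueError(f"non-ACGT characters in reference: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignScoring:
    """Global alignment scores. A gap of length k costs open + (k-1)*extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class CloneAlignment:
    """A global alignment of one clone against the reference.

    ``ref_gapped`` and ``clone_gapped`` are the two rows of the alignment;
    gap columns use '-'.
    """

    ref: ReferenceSequence
    clone_id: str
    ref_gapped: str
    clone_gapped: str
    score: float

    @property
    def ref_id(self) -> str:
        return self.ref.id

    @property
    def aligned_bp(self) -> int:
        """Columns where both rows carry a base (match or mismatch)."""
        return sum(
            1
            for r, c in zip(self.ref_gapped, self.clone_gapped)
            if r != "-" and c != "-"
        )

    @property
    def n_mismatches(self) -> int:
        return sum(
            1
            for r, c in zip(self.ref_gapped, self.clone_gapped)
            if r != "-" and c != "-" and r != c
        )

    @property
    def n_indel_events(self) -> int:
        """Number of maximal gap runs in either row."""
        events, in_gap = 0, False
        for r, c in zip(self.ref_gapped, self.clone_gapped):
            gap = r == "-" or c == "-"
            if gap and not in_gap:
                events += 1
            in_gap = gap
        return events


@dataclass(frozen=True)
class Substitution:
    """A single-base substitution in reference coordinates."""

    ref_position: int
    ref_base: str
    alt_base: str
    clone_id: str
    hotspot: str = "none"  # WRCY | RGYW | none

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ValueError("bases must be A/C/G/T")


@dataclass
class MutationSummary:
    """Per-condition aggregate of substitution calls.

    ``hotspot_fraction`` is None when there are no substitutions.
    """

    condition: str
    total_aligned_bp: int
    n_substitutions: int
    n_indel_events: int
    spectrum: np.ndarray  # 4x4 counts indexed by (ref, alt) in ACGT order
    n_hotspot: int
    n_clones: int
    substitutions: list[Substitution] = field(default_factory=list, repr=False)

    @property
    def mut_per_bp(self) -> float:
        return self.n_substitutions / self.total_aligned_bp

    @property
    def hotspot_fraction(self) -> float | None:
        if self.n_substitutions == 0:
            return None
        return self.n_hotspot / self.n_substitutions

    @property
    def cg_fraction(self) -> float | None:
        if self.n_substitutions == 0:
            return None
        cg = self.spectrum[_BASE_INDEX["C"], :].sum() + self.spectrum[
            _BASE_INDEX["G"], :
        ].sum()
        return float(cg) / self.n_substitutions

    @property
    def qc_pass(self) -> bool:
        return self.total_aligned_bp >= MIN_ASSESSED_BP


@dataclass
class FoldChangeResult:
    """Rate ratio of mutations/bp between two conditions with exact inference."""

    rate_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "exact conditional binomial"


def _check_seq(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} is empty")
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"non-ACGT characters in {what}: {sorted(bad)}")
    return seq


def _make_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_clone(
    ref: ReferenceSequence,
    clone_seq: str,
    clone_id: str = "clone",
    scoring: AlignScoring = AlignScoring(),
) -> CloneAlignment:
    """Optimal global alignment of a clone against the reference.

    Mismatches score above gaps at the defaults, so point substitutions are
    preferred over spurious indel pairs. Among co-optimal alignments the
    aligner's first enumeration order is taken, which is deterministic.
    """
    clone_seq = _check_seq(clone_seq, f"clone {clone_id}")
    aligner = _make_aligner(scoring)
    aln = aligner.align(ref.seq, clone_seq)[0]
    ref_row, clone_row = str(aln[0]), str(aln[1])
    return CloneAlignment(
        ref=ref,
        clone_id=clone_id,
        ref_gapped=ref_row,
        clone_gapped=clone_row,
        score=float(aln.score),
    )


def classify_hotspot(ref: ReferenceSequence, position: int) -> str:
    """Classify a reference position against the AID hotspot motif.

    Returns "WRCY" if the base is the C of a WRCY match, "RGYW" if it is the
    G of an RGYW match (the motif seen by AID on the bottom strand), else
    "none". Motif windows truncated by either sequence end never match; WRCY
    takes precedence if a position could satisfy both readings.
    """
    s = ref.seq
    if not 0 <= position < len(s):
        raise ValueError(f"position {position} out of range for {len(s)} bp reference")
    if s[position] == "C" and position >= 2 and position + 1 < len(s):
        if s[position - 2] in _W and s[position - 1] in _R and s[position + 1] in _Y:
            return "WRCY"
    if s[position] == "G" and position >= 1 and position + 2 < len(s):
        if s[position - 1] in _R and s[position + 1] in _Y and s[position + 2] in _W:
            return "RGYW"
    return "none"


def hotspot_labels(ref: ReferenceSequence) -> list[str]:
    """Hotspot label for every reference position."""
    return [classify_hotspot(ref, i) for i in range(len(ref))]


def call_substitutions(aln: CloneAlignment) -> list[Substitution]:
    """One Substitution per mismatched base-base column, in reference coords.

    Indel columns contribute no substitutions (they are tallied separately as
    indel events by the alignment object).
    """
    subs: list[Substitution] = []
    ref_pos = 0
    for r, c in zip(aln.ref_gapped, aln.clone_gapped):
        if r != "-" and c != "-" and r != c:
            subs.append(
                Substitution(
                    ref_position=ref_pos,
                    ref_base=r,
                    alt_base=c,
                    clone_id=aln.clone_id,
                    hotspot=classify_hotspot(aln.ref, ref_pos),
                )
            )
        if r != "-":
            ref_pos += 1
    return subs


def qc_clones(
    alignments: list[CloneAlignment],
    max_mismatch_frac: float = 0.10,
    min_length_frac: float = 0.80,
    collapse_duplicates: bool = False,
) -> tuple[list[CloneAlignment], list[tuple[str, str]]]:
    """Filter cloning artifacts before summarising.

    Clones with more than ``max_mismatch_frac`` mismatched aligned columns or
    shorter than ``min_length_frac`` of the reference are discarded.
    Duplicate clone sequences are kept by default (flagged); with
    ``collapse_duplicates`` only the first of each identical sequence is kept.

    Returns (kept alignments, [(clone_id, reason), ...]) where reason is one
    of ``high_mismatch``, ``short``, ``duplicate`` (duplicates are listed
    even when kept).
    """
    kept: list[CloneAlignment] = []
    flagged: list[tuple[str, str]] = []
    seen: set[str] = set()
    for aln in alignments:
        clone_seq = aln.clone_gapped.replace("-", "")
        if len(clone_seq) < min_length_frac * len(aln.ref):
            flagged.append((aln.clone_id, "short"))
            continue
        if aln.aligned_bp and aln.n_mismatches / aln.aligned_bp > max_mismatch_frac:
            flagged.append((aln.clone_id, "high_mismatch"))
            continue
        if clone_seq in seen:
            flagged.append((aln.clone_id, "duplicate"))
            if collapse_duplicates:
                continue
        seen.add(clone_seq)
        kept.append(aln)
    return kept, flagged


def summarize_condition(
    alignments: list[CloneAlignment], condition: str
) -> MutationSummary:
    """Aggregate alignments of one condition into a MutationSummary."""
    if not alignments:
        raise ValueError("need at least one alignment")
    ref_ids = {a.ref.id for a in alignments}
    ref_seqs = {a.ref.seq for a in alignments}
    if len(ref_ids) > 1 or len(ref_seqs) > 1:
        raise ValueError(f"alignments mix references: {sorted(ref_ids)}")

    spectrum = np.zeros((4, 4), dtype=np.int64)
    subs: list[Substitution] = []
    total_bp = 0
    indels = 0
    for aln in alignments:
        total_bp += aln.aligned_bp
        indels += aln.n_indel_events
        for sub in call_substitutions(aln):
            spectrum[_BASE_INDEX[sub.ref_base], _BASE_INDEX[sub.alt_base]] += 1
            subs.append(sub)
    n_hot = sum(1 for s in subs if s.hotspot != "none")
    return MutationSummary(
        condition=condition,
        total_aligned_bp=total_bp,
        n_substitutions=len(subs),
        n_indel_events=indels,
        spectrum=spectrum,
        n_hotspot=n_hot,
        n_clones=len(alignments),
        substitutions=subs,
    )


def compare_conditions(
    a: MutationSummary, b: MutationSummary, conf_level: float = 0.95
) -> FoldChangeResult:
    """Exact conditional test of the mutations/bp rate ratio b vs a.

    Conditional on the total substitution count N = n_a + n_b, under the
    null of equal per-bp rates n_b ~ Binomial(N, bp_b/(bp_a+bp_b)). The
    two-sided p-value sums all outcomes no more likely than the observed
    one; the CI inverts the exact Clopper-Pearson interval for the binomial
    proportion onto the rate-ratio scale via ratio = odds(p) * bp_a/bp_b.
    """
    if a.total_aligned_bp <= 0 or b.total_aligned_bp <= 0:
        raise ValueError("both conditions need positive aligned bp")
    n_a, n_b = a.n_substitutions, b.n_substitutions
    bp_a, bp_b = a.total_aligned_bp, b.total_aligned_bp
    n_total = n_a + n_b
    if n_total == 0:
        return FoldChangeResult(
            rate_ratio=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=1.0,
        )
    rate_ratio = (n_b / bp_b) / (n_a / bp_a) if n_a > 0 else float("inf")
    p_null = bp_b / (bp_a + bp_b)
    test = stats.binomtest(n_b, n_total, p_null)
    ci = test.proportion_ci(confidence_level=conf_level, method="exact")
    scale = bp_a / bp_b

    def _odds(p: float) -> float:
        if p >= 1.0:
            return float("inf")
        return p / (1.0 - p)

    return FoldChangeResult(
        rate_ratio=rate_ratio,
        ci_low=_odds(ci.low) * scale,
        ci_high=_odds(ci.high) * scale,
        p_value=float(test.pvalue),
    )


def substitution_spectrum(
    summary: MutationSummary,
) -> tuple[np.ndarray, float | None, float | None]:
    """(4x4 count matrix, cg_fraction, transition_fraction) for a summary.

    Transitions are A<->G and C<->T. Fractions are None with no substitutions.
    """
    spectrum = summary.spectrum.copy()
    n = int(spectrum.sum())
    if n == 0:
        return spectrum, None, None
    a, c, g, t = (_BASE_INDEX[x] for x in "ACGT")
    transitions = spectrum[a, g] + spectrum[g, a] + spectrum[c, t] + spectrum[t, c]
    return spectrum, summary.cg_fraction, float(transitions) / n
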