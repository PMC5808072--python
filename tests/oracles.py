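"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a result by exhaustive enumeration or direct string
scanning, sharing no code with the implementation it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b) strings.

    Gap-against-gap columns are excluded; feasible only for tiny strings.
    """
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ra, rb in enumerate_global_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb
    if a:
        for ra, rb in enumerate_global_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_global_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb


def score_alignment(
    row_a: str, row_b: str, match: float, mismatch: float,
    gap_open: float, gap_extend: float,
) -> float:
    """Affine score where a gap of length k costs gap_open + (k-1)*gap_extend."""
    score = 0.0
    prev_gap_a = prev_gap_b = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            score += gap_extend if prev_gap_a else gap_open
            prev_gap_a, prev_gap_b = True, False
        elif cb == "-":
            score += gap_extend if prev_gap_b else gap_open
            prev_gap_a, prev_gap_b = False, True
        else:
            score += match if ca == cb else mismatch
            prev_gap_a = prev_gap_b = False
    return score


def best_alignment_score(a: str, b: str, match, mismatch, gap_open, gap_extend):
    return max(
        score_alignment(ra, rb, match, mismatch, gap_open, gap_extend)
        for ra, rb in enumerate_global_alignments(a, b)
    )


def positionwise_substitutions(ref: str, clone: str) -> list[tuple[int, str, str]]:
    """Substitutions of two equal-length gap-free sequences by direct scan."""
    assert len(ref) == len(clone)
    return [
        (i, r, c) for i, (r, c) in enumerate(zip(ref, clone)) if r != c
    ]


def _motif_hits(seq: str, motif_strings: set[str], offset: int) -> set[int]:
    """Start+offset positions of any motif string occurrence (overlaps allowed)."""
    hits = set()
    k = len(next(iter(motif_strings)))
    for i in range(len(seq) - k + 1):
        if seq[i : i + k] in motif_strings:
            hits.add(i + offset)
    return hits


def hotspot_scan(seq: str) -> list[str]:
    """Two-strand WRCY scan: labels per position by explicit motif matching.

    All 8 concrete WRCY strings are matched on the sequence (mutable C at
    start+2) and on its reverse complement (which maps to RGYW sites on the
    forward strand, mutable G). WRCY wins if a position matches both.
    """
    wrcy = {
        "".join(m)
        for m in product("AT", "AG", "C", "CT")
    }
    n = len(seq)
    forward = _motif_hits(seq, wrcy, offset=2)
    rc = seq.translate(_COMPLEMENT)[::-1]
    # C at rc position j corresponds to forward position n-1-j (a G there)
    reverse = {n - 1 - j for j in _motif_hits(rc, wrcy, offset=2)}
    labels = []
    for i in range(n):
        if i in forward:
            labels.append("WRCY")
        elif i in reverse:
            labels.append("RGYW")
        else:
            labels.append("none")
    return labels


def brute_maximal_segments(x: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal scoring segments by recursive exhaustive enumeration.

    Repeatedly select the best-scoring interval (ties: shortest, then
    leftmost) and recurse into the flanks; intervals with score <= 0 are
    discarded. O(n^2) per level.
    """
    x = np.asarray(x, dtype=float)
    prefix = np.concatenate([[0.0], np.cumsum(x)])

    def best(lo: int, hi: int) -> tuple[int, int, float] | None:
        pre = prefix[lo : hi + 1]
        starts, ends = np.triu_indices(len(pre), k=1)
        scores = pre[ends] - pre[starts]
        top = scores.max(initial=0.0)
        if top <= 0:
            return None
        cand = np.flatnonzero(scores == top)
        lengths = ends[cand] - starts[cand]
        cand = cand[lengths == lengths.min()]  # shortest, then leftmost
        k = cand[np.argmin(starts[cand])]
        return lo + int(starts[k]), lo + int(ends[k]), float(top)

    out: list[tuple[int, int, float]] = []

    def recurse(lo: int, hi: int) -> None:
        found = best(lo, hi)
        if found is None:
            return
        i, j, s = found
        recurse(lo, i)
        out.append((i, j, s))
        recurse(j, hi)

    recurse(0, len(x))
    return sorted(out)
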