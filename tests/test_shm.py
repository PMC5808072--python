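"""Alignment, substitution calling, hotspot classification and contrasts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lamingate import shm
from lamingate.shm import (
    AlignScoring,
    ReferenceSequence,
    align_clone,
    call_substitutions,
    classify_hotspot,
    compare_conditions,
    hotspot_labels,
    qc_clones,
    substitution_spectrum,
    summarize_condition,
)

from .oracles import (
    best_alignment_score,
    hotspot_scan,
    positionwise_substitutions,
)


class TestAlignClone:
    def test_identity(self):
        ref = ReferenceSequence("r", "ACGT")
        aln = align_clone(ref, "ACGT")
        assert aln.aligned_bp == 4
        assert call_substitutions(aln) == []

    def test_single_mismatch(self):
        ref = ReferenceSequence("r", "ACGT")
        aln = align_clone(ref, "ACTT")
        assert aln.aligned_bp == 4
        subs = call_substitutions(aln)
        assert [(s.ref_position, s.ref_base, s.alt_base) for s in subs] == [
            (2, "G", "T")
        ]

    def test_single_deletion_matches_enumeration_oracle(self):
        ref = ReferenceSequence("r", "ACGT")
        scoring = AlignScoring(1, -1, -2, -1)
        aln = align_clone(ref, "ACT", scoring=scoring)
        assert aln.aligned_bp == 3
        assert aln.n_indel_events == 1
        assert call_substitutions(aln) == []
        expected = best_alignment_score("ACGT", "ACT", 1, -1, -2, -1)
        assert aln.score == expected

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_score_equals_enumeration_on_tiny_pairs(self, seed):
        rng = np.random.default_rng(seed)
        scoring = AlignScoring(1, -1, -2, -1)
        for _ in range(15):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 7)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(2, 7)))
            aln = align_clone(ReferenceSequence("r", a), b, scoring=scoring)
            assert aln.score == best_alignment_score(a, b, 1, -1, -2, -1)

    def test_rejects_non_acgt(self):
        ref = ReferenceSequence("r", "ACGT")
        with pytest.raises(ValueError, match="non-ACGT"):
            align_clone(ref, "ACNT")
        with pytest.raises(ValueError, match="non-ACGT"):
            ReferenceSequence("r", "ACNT")


class TestCallSubstitutions:
    def test_matches_positionwise_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            ref_seq = "".join(rng.choice(list("ACGT"), size=50))
            clone = list(ref_seq)
            for pos in rng.choice(50, size=rng.integers(0, 6), replace=False):
                clone[pos] = rng.choice([b for b in "ACGT" if b != clone[pos]])
            clone = "".join(clone)
            ref = ReferenceSequence("r", ref_seq)
            got = [
                (s.ref_position, s.ref_base, s.alt_base)
                for s in call_substitutions(align_clone(ref, clone))
            ]
            assert got == positionwise_substitutions(ref_seq, clone)


class TestClassifyHotspot:
    @pytest.mark.parametrize(
        "seq,pos,label",
        [
            ("TACT", 2, "WRCY"),
            ("AGCT", 1, "RGYW"),
            ("GGCC", 2, "none"),  # G not in W
            ("TACTA", 0, "none"),  # window off the left end
            ("AGCT", 3, "none"),  # window off the right end
        ],
    )
    def test_motif_definition(self, seq, pos, label):
        assert classify_hotspot(ReferenceSequence("r", seq), pos) == label

    def test_position_out_of_range(self):
        ref = ReferenceSequence("r", "TACT")
        with pytest.raises(ValueError, match="out of range"):
            classify_hotspot(ref, 4)

    def test_matches_two_strand_scan_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            ref = ReferenceSequence("r", seq)
            assert hotspot_labels(ref) == hotspot_scan(seq)


class TestSummarize:
    def _alignments(self, ref, clones):
        return [align_clone(ref, c, f"c{i}") for i, c in enumerate(clones)]

    def test_mut_per_bp_arithmetic(self, ref565):
        rng = np.random.default_rng(2)
        clones = []
        total_subs = 0
        for _ in range(30):
            clone = list(ref565.seq)
            k = rng.integers(0, 2)
            for pos in rng.choice(len(clone), size=k, replace=False):
                clone[pos] = [b for b in "ACGT" if b != clone[pos]][0]
            total_subs += k
            clones.append("".join(clone))
        s = summarize_condition(self._alignments(ref565, clones), "cond")
        assert s.total_aligned_bp == 30 * 565
        assert s.n_substitutions == total_subs
        assert s.mut_per_bp == pytest.approx(total_subs / 16950)
        assert s.qc_pass

    def test_qc_fails_below_10kb(self):
        ref = ReferenceSequence("r", "ACGT" * 25)  # 100 bp
        alns = self._alignments(ref, [ref.seq] * 3)
        s = summarize_condition(alns, "tiny")
        assert s.total_aligned_bp == 300
        assert not s.qc_pass

    def test_zero_substitutions_degenerate(self, ref565):
        s = summarize_condition(self._alignments(ref565, [ref565.seq] * 2), "id")
        assert s.mut_per_bp == 0
        assert s.hotspot_fraction is None
        assert s.cg_fraction is None

    def test_mixed_references_rejected(self, ref565):
        other = ReferenceSequence("other", ref565.seq[:-1] + "A")
        alns = [align_clone(ref565, ref565.seq), align_clone(other, other.seq)]
        with pytest.raises(ValueError, match="mix"):
            summarize_condition(alns, "bad")

    def test_adding_clean_clone_never_increases_rate(self, ref565):
        clone = ref565.seq[:100] + ("A" if ref565.seq[100] != "A" else "C") + ref565.seq[101:]
        alns = self._alignments(ref565, [clone])
        before = summarize_condition(alns, "x").mut_per_bp
        alns.append(align_clone(ref565, ref565.seq, "clean"))
        after = summarize_condition(alns, "x").mut_per_bp
        assert after <= before


class TestQCClones:
    def test_short_and_divergent_discarded_duplicates_flagged(self, ref565):
        rng = np.random.default_rng(3)
        good = ref565.seq
        short = ref565.seq[: int(0.5 * len(ref565))]
        noisy = "".join(
            rng.choice([b for b in "ACGT" if b != c]) if rng.random() < 0.2 else c
            for c in ref565.seq
        )
        alns = [
            align_clone(ref565, s, f"c{i}")
            for i, s in enumerate([good, short, noisy, good])
        ]
        kept, flagged = qc_clones(alns)
        assert [a.clone_id for a in kept] == ["c0", "c3"]
        assert ("c1", "short") in flagged
        assert ("c2", "high_mismatch") in flagged
        assert ("c3", "duplicate") in flagged
        kept2, _ = qc_clones(alns, collapse_duplicates=True)
        assert [a.clone_id for a in kept2] == ["c0"]


class TestCompareConditions:
    def _summary(self, n_subs, bp, cond="x"):
        # minimal synthetic summary with the given totals
        spectrum = np.zeros((4, 4), dtype=np.int64)
        spectrum[1, 3] = n_subs  # all C->T
        return shm.MutationSummary(
            condition=cond, total_aligned_bp=bp, n_substitutions=n_subs,
            n_indel_events=0, spectrum=spectrum, n_hotspot=0, n_clones=1,
        )

    def test_rate_ratio_arithmetic(self):
        fc = compare_conditions(self._summary(2, 10_000), self._summary(9, 10_000))
        assert fc.rate_ratio == pytest.approx(4.5)

    def test_exact_two_sided_p_from_binomial_tails(self):
        # central Binomial(11, 1/2): P(X<=2) + P(X>=9) = 134/2048
        fc = compare_conditions(self._summary(2, 10_000), self._summary(9, 10_000))
        assert fc.p_value == pytest.approx(134 / 2048)

    def test_null_identity(self):
        fc = compare_conditions(self._summary(5, 10_000), self._summary(5, 10_000))
        assert fc.rate_ratio == pytest.approx(1.0)
        assert fc.p_value == pytest.approx(1.0)

    def test_ci_contains_point_estimate(self):
        for na, nb in [(2, 9), (1, 20), (10, 10), (0, 4)]:
            fc = compare_conditions(
                self._summary(na, 12_000), self._summary(nb, 9_000)
            )
            assert fc.ci_low <= fc.rate_ratio <= fc.ci_high
            assert 0 < fc.p_value <= 1

    def test_both_zero(self):
        fc = compare_conditions(self._summary(0, 10_000), self._summary(0, 10_000))
        assert fc.p_value == 1.0
        assert np.isnan(fc.rate_ratio)


class TestSpectrum:
    def test_cg_fraction_example(self, ref565):
        # plant C->T, C->T, G->A, A->G
        seq = "ACGTACGTAA"
        ref = ReferenceSequence("r", seq)
        clones = ["ATGTACGTAA", "ATGTACGTAA", "ACATACGTAA", "ACGTGCGTAA"]
        s = summarize_condition(
            [align_clone(ref, c, f"c{i}") for i, c in enumerate(clones)], "x"
        )
        matrix, cg, ts = substitution_spectrum(s)
        assert matrix.sum() == 4
        assert cg == pytest.approx(0.75)
        assert ts == pytest.approx(1.0)  # all four are transitions

    def test_empty_spectrum(self, ref565):
        s = summarize_condition([align_clone(ref565, ref565.seq)], "x")
        matrix, cg, ts = substitution_spectrum(s)
        assert matrix.sum() == 0 and cg is None and ts is None

    def test_row_sums_match_direct_tally(self, ref565):
        rng = np.random.default_rng(8)
        clones = []
        for _ in range(10):
            clone = list(ref565.seq)
            for pos in rng.choice(565, size=3, replace=False):
                clone[pos] = rng.choice([b for b in "ACGT" if b != clone[pos]])
            clones.append("".join(clone))
        s = summarize_condition(
            [align_clone(ref565, c, f"c{i}") for i, c in enumerate(clones)], "x"
        )
        matrix, _, _ = substitution_spectrum(s)
        tally = np.zeros((4, 4), dtype=int)
        idx = {b: i for i, b in enumerate("ACGT")}
        for clone in clones:
            for i, (r, c) in enumerate(zip(ref565.seq, clone)):
                if r != c:
                    tally[idx[r], idx[c]] += 1
        assert (matrix == tally).all()
        assert matrix.sum() == s.n_substitutions


@given(st.integers(0, 2**31 - 1))
def test_hotspot_labels_match_oracle_property(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    assert hotspot_labels(ReferenceSequence("r", seq)) == hotspot_scan(seq)
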