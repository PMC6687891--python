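import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from satmut import annotation_scoring as ann
from satmut.core import TargetElement, Variant, reverse_complement


def brute_force_delta_svm(variant, element, weights, k, lookup_revcomp=True):
    """Independent enumeration of every k-mer overlapping the variant."""

    def lookup(kmer):
        if kmer in weights:
            return weights[kmer]
        if lookup_revcomp:
            return weights.get(reverse_complement(kmer), 0.0)
        return 0.0

    ref_seq = element.sequence
    alt_seq = ref_seq[: variant.position] + variant.alt + ref_seq[variant.position + 1 :]
    ref_vals, alt_vals = [], []
    for start in range(len(ref_seq) - k + 1):
        if start <= variant.position < start + k:
            ref_vals.append(lookup(ref_seq[start : start + k]))
            alt_vals.append(lookup(alt_seq[start : start + k]))
    return float(np.mean(ref_vals) - np.mean(alt_vals))


class TestDeltaSVM:
    def test_all_missing_table_scores_zero(self):
        element = TargetElement("e", "ACGTACGT")
        table = ann.KmerWeightTable({"GGGG": 1.0})
        assert ann.delta_svm_score(Variant(3, "T", "A"), element, table) == 0.0

    def test_toy_hand_computed(self):
        # k=2 table {AC:1, CC:-1}; "AACA" with A>C at position 1:
        # ref 2-mers over pos 1: AA, AC -> mean (0+1)/2 = 0.5
        # alt "ACCA" 2-mers over pos 1: AC, CC -> mean (1-1)/2 = 0
        # score = 0.5 - 0 = 0.5
        element = TargetElement("e", "AACA")
        table = ann.KmerWeightTable({"AC": 1.0, "CC": -1.0}, lookup_revcomp=False)
        score = ann.delta_svm_score(Variant(1, "A", "C"), element, table)
        assert score == pytest.approx(0.5)

    def test_identity_symmetry(self):
        # ref and alt sharing identical overlapping k-mer multisets -> 0
        element = TargetElement("e", "AAAA")
        table = ann.KmerWeightTable({"AA": 2.0, "AT": 2.0, "TA": 2.0})
        # A>T at pos 1 in AAAA: ref {AA,AA}, alt {AT,TA}: all weight 2 -> 0
        assert ann.delta_svm_score(Variant(1, "A", "T"), element, table) == pytest.approx(0.0)

    def test_sign_convention_negates(self):
        element = TargetElement("e", "ACGTACGTAC")
        table = ann.KmerWeightTable({"ACG": 1.5, "CGT": -0.5, "GTA": 0.25})
        v = Variant(4, "A", "G")
        forward = ann.delta_svm_score(v, element, table, sign="ref-minus-alt")
        flipped = ann.delta_svm_score(v, element, table, sign="alt-minus-ref")
        assert flipped == -forward

    def test_deletion_rejected(self):
        element = TargetElement("e", "ACGTACGT")
        table = ann.KmerWeightTable({"AC": 1.0})
        with pytest.raises(ann.UnsupportedVariantError):
            ann.delta_svm_score(Variant(2, "G", ""), element, table)

    def test_random_cases_brute_force(self, rng):
        # 100 random (sequence <= 30 bp, k <= 4) cases vs exhaustive enumeration
        for _ in range(100):
            length = int(rng.integers(8, 31))
            k = int(rng.integers(2, 5))
            seq = "".join(rng.choice(list("ACGT"), length))
            element = TargetElement("e", seq)
            kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
            chosen = rng.choice(kmers, size=min(20, len(kmers)), replace=False)
            weights = {km: float(rng.normal()) for km in chosen}
            table = ann.KmerWeightTable(weights)
            pos = int(rng.integers(length))
            ref = seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            v = Variant(pos, ref, alt)
            assert ann.delta_svm_score(v, element, table) == pytest.approx(
                brute_force_delta_svm(v, element, weights, k)
            )

    def test_revcomp_fallback(self):
        element = TargetElement("e", "AAAA")
        # only the revcomp of AA (TT) present
        table = ann.KmerWeightTable({"TT": 3.0})
        v = Variant(1, "A", "C")
        # ref kmers {AA, AA} -> 3.0 each via revcomp; alt {AC, CA} -> 0
        assert ann.delta_svm_score(v, element, table) == pytest.approx(3.0)


def brute_force_scan(element, pwm):
    out = []
    for start in range(len(element) - len(pwm) + 1):
        window = element.sequence[start : start + len(pwm)]
        out.append((start, "+", pwm.score(window)))
        out.append((start, "-", pwm.score(reverse_complement(window))))
    return out


class TestPWM:
    def _pwm(self, rows, motif_id="m"):
        return ann.PWM(motif_id, np.array(rows, dtype=float))

    def test_best_possible_score(self):
        pwm = self._pwm([[1, 0, 0, 0], [0, 2, 0, 0], [0, 0, 3, 0], [0, 0, 0, 4]])
        assert pwm.best_possible_score == 10

    def test_perfect_match_scores_best(self):
        pwm = self._pwm([[2, -1, -1, -1], [-1, 2, -1, -1], [-1, -1, 2, -1], [-1, -1, -1, 2]])
        element = TargetElement("e", "ACGTAA")
        matches = ann.scan_pwm(element, pwm)
        best = max(matches, key=lambda m: m.raw_score)
        assert (best.start, best.strand) == (0, "+")
        assert best.raw_score == pwm.best_possible_score

    def test_palindromic_motif_strand_symmetry(self):
        # ACGT's revcomp is ACGT: palindromic log-odds columns
        pwm = self._pwm([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])
        element = TargetElement("e", "AACGTACG")
        for start in range(len(element) - 4 + 1):
            fwd = [m for m in ann.scan_pwm(element, pwm) if m.start == start]
            assert fwd[0].raw_score == pytest.approx(fwd[1].raw_score)

    def test_scan_equals_brute_force(self, rng):
        for _ in range(20):
            length = int(rng.integers(6, 50))
            width = int(rng.integers(4, min(8, length) + 1))
            pwm = ann.PWM("m", rng.normal(size=(width, 4)))
            element = TargetElement("e", "".join(rng.choice(list("ACGT"), length)))
            got = [(m.start, m.strand, m.raw_score) for m in ann.scan_pwm(element, pwm)]
            expected = brute_force_scan(element, pwm)
            assert len(got) == len(expected) == 2 * (length - width + 1)
            for g, e in zip(sorted(got), sorted(expected)):
                assert g[:2] == e[:2]
                assert g[2] == pytest.approx(e[2])

    def test_pwm_wider_than_element(self):
        pwm = ann.PWM("m", np.zeros((10, 4)))
        assert ann.scan_pwm(TargetElement("e", "ACGTA"), pwm) == []

    def test_from_counts_log_odds(self):
        counts = np.array([[8, 0, 0, 0], [0, 8, 0, 0], [2, 2, 2, 2], [0, 0, 0, 8]])
        pwm = ann.PWM.from_counts("m", counts, pseudocount=0.8)
        expected_00 = np.log2(((8 + 0.8) / (8 + 3.2)) / 0.25)
        assert pwm.matrix[0, 0] == pytest.approx(expected_00)
        assert pwm.matrix[2].max() == pytest.approx(pwm.matrix[2].min())


class TestPercentiles:
    def _matches(self, scores):
        return [ann.MotifMatch("m", 0, 1, "+", s) for s in scores]

    def test_linear_interpolation_oracle(self):
        thresholds = ann.motif_percentile_thresholds(self._matches([10, 20, 30, 40]), [50])
        assert thresholds[50] == pytest.approx(25.0)

    def test_single_score(self):
        thresholds = ann.motif_percentile_thresholds(self._matches([7.0]), [10, 50, 90])
        assert all(v == pytest.approx(7.0) for v in thresholds.values())

    def test_constant_pool(self):
        thresholds = ann.motif_percentile_thresholds(self._matches([3.0] * 10), [25, 75])
        assert set(thresholds.values()) == {3.0}

    def test_monotone_in_percentile(self, rng):
        matches = self._matches(rng.normal(size=50).tolist())
        ps = [10, 25, 50, 75, 90]
        thresholds = ann.motif_percentile_thresholds(matches, ps)
        values = [thresholds[p] for p in ps]
        assert values == sorted(values)

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            ann.motif_percentile_thresholds([], [50])


class TestOverlapCounting:
    def test_same_motif_both_strands_once(self):
        matches = [
            ann.MotifMatch("m1", 2, 8, "+", 1.0),
            ann.MotifMatch("m1", 3, 9, "-", 1.0),
        ]
        assert ann.count_overlapping_motifs(5, matches) == 1

    def test_no_overlap(self):
        matches = [ann.MotifMatch("m1", 2, 8, "+", 1.0)]
        assert ann.count_overlapping_motifs(10, matches) == 0

    def test_interval_stabbing_oracle(self):
        matches = [
            ann.MotifMatch("m1", 0, 5, "+", 1.0),
            ann.MotifMatch("m1", 4, 9, "-", 1.0),   # merges with previous
            ann.MotifMatch("m2", 3, 7, "+", 1.0),
            ann.MotifMatch("m3", 8, 12, "+", 1.0),
        ]
        # brute force: per position, count distinct motifs with a merged
        # interval covering it
        merged = {"m1": [(0, 9)], "m2": [(3, 7)], "m3": [(8, 12)]}
        for pos in range(13):
            expected = sum(
                1 for ivs in merged.values() for s, e in ivs if s <= pos < e
            )
            assert ann.count_overlapping_motifs(pos, matches) == expected

    def test_unmerged_counts_every_match(self):
        matches = [
            ann.MotifMatch("m1", 0, 5, "+", 1.0),
            ann.MotifMatch("m1", 1, 6, "-", 1.0),
        ]
        assert ann.count_overlapping_motifs(2, matches, merge_same_motif=False) == 2


class TestPwmDelta:
    def test_consensus_creation_gated(self):
        pwm = ann.PWM("m", np.array([[2, -2, -2, -2]] * 4))  # consensus AAAA
        element = TargetElement("e", "TTTTCAAATTTT")
        v = Variant(4, "C", "A")  # creates AAAA at 4..8
        delta, gated = ann.pwm_delta(v, element, pwm)
        assert delta > 0
        assert gated

    def test_low_scoring_not_gated(self):
        pwm = ann.PWM("m", np.array([[5, -5, -5, -5]] * 6))
        element = TargetElement("e", "CCCCCCGGGGGG")
        delta, gated = ann.pwm_delta(Variant(6, "G", "T"), element, pwm)
        assert not gated

    def test_brute_force_enumeration(self, rng):
        for _ in range(20):
            pwm = ann.PWM("m", rng.normal(size=(4, 4)))
            seq = "".join(rng.choice(list("ACGT"), 8))
            element = TargetElement("e", seq)
            pos = int(rng.integers(8))
            ref = seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            v = Variant(pos, ref, alt)
            delta, gated = ann.pwm_delta(v, element, pwm, gate_percentile=0.8)
            alt_seq = v.apply(seq)
            bests = {}
            for name, s in (("ref", seq), ("alt", alt_seq)):
                scores = []
                for start in range(len(s) - 4 + 1):
                    if start <= pos < start + 4:
                        w = s[start : start + 4]
                        scores += [pwm.score(w), pwm.score(reverse_complement(w))]
                bests[name] = max(scores)
            assert delta == pytest.approx(bests["alt"] - bests["ref"])
            assert gated == (max(bests.values()) > 0.8 * pwm.best_possible_score)


class TestTopFactors:
    def _matches(self, counts):
        out = []
        for factor, n in counts.items():
            out += [ann.MotifMatch(f"{factor}.{i}", 0, 5, "+", 1.0, factor=factor)
                    for i in range(n)]
        return out

    def test_three_factors_all_returned(self):
        result = ann.top_factors(self._matches({"A": 3, "B": 2, "C": 1}), top_n=5)
        assert set(result) == {"A", "B", "C"}

    def test_tie_inclusion(self):
        counts = {"A": 5, "B": 5, "C": 4, "D": 4, "E": 3, "F": 3, "G": 2}
        result = ann.top_factors(self._matches(counts), top_n=5)
        assert set(result) == {"A", "B", "C", "D", "E", "F"}

    def test_all_equal_counts(self):
        result = ann.top_factors(self._matches({c: 2 for c in "ABCDEFG"}), top_n=5)
        assert set(result) == set("ABCDEFG")


@settings(max_examples=30)
@given(st.text(alphabet="ACGT", min_size=10, max_size=50), st.integers(0, 1000))
def test_delta_svm_alt_minus_ref_negation_property(seq, salt):
    rng = np.random.default_rng(salt)
    element = TargetElement("e", seq)
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
    weights = {km: float(rng.normal()) for km in rng.choice(kmers, 10, replace=False)}
    table = ann.KmerWeightTable(weights)
    pos = int(rng.integers(len(seq)))
    ref = seq[pos]
    alt = rng.choice([b for b in "ACGT" if b != ref])
    v = Variant(pos, ref, alt)
    a = ann.delta_svm_score(v, element, table, sign="ref-minus-alt")
    b = ann.delta_svm_score(v, element, table, sign="alt-minus-ref")
    assert a == -b


def test_read_jaspar(tmp_path):
    pfm = tmp_path / "motifs.jaspar"
    pfm.write_text(
        ">MA0001.1 FACTOR1\n"
        "A [ 8 0 2 0 ]\n"
        "C [ 0 8 2 0 ]\n"
        "G [ 0 0 2 8 ]\n"
        "T [ 0 0 2 0 ]\n"
    )
    pwms = ann.read_jaspar_pwms(pfm)
    assert len(pwms) == 1
    assert len(pwms[0]) == 4
    assert pwms[0].factor == "FACTOR1"
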