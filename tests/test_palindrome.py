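"""Self-comparison, palindrome calls, similarity bins and unit orthology."""

import numpy as np
import pytest

from conftest import mutate, random_dna
from palevol.errors import ParameterError
from palevol.palindrome import (
    DuplicatedUnit,
    bin_similarity,
    detect_palindromes,
    self_compare,
    unit_orthology_scores,
)
from palevol.seqmodel import Interval, NucSequence, reverse_complement


class TestSelfCompare:
    def test_perfect_inverted_repeat(self, rng):
        u = random_dna(rng, 5000)
        seq = NucSequence("p", u + reverse_complement(u))
        segs = self_compare(seq, k=12, min_segment=300)
        inv = [m for m in segs if m.orientation == "inverted"]
        assert len(inv) == 1
        m = inv[0]
        assert m.identity == 1.0
        assert m.query.start == 0 and m.subject.end == 10000
        # both halves covered up to the k-sized center overlap
        assert m.query.end >= 5000 and m.subject.start <= 5000

    def test_tandem_duplicate_direct(self, rng):
        u = random_dna(rng, 4000)
        seq = NucSequence("t", u + u)
        segs = self_compare(seq, k=12, min_segment=300)
        direct = [m for m in segs if m.orientation == "direct"]
        assert len(direct) == 1
        assert direct[0].query.start == 0 and direct[0].subject.end == 8000

    def test_random_sequence_no_segments(self, rng):
        for seed in range(10):
            seq = NucSequence("r", random_dna(np.random.default_rng(seed), 20000))
            assert self_compare(seq, k=12, min_segment=300) == []

    def test_revcomp_preserves_segment_count(self, rng):
        u = random_dna(rng, 3000)
        s = u + random_dna(rng, 1000) + reverse_complement(mutate(u, 0.01, rng))
        fwd = self_compare(NucSequence("s", s), k=12, min_segment=300)
        rev = self_compare(NucSequence("s_rc", reverse_complement(s)), k=12, min_segment=300)
        assert len(fwd) == len(rev)
        assert sum(m.orientation == "inverted" for m in fwd) == sum(
            m.orientation == "inverted" for m in rev
        )

    def test_small_k_rejected(self, rng):
        with pytest.raises(ParameterError):
            self_compare(NucSequence("x", random_dna(rng, 100)), k=4)


class TestBinSimilarity:
    @pytest.mark.parametrize(
        "identity,color",
        [
            (0.96, "red"),
            (0.951, "red"),
            (0.95, "orange"),
            (0.92, "orange"),
            (0.901, "orange"),
            (0.90, "green"),
            (0.86, "green"),
            (0.85, "blue"),
            (0.2, "blue"),
        ],
    )
    def test_bins(self, identity, color):
        assert bin_similarity(identity) == color

    def test_out_of_range(self):
        with pytest.raises(ParameterError):
            bin_similarity(1.2)


class TestDetectPalindromes:
    def test_planted_palindrome_with_mutations(self, rng):
        arm = random_dna(rng, 10000)
        loop = random_dna(rng, 2000)
        arm2 = mutate(arm, 0.01, rng)
        seq = NucSequence("pal", arm + loop + reverse_complement(arm2))
        segs = self_compare(seq, k=12, min_segment=300)
        calls = detect_palindromes(segs, seq, min_arm=5000)
        assert len(calls) == 1
        c = calls[0]
        k = 12
        assert abs(c.arm1.start - 0) <= k and abs(c.arm1.end - 10000) <= k
        assert abs(c.arm2.start - 12000) <= k and abs(c.arm2.end - 22000) <= k
        assert 0.985 <= c.arm_identity <= 0.995
        assert c.loop is not None and len(c.loop) == pytest.approx(2000, abs=2 * k)

    def test_decayed_arm_with_deletion(self, rng):
        # one arm lost an interior 6 kb: the call reports the shortened
        # overlapping span (short stem, large loop)
        arm = random_dna(rng, 10000)
        arm2 = mutate(arm, 0.005, rng)
        decayed = arm2[:2000] + arm2[8000:]  # 6 kb interior deletion
        seq = NucSequence("dec", arm + random_dna(rng, 2000) + reverse_complement(decayed))
        segs = self_compare(seq, k=12, min_segment=300)
        calls = detect_palindromes(segs, seq, min_arm=1000, min_identity=0.5)
        assert len(calls) >= 1
        assert max(len(c.arm2) for c in calls) <= 4500

    def test_direct_only_no_calls(self, rng):
        u = random_dna(rng, 5000)
        seq = NucSequence("t", u + u)
        segs = self_compare(seq, k=12, min_segment=300)
        assert detect_palindromes(segs, seq) == []

    def test_revcomp_mirror_calls(self, rng):
        arm = random_dna(rng, 8000)
        seq_s = arm + random_dna(rng, 1500) + reverse_complement(mutate(arm, 0.01, rng))
        L = len(seq_s)
        fwd_seq = NucSequence("f", seq_s)
        rev_seq = NucSequence("r", reverse_complement(seq_s))
        fwd = detect_palindromes(self_compare(fwd_seq, 12, 300), fwd_seq, min_arm=4000)
        rev = detect_palindromes(self_compare(rev_seq, 12, 300), rev_seq, min_arm=4000)
        assert len(fwd) == len(rev) == 1
        f, r = fwd[0], rev[0]
        assert abs((L - r.arm2.end) - f.arm1.start) <= 24
        assert abs((L - r.arm1.start) - f.arm2.end) <= 24

    def test_planted_recovery_across_seeds(self):
        # arms 5-20 kb, identity 0.95-1.0: recall and boundary accuracy
        k = 12
        hits = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            arm_len = int(rng.integers(5000, 20001))
            div = rng.uniform(0.0, 0.05)
            arm = random_dna(rng, arm_len)
            seq = NucSequence(
                "p", arm + random_dna(rng, 2000) + reverse_complement(mutate(arm, div, rng))
            )
            calls = detect_palindromes(
                self_compare(seq, k=k, min_segment=300), seq, min_arm=4000, min_identity=0.9
            )
            if len(calls) == 1 and abs(calls[0].arm1.end - arm_len) <= 2 * k:
                hits += 1
        assert hits >= 15 * 0.95 - 1e-9


class TestUnitOrthology:
    def unit(self, label, markers, pos=0):
        return DuplicatedUnit(Interval("s", pos, pos + 10), label, frozenset(markers))

    def test_identical_sets_paired(self):
        res = unit_orthology_scores(
            [self.unit("h1", "abc")], [self.unit("m1", "abc")]
        )
        assert res.pairs == [("h1", "m1", 1.0)]

    def test_dominant_overlap_assigned(self):
        a = [self.unit("x", "abcdefgh")]
        b = [
            self.unit("y", "abcdefzz", 0),
            self.unit("w", "ab", 10),
            self.unit("v", "zzz", 20),
        ]
        res = unit_orthology_scores(a, b)
        assert res.pairs[0][:2] == ("x", "y")

    def test_disjoint_sets_all_flagged_unassigned(self):
        a = [self.unit("h1", "ab"), self.unit("h2", "")]
        b = [self.unit("m1", "xy")]
        res = unit_orthology_scores(a, b)
        assert res.pairs == []
        assert res.unassigned_a == ["h1", "h2"] and res.unassigned_b == ["m1"]
        assert res.flagged_empty == ["h2"]

    def test_one_to_one_greedy(self):
        a = [self.unit("h1", "abcd"), self.unit("h2", "abce")]
        b = [self.unit("m1", "abcd"), self.unit("m2", "abce")]
        res = unit_orthology_scores(a, b)
        assert ("h1", "m1", 1.0) in res.pairs and ("h2", "m2", 1.0) in res.pairs
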