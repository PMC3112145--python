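"""Codon-level divergence: p-distance, Nei-Gojobori, CpG masking, tests."""

import itertools
import math

import numpy as np
import pytest
from Bio.Data import CodonTable

from palevol.divergence import (
    CodonAlignment,
    CorrectionUndefinedError,
    count_amino_acid_changes,
    dnds_z_test,
    flag_cpg_codons,
    nei_gojobori,
    ng_excluding_cpg,
    p_distance,
    region_rate_compare,
)
from palevol.errors import NoDataError, ParameterError
from palevol.seqmodel import Interval, PairwiseAlignment

# ---------------------------------------------------------------------------
# Independent oracle: exhaustive pathway enumeration with Biopython's table.

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODE = dict(_TABLE.forward_table)
for c in _TABLE.stop_codons:
    _CODE[c] = "*"


def oracle_syn_sites(codon):
    aa = _CODE[codon]
    n_syn = 0
    for pos, b in itertools.product(range(3), "ACGT"):
        if b == codon[pos]:
            continue
        if _CODE[codon[:pos] + b + codon[pos + 1 :]] == aa:
            n_syn += 1
    return n_syn / 3.0


def oracle_diffs(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODE[nxt] == "*" and nxt != c2:
                blocked = True
            sd += _CODE[nxt] == _CODE[cur]
            nd += _CODE[nxt] != _CODE[cur]
            cur = nxt
        paths.append((blocked, sd, nd))
    ok = [(s, n) for b, s, n in paths if not b] or [(s, n) for _, s, n in paths]
    return sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok)


def oracle_ng(codons_a, codons_b):
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if _CODE[ca] == "*" or _CODE[cb] == "*":
            continue
        s = (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2.0
        sd, nd = oracle_diffs(ca, cb)
        S += s
        N += 3.0 - s
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def random_codons(rng, n):
    bases = "ACGT"
    out = []
    while len(out) < n:
        c = "".join(rng.choice(list(bases), 3))
        if _CODE[c] != "*":
            out.append(c)
    return out


# ---------------------------------------------------------------------------


class TestPDistance:
    def test_simple_mismatch(self):
        r = p_distance(PairwiseAlignment("a", "b", "ACGTACGT", "ACGTACGA"))
        assert r.p == 0.125 and r.n_sites == 8

    def test_pairwise_deletion(self):
        r = p_distance(PairwiseAlignment("a", "b", "AC-T", "ACGT"))
        assert r.p == 0.0 and r.n_sites == 3

    def test_se_matches_binomial_form(self):
        # 20 mismatches over 2880 sites: p=0.00694, se ~ 0.00155 (reported
        # in "0.7% (+/-0.2)" style for duplicated-unit comparisons)
        p, n = 20 / 2880, 2880
        a = "A" * 2880
        b = "G" * 20 + "A" * 2860
        r = p_distance(PairwiseAlignment("a", "b", a, b))
        assert r.p == pytest.approx(p)
        assert r.se == pytest.approx(math.sqrt(p * (1 - p) / n))
        assert r.se == pytest.approx(0.00155, abs=5e-5)

    def test_symmetry_and_identity(self, pair_factory):
        aln = pair_factory(600, 0.1)
        fwd = p_distance(aln)
        rev = p_distance(PairwiseAlignment("b", "a", aln.seq_b, aln.seq_a))
        assert fwd.p == rev.p
        assert p_distance(PairwiseAlignment("a", "a", aln.seq_a, aln.seq_a)).p == 0.0

    def test_n_treated_as_missing(self):
        r = p_distance(PairwiseAlignment("a", "b", "ANGT", "AAGT"))
        assert r.n_sites == 3 and r.p == 0.0

    def test_no_data(self):
        with pytest.raises(NoDataError):
            p_distance(PairwiseAlignment("a", "b", "NN", "AA"))


class TestNeiGojobori:
    def test_glycine_synonymous_change(self):
        ng = nei_gojobori(CodonAlignment.from_ungapped(["x", "y"], ["GGGGGG", "GGAGGG"]))
        assert (ng.S, ng.N, ng.Sd, ng.Nd) == (2.0, 4.0, 1.0, 0.0)
        assert ng.pS == 0.5 and ng.pN == 0.0

    def test_met_to_ile_nonsynonymous(self):
        ng = nei_gojobori(CodonAlignment.from_ungapped(["x", "y"], ["ATG", "ATA"]))
        assert ng.S == pytest.approx(1 / 3)
        assert ng.N == pytest.approx(8 / 3)
        assert ng.Nd == 1.0 and ng.pN == pytest.approx(0.375) and ng.pS == 0.0

    def test_identical_rows(self):
        ng = nei_gojobori(CodonAlignment.from_ungapped(["x", "y"], ["ATGGCT", "ATGGCT"]))
        assert ng.Sd == ng.Nd == 0.0 and ng.pS == ng.pN == 0.0

    def test_site_count_conservation(self, rng):
        a = random_codons(rng, 40)
        b = random_codons(rng, 40)
        ng = nei_gojobori(CodonAlignment.from_ungapped(["a", "b"], ["".join(a), "".join(b)]))
        assert ng.S + ng.N == pytest.approx(3 * ng.n_codons_compared)

    def test_matches_oracle_on_random_alignments(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 6))
            a, b = random_codons(rng, n), random_codons(rng, n)
            ng = nei_gojobori(CodonAlignment.from_ungapped(["a", "b"], ["".join(a), "".join(b)]))
            S, N, Sd, Nd = oracle_ng(a, b)
            assert ng.S == pytest.approx(S) and ng.N == pytest.approx(N)
            assert ng.Sd == pytest.approx(Sd) and ng.Nd == pytest.approx(Nd)

    def test_jc_correction_undefined(self):
        # pS = 1 on a fully synonymous-divergent alignment
        aln = CodonAlignment.from_ungapped(["a", "b"], ["GGG" * 4, "GGA" * 4])
        with pytest.raises(CorrectionUndefinedError):
            nei_gojobori(aln, correction="jukes_cantor")

    def test_gapped_codons_skipped(self):
        aln = CodonAlignment(["a", "b"], ["GGG---", "GGAGGG"])
        ng = nei_gojobori(aln)
        assert ng.n_codons_compared == 1 and ng.Sd == 1.0


class TestCpGFlags:
    def test_within_codon_rule(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ACGGGG", "ACGGGG"])
        flags, n = flag_cpg_codons(aln, "within_codon")
        assert list(flags) == [True, False] and n == 1

    def test_spanning_rule_flags_both_sides(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["AACGTT", "AACGTT"])
        flags_w, n_w = flag_cpg_codons(aln, "within_codon")
        flags_s, n_s = flag_cpg_codons(aln, "spanning")
        assert n_w == 0
        assert list(flags_s) == [True, True] and n_s == 2

    def test_any_row_flags(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["AAAAAA", "ACGAAA"])
        flags, n = flag_cpg_codons(aln, "spanning")
        assert list(flags) == [True, False]

    def test_exclusion_identity_when_no_flags(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ATTGAT", "ATAGAT"])
        assert flag_cpg_codons(aln, "spanning")[1] == 0
        ng_a = nei_gojobori(aln)
        ng_b = ng_excluding_cpg(aln)
        assert (ng_a.S, ng_a.N, ng_a.Sd, ng_a.Nd) == (ng_b.S, ng_b.N, ng_b.Sd, ng_b.Nd)

    def test_all_differences_in_flagged_codons(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ACGAAA", "ACAAAA"])
        ng = ng_excluding_cpg(aln)
        assert ng.pS == ng.pN == 0.0

    def test_all_flagged_raises(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ACG", "ACG"])
        with pytest.raises(NoDataError):
            ng_excluding_cpg(aln)


class TestDnDsTest:
    def test_identical_inputs_give_z_zero(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ATGGCT" * 20, "ATGGCT" * 20])
        ng = nei_gojobori(aln, bootstrap_reps=100, seed=0)
        t = dnds_z_test(ng)
        assert t.z == 0.0 and t.p_two_sided == 1.0

    def test_needs_bootstrap(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ATGGCT", "ATGGCT"])
        with pytest.raises(NoDataError):
            dnds_z_test(nei_gojobori(aln))

    def test_purifying_selection_detected(self):
        # omega = 0.2, 500 codons: the test should reject dN = dS in most
        # seeded replicates (power check; the full-size suite lives in the
        # acceptance tests)
        from palevol.synthetic import simulate_cds_pair

        hits = 0
        for seed in range(20):
            sa, sb, _ = simulate_cds_pair(500, t=0.15, omega=0.2, cpg_mult=1.0, seed=seed)
            aln = CodonAlignment.from_ungapped(["a", "b"], [sa.residues, sb.residues])
            ng = nei_gojobori(aln, bootstrap_reps=400, seed=seed)
            hits += dnds_z_test(ng).p_two_sided < 0.05
        assert hits >= 16

    def test_ratio_undefined_when_ds_zero(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ATGGCT" * 5, "ATGGCG" * 5])
        ng = nei_gojobori(aln, bootstrap_reps=100, seed=0)
        t = dnds_z_test(ng)
        # dS > 0 here (GCT->GCG is synonymous); build a true dS=0 case
        aln2 = CodonAlignment.from_ungapped(["a", "b"], ["ATGATG", "ATGCTG"])
        ng2 = nei_gojobori(aln2, bootstrap_reps=100, seed=0)
        t2 = dnds_z_test(ng2)
        assert t2.dn_ds_ratio is None and np.isfinite(t2.p_two_sided)


class TestRegionRateCompare:
    def test_whole_cds_region_rejected(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ATGGCT", "ATGGCT"])
        with pytest.raises(ParameterError):
            region_rate_compare(aln, 0, 1, Interval("cds", 0, 6))

    def test_planted_elevated_region_detected(self, rng):
        # inside region: heavy nonsynonymous divergence; outside: none
        inside_a, inside_b = [], []
        for _ in range(60):
            inside_a.append("ATG")
            inside_b.append("CTG" if rng.random() < 0.5 else "ATG")
        outside = ["GCT"] * 140
        a = "".join(inside_a + outside)
        b = "".join(inside_b + outside)
        aln = CodonAlignment.from_ungapped(["a", "b"], [a, b])
        rep = region_rate_compare(aln, 0, 1, Interval("cds", 0, 180), metric="nonsyn")
        assert rep.rate_in > rep.rate_out and rep.p_value < 0.01

    def test_null_calibration_light(self, rng):
        # same single-site substitution process inside and outside the
        # region: Fisher p should reject at no more than ~2x nominal
        from conftest import mutate

        rejections = 0
        for _ in range(100):
            a = "".join(random_codons(rng, 120))
            b = mutate(a, 0.05, rng)  # stop codons are skipped by the estimator
            aln = CodonAlignment.from_ungapped(["a", "b"], [a, b])
            rep = region_rate_compare(aln, 0, 1, Interval("cds", 0, 180))
            rejections += rep.p_value < 0.05
        assert rejections <= 10


class TestAminoAcidChanges:
    def test_identical(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ATGGCT", "ATGGCT"])
        assert count_amino_acid_changes(aln) == (0, 0)

    def test_single_change_in_region(self):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["ATGGCT", "ATGGAT"])
        assert count_amino_acid_changes(aln, region=Interval("cds", 3, 6)) == (1, 1)

    def test_thirteen_changes_ten_in_epitope_region(self):
        # mirror of two near-identical paralogs: 13 amino-acid changes, 10
        # concentrated in a marked 5' region
        n = 100
        a = ["GCT"] * n
        b = list(a)
        region = Interval("cds", 0, 90)  # codons 0..29
        for j in range(10):
            b[j] = "GTT"      # Ala -> Val inside the region
        for j in (40, 60, 80):
            b[j] = "ACT"      # Ala -> Thr outside
        aln = CodonAlignment.from_ungapped(["a", "b"], ["".join(a), "".join(b)])
        assert count_amino_acid_changes(aln, region=region) == (13, 10)

    def test_stop_codon_skipped_with_warning(self, caplog):
        aln = CodonAlignment.from_ungapped(["a", "b"], ["TGAGCT", "TGGGCT"])
        with caplog.at_level("WARNING"):
            total, _ = count_amino_acid_changes(aln)
        assert total == 0 and "stop" in caplog.text
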