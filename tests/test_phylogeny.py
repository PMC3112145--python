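"""Neighbor joining, bootstrap support and outgroup rooting."""

import numpy as np
import pytest

from palevol.errors import NoDataError, ParameterError
from palevol.phylogeny import (
    DistanceMatrix,
    PhyloTree,
    bootstrap_support,
    build_distance_matrix,
    nj_tree,
    root_with_outgroup,
)
from palevol.synthetic import simulate_family_alignment


def random_additive_matrix(rng, n):
    """Path-length matrix of a random binary tree with positive branches."""
    labels = [f"t{i}" for i in range(n)]
    D = {a: {} for a in labels}
    clusters = {lab: {lab: 0.0} for lab in labels}
    while len(clusters) > 1:
        keys = sorted(clusters)
        i, j = rng.choice(len(keys), 2, replace=False)
        ka, kb = keys[i], keys[j]
        la, lb = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        for ma, da in clusters[ka].items():
            for mb, db in clusters[kb].items():
                D[ma][mb] = D[mb][ma] = da + la + db + lb
        merged = {m: d + la for m, d in clusters[ka].items()}
        merged.update({m: d + lb for m, d in clusters[kb].items()})
        del clusters[ka], clusters[kb]
        clusters[f"c{len(clusters)}"] = merged
    mat = np.array([[D[a].get(b, 0.0) for b in labels] for a in labels])
    return DistanceMatrix(labels, mat)


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(ParameterError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_tsv_round_trip(self, tmp_path, rng):
        dm = random_additive_matrix(rng, 5)
        p = tmp_path / "dm.tsv"
        dm.to_tsv(p)
        back = DistanceMatrix.from_tsv(p)
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.d, dm.d, rtol=1e-9)

    def test_from_alignment_complete_deletion(self):
        dm = build_distance_matrix(["a", "b", "c"], ["ACGT", "AC-T", "GCGT"], "complete")
        # column 2 dropped (gap in b): 3 comparable columns
        assert dm.d[0, 2] == pytest.approx(1 / 3)
        assert dm.d[0, 1] == 0.0


class TestNJ:
    def test_three_point_formulas(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        )
        tree = nj_tree(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.1)
        assert lengths["C"] == pytest.approx(0.3)

    def test_exact_on_additive_matrices(self, rng):
        for _ in range(20):
            dm = random_additive_matrix(rng, int(rng.integers(5, 9)))
            tree = nj_tree(dm)
            ld = tree.leaf_distances()
            order = [ld.labels.index(l) for l in dm.labels]
            np.testing.assert_allclose(ld.d[np.ix_(order, order)], dm.d, atol=1e-9)

    def test_matches_independent_nj_topology(self, rng):
        # cross-check against scikit-bio's neighbor joining on the same matrix
        import skbio

        for seed in range(5):
            dm = random_additive_matrix(np.random.default_rng(seed), 7)
            ours = nj_tree(dm)
            sk = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.labels))
            sk_tree = PhyloTree.from_newick(str(sk).strip())
            assert ours.bipartitions() == sk_tree.bipartitions()

    def test_star_matrix_total_length(self):
        dm = DistanceMatrix(["a", "b", "c", "d"], np.full((4, 4), 0.5) - 0.5 * np.eye(4))
        tree = nj_tree(dm)
        total = sum(
            n.edge.length or 0.0
            for n in tree.tree.preorder_node_iter()
            if n is not tree.tree.seed_node
        )
        assert total == pytest.approx(1.0)  # 4 pendant branches of 0.25

    def test_too_few_taxa(self):
        with pytest.raises(ParameterError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_newick_round_trip(self, rng):
        tree = nj_tree(random_additive_matrix(rng, 6))
        back = PhyloTree.from_newick(tree.newick())
        assert back.bipartitions() == tree.bipartitions()


class TestBootstrap:
    def test_two_clean_clades_full_support(self):
        aln = {
            "a1": "A" * 100 + "C" * 100,
            "a2": "A" * 100 + "C" * 100,
            "b1": "G" * 100 + "T" * 100,
            "b2": "G" * 100 + "T" * 100,
        }
        tree = bootstrap_support(aln, n_reps=100, seed=0)
        assert set(tree.supports.values()) == {100.0}

    def test_random_sequences_low_support(self, rng):
        ids = [f"s{i}" for i in range(8)]
        aln = {i: "".join(rng.choice(list("ACGT"), 300)) for i in ids}
        tree = bootstrap_support(aln, n_reps=100, seed=1)
        assert np.median(list(tree.supports.values())) < 70

    def test_deterministic_given_seed(self, rng):
        ids = [f"s{i}" for i in range(6)]
        aln = {i: "".join(rng.choice(list("ACGT"), 200)) for i in ids}
        t1 = bootstrap_support(aln, n_reps=50, seed=42)
        t2 = bootstrap_support(aln, n_reps=50, seed=42)
        assert t1.supports == t2.supports

    def test_taxon_order_invariance(self, rng):
        ids = [f"s{i}" for i in range(5)]
        aln = {i: "".join(rng.choice(list("ACGT"), 200)) for i in ids}
        t1 = bootstrap_support(dict(sorted(aln.items())), n_reps=50, seed=7)
        t2 = bootstrap_support(dict(sorted(aln.items(), reverse=True)), n_reps=50, seed=7)
        assert set(t1.supports) == set(t2.supports)

    def test_topology_recovery_long_internal_branch(self):
        truth = PhyloTree.from_newick("((A:0.05,B:0.05):0.3,(C:0.05,D:0.05):0.3);")
        hits = 0
        for seed in range(20):
            aln, _ = simulate_family_alignment(truth, n_sites=2000, seed=seed)
            dm = build_distance_matrix(list(aln), list(aln.values()), "complete")
            tree = nj_tree(dm)
            hits += frozenset({"C", "D"}) in tree.bipartitions() or frozenset(
                {"A", "B"}
            ) in tree.bipartitions()
        assert hits >= 19


class TestRooting:
    def test_outgroup_alone_on_one_side(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.2, 0.9], [0.2, 0, 0.9], [0.9, 0.9, 0]])
        )
        rooted = root_with_outgroup(nj_tree(dm), "C")
        children = rooted.tree.seed_node.child_nodes()
        sides = [{lf.taxon.label for lf in c.leaf_iter()} for c in children]
        assert {"C"} in sides

    def test_rooting_preserves_bipartitions(self, rng):
        tree = nj_tree(random_additive_matrix(rng, 6))
        rooted = root_with_outgroup(tree, "t0")
        assert rooted.bipartitions() == tree.bipartitions()

    def test_missing_outgroup(self, rng):
        tree = nj_tree(random_additive_matrix(rng, 5))
        with pytest.raises(ParameterError):
            root_with_outgroup(tree, "nope")

    def test_ingroup_monophyly_preserved(self):
        truth = PhyloTree.from_newick("(((A:0.1,B:0.1):0.1,C:0.2):0.3,OUT:0.8);")
        aln, _ = simulate_family_alignment(truth, n_sites=3000, seed=5)
        tree = nj_tree(build_distance_matrix(list(aln), list(aln.values())))
        rooted = root_with_outgroup(tree, "OUT")
        children = rooted.tree.seed_node.child_nodes()
        sides = [{lf.taxon.label for lf in c.leaf_iter()} for c in children]
        assert {"A", "B", "C"} in sides
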