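import numpy as np
import pytest

from prodomainkit.seqio import Alignment
from prodomainkit.trees import (
    DistanceMatrix,
    TreeError,
    bootstrap_support,
    clade_query,
    compare_partitions,
    distance_matrix,
    from_newick,
    nj,
    robinson_foulds,
    root_with_outgroup,
    significance_threshold,
    to_newick,
)


def _leafset(tree):
    return {l.taxon.label for l in tree.leaf_node_iter()}


def _path_lengths(tree):
    """Leaf-pair path-length matrix from a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            out[(a.label, b.label)] = pdm.distance(a, b)
    return out


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b", "c"], ["MKWV", "MKWV", "MKWV"])
        dm = distance_matrix(aln)
        assert np.allclose(dm.matrix, 0.0)

    def test_p_distance_counts_mismatches(self):
        aln = Alignment(["a", "b", "c"], ["AAAA", "AAAT", "TTTT"])
        dm = distance_matrix(aln, "p_distance")
        assert dm.matrix[0, 1] == pytest.approx(0.25)
        assert dm.matrix[0, 2] == pytest.approx(1.0)

    def test_pairwise_deletion_ignores_gapped_columns(self):
        aln = Alignment(["a", "b", "c"], ["AA-A", "AAAT", "AATT"])
        dm = distance_matrix(aln)
        # a vs b over cols 1,2,4: one mismatch of three
        assert dm.matrix[0, 1] == pytest.approx(1 / 3)

    def test_zero_shared_columns_is_error(self):
        aln = Alignment(["a", "b", "c"], ["A--", "-A-", "AA-"])
        with pytest.raises(TreeError, match="share no"):
            distance_matrix(aln)

    def test_blosum_scoredist_zero_for_self_and_positive_otherwise(self):
        aln = Alignment(["a", "b", "c"], ["MKWV", "MKWV", "ACDE"])
        dm = distance_matrix(aln, "blosum_scoredist")
        assert dm.matrix[0, 1] == pytest.approx(0.0)
        assert dm.matrix[0, 2] > 0

    def test_symmetry_validation(self):
        with pytest.raises(TreeError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


ADDITIVE = DistanceMatrix(
    ["A", "B", "C", "D"],
    np.array([
        [0, 3, 5, 3],
        [3, 0, 6, 4],
        [5, 6, 0, 4],
        [3, 4, 4, 0],
    ], dtype=float),
)


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_four_taxon_topology_and_path_lengths(self):
        """NJ on an additive matrix returns the generating topology (AB|CD)
        and path lengths reproduce every pairwise distance."""
        tree = nj(ADDITIVE)
        paths = _path_lengths(tree)
        for (a, b), d in paths.items():
            i, j = ADDITIVE.ids.index(a), ADDITIVE.ids.index(b)
            assert d == pytest.approx(ADDITIVE.matrix[i, j])
        rooted = root_with_outgroup(tree, "D")
        assert clade_query(rooted, ["A", "B"])["present_as_clade"]

    def test_agrees_with_independent_nj_implementation(self):
        """Cross-check against scikit-bio's neighbor joining on a random
        perturbed matrix (topology comparison via RF distance)."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(42)
        n = 7
        base = rng.uniform(0.2, 1.0, size=(n, n))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 0.0)
        ids = [f"t{i}" for i in range(n)]
        import io

        ours = nj(DistanceMatrix(ids, mat))
        buf = io.StringIO()
        skbio_nj(SkbioDM(mat, ids)).write(buf)
        assert robinson_foulds(ours, from_newick(buf.getvalue())) == 0

    def test_duplicate_taxa_are_siblings(self):
        dm = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array([[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], float),
        )
        rooted = root_with_outgroup(nj(dm), "D")
        assert clade_query(rooted, ["A", "B"])["present_as_clade"]

    def test_too_few_taxa(self):
        with pytest.raises(TreeError):
            nj(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


class TestBootstrap:
    def _aln(self):
        rows = {
            "a": "AAAAAAAAWWWWWWWW",
            "b": "AAAAAAAAWWWWWWWW",
            "c": "TTTTTTTTGGGGGGGG",
            "d": "TTTTTTTTGGGGGGGG",
            "e": "AATTAATTWGWGWGWG",
        }
        return Alignment(list(rows), list(rows.values()))

    def test_same_seed_reproducible(self):
        t1 = bootstrap_support(self._aln(), n_reps=25, seed=5)
        t2 = bootstrap_support(self._aln(), n_reps=25, seed=5)
        assert to_newick(t1) == to_newick(t2)

    def test_deep_split_gets_high_support(self):
        tree = bootstrap_support(self._aln(), n_reps=100, seed=1)
        rooted = root_with_outgroup(tree, "e")
        q = clade_query(rooted, ["a", "b"])
        assert q["present_as_clade"] and q["support"] >= 0.95

    def test_supports_in_unit_interval(self):
        tree = bootstrap_support(self._aln(), n_reps=50, seed=2)
        for node in tree.preorder_node_iter():
            sup = getattr(node, "support", None)
            if sup is not None:
                assert 0.0 <= sup <= 1.0

    def test_zero_replicates_is_error(self):
        with pytest.raises(TreeError):
            bootstrap_support(self._aln(), n_reps=0, seed=0)


class TestRooting:
    def test_three_leaf_rooting(self):
        tree = nj(DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        ))
        rooted = root_with_outgroup(tree, "C")
        children = rooted.seed_node.child_nodes()
        labels = [c.taxon.label if c.taxon else None for c in children]
        assert "C" in labels
        assert clade_query(rooted, ["A", "B"])["present_as_clade"]

    def test_rerooting_same_taxon_is_stable(self):
        tree = nj(ADDITIVE)
        r1 = root_with_outgroup(tree, "D")
        r2 = root_with_outgroup(r1, "D")
        assert robinson_foulds(r1, r2) == 0

    def test_absent_taxon_is_error(self):
        with pytest.raises(TreeError):
            root_with_outgroup(nj(ADDITIVE), "ZZ")


class TestSignificanceThreshold:
    @pytest.mark.parametrize("n,expected", [
        (185, 0.95), (151, 0.95),
        (120, 0.85), (101, 0.85),
        (75, 0.65), (51, 0.65),
        (30, 0.50), (26, 0.50), (25, 0.50),
    ])
    def test_band_lookup(self, n, expected):
        assert significance_threshold(n) == expected

    @pytest.mark.parametrize("n,expected", [(150, 0.85), (100, 0.65), (50, 0.50)])
    def test_boundaries_take_lenient_band(self, n, expected):
        assert significance_threshold(n) == expected

    def test_below_25_is_error(self):
        with pytest.raises(TreeError, match="insufficient"):
            significance_threshold(24)

    def test_monotone_nondecreasing(self):
        vals = [significance_threshold(n) for n in range(25, 300)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestNewickRoundtrip:
    def test_topology_lengths_supports_preserved(self):
        tree = nj(ADDITIVE)
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.parent_node is not None:
                node.support = 0.87
        back = from_newick(to_newick(tree))
        assert robinson_foulds(tree, back) == 0
        sups = [getattr(n, "support", None) for n in back.preorder_node_iter()
                if not n.is_leaf() and n.parent_node is not None]
        assert 0.87 in sups
        orig = sorted(l.edge.length for l in tree.leaf_node_iter())
        got = sorted(l.edge.length for l in back.leaf_node_iter())
        assert got == pytest.approx(orig, abs=1e-6)


class TestCladeAndComparison:
    def test_singleton_convention(self):
        rooted = root_with_outgroup(nj(ADDITIVE), "D")
        assert clade_query(rooted, ["A"]) == {
            "present_as_clade": True, "support": 1.0
        }

    def test_unknown_taxon_is_error(self):
        rooted = root_with_outgroup(nj(ADDITIVE), "D")
        with pytest.raises(TreeError):
            clade_query(rooted, ["A", "ZZ"])

    def test_identical_trees_yield_no_prodomain_only_flags(self):
        rooted = root_with_outgroup(nj(ADDITIVE), "D")
        trees = {p: rooted for p in ("prodomain", "ligand", "full_length")}
        cmp_ = compare_partitions(trees, {"ab": ["A", "B"]})
        assert cmp_.table["ab"]["prodomain"]["present_as_clade"]
        assert cmp_.prodomain_only == []

    def test_leafset_mismatch_is_error(self):
        r1 = root_with_outgroup(nj(ADDITIVE), "D")
        dm = DistanceMatrix(["A", "B", "X"],
                            np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], float))
        r2 = root_with_outgroup(nj(dm), "X")
        with pytest.raises(TreeError, match="leaf set"):
            compare_partitions({"prodomain": r1, "ligand": r2}, {"ab": ["A", "B"]})

    def test_cluster_with_unknown_taxon_is_error(self):
        rooted = root_with_outgroup(nj(ADDITIVE), "D")
        with pytest.raises(TreeError):
            compare_partitions({"prodomain": rooted}, {"bad": ["A", "ZZ"]})
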