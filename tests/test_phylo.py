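import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from genotax.indexes import PairwiseResults
from genotax.phylo import (
    TreeValidationError,
    collapse_low_support,
    infer_tree,
    map_support,
    pseudo_bootstrap,
    root_with_outgroup,
    tree_bipartitions,
    tree_to_distance_matrix,
)

from helpers import random_additive_tree


def _read(newick):
    return TreeNode.read(io.StringIO(newick))


class TestInferTree:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # hand-constructed from the tree ((a:2,b:3):3,(c:4,d:5)) -> distances
        dm = pd.DataFrame(
            [[0, 5, 9, 10], [5, 0, 10, 11], [9, 10, 0, 9], [10, 11, 9, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        for method in ("nj", "bme"):
            tree = infer_tree(dm, method)
            rec = tree_to_distance_matrix(tree).loc[list("abcd"), list("abcd")]
            assert np.allclose(rec.values, dm.values, atol=1e-9)
            assert tree_bipartitions(tree) == {frozenset({"c", "d"})}

    def test_three_taxa_closed_form(self):
        dm = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("abc"), columns=list("abc"),
            dtype=float,
        )
        tree = infer_tree(dm, "bme")
        lengths = {t.name: t.length for t in tree.tips()}
        # three-point formulas: a=(3+4-5)/2=1, b=(3+5-4)/2=2, c=(4+5-3)/2=3
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_trees_inverted_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        newick, dm, labels = random_additive_tree(n, rng)
        tree = infer_tree(dm, "bme")
        rec = tree_to_distance_matrix(tree).loc[labels, labels]
        assert np.allclose(rec.values, dm.values, atol=1e-6)
        assert tree.compare_rfd(_read(newick)) == 0.0

    def test_nan_matrix_rejected(self):
        dm = pd.DataFrame(np.full((3, 3), np.nan), index=list("abc"), columns=list("abc"))
        with pytest.raises(TreeValidationError):
            infer_tree(dm)

    def test_asymmetric_matrix_rejected(self):
        dm = pd.DataFrame(
            [[0, 1, 2], [5, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc"),
            dtype=float,
        )
        with pytest.raises(TreeValidationError):
            infer_tree(dm)

    def test_fewer_than_three_taxa_rejected(self):
        dm = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"), dtype=float)
        with pytest.raises(TreeValidationError):
            infer_tree(dm)

    def test_negative_length_estimates_clamped(self):
        # a non-additive noisy matrix can yield negative NJ estimates
        rng = np.random.default_rng(3)
        n = 6
        mat = rng.uniform(1, 2, size=(n, n))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        ids = [f"t{i}" for i in range(n)]
        dm = pd.DataFrame(mat, index=ids, columns=ids)
        for method in ("nj", "bme"):
            tree = infer_tree(dm, method)
            assert all(
                (node.length or 0) >= 0 for node in tree.traverse(include_self=False)
            )


class TestSupport:
    def test_bipartition_in_all_replicates_scores_100(self):
        main = _read("((a,b),(c,d),e);")
        reps = [_read("((a,b),(c,d),e);") for _ in range(100)]
        sup = map_support(main, reps)
        names = {node.name for node in sup.non_tips(include_self=False)}
        assert names == {"100"}

    def test_bipartition_in_no_replicate_scores_0(self):
        main = _read("((a,b),(c,d),e);")
        reps = [_read("((a,c),(b,d),e);") for _ in range(10)]
        sup = map_support(main, reps)
        names = {node.name for node in sup.non_tips(include_self=False)}
        assert names == {"0"}

    def test_support_equals_exhaustive_bipartition_count(self):
        # 5-taxon toy: hand-built replicate list with a 60/40 split
        main = _read("(((a,b),c),(d,e));")
        reps = [_read("(((a,b),c),(d,e));")] * 6 + [_read("(((a,c),b),(d,e));")] * 4
        sup = map_support(main, reps)
        by_side = {
            frozenset(t.name for t in node.tips()): node.name
            for node in sup.non_tips(include_self=False)
        }
        assert by_side[frozenset("ab")] == "60"
        assert by_side[frozenset("abc")] == "100"
        assert by_side[frozenset("de")] == "100"

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(TreeValidationError):
            map_support(_read("((a,b),c);"), [_read("((a,b),x);")])


class TestCollapse:
    def test_boundary_50_collapsed_51_kept(self):
        tree = _read("(((a,b)50,c)51,(d,e)100);")
        out = collapse_low_support(tree, 50)
        clades = {
            frozenset(t.name for t in node.tips())
            for node in out.non_tips(include_self=False)
        }
        assert frozenset("ab") not in clades  # "50% or less" -> contracted
        assert frozenset("abc") in clades
        assert frozenset("de") in clades

    def test_all_high_support_unchanged(self):
        tree = _read("(((a,b)100,c)100,(d,e)100);")
        out = collapse_low_support(tree, 50)
        assert tree_bipartitions(out) == tree_bipartitions(tree)

    def test_leaf_set_and_edge_count_never_grow(self):
        tree = _read("(((a,b)10,c)90,(d,e)40);")
        out = collapse_low_support(tree, 50)
        assert {t.name for t in out.tips()} == {t.name for t in tree.tips()}
        assert len(list(out.non_tips())) <= len(list(tree.non_tips()))


class TestRooting:
    def test_single_leaf_outgroup_always_roots(self):
        tree = _read("((a,b),(c,d),e);")
        rooted = root_with_outgroup(tree, ["e"])
        sides = [{t.name for t in child.tips()} or {child.name} for child in rooted.children]
        assert {"e"} in sides

    def test_two_leaf_monophyletic_outgroup_roots_on_stem(self):
        tree = _read("((a,b),(c,d),e);")
        rooted = root_with_outgroup(tree, ["c", "d"])
        sides = [{t.name for t in child.tips()} or {child.name} for child in rooted.children]
        assert {"c", "d"} in sides

    def test_scattered_outgroup_errors_naming_conflicts(self):
        tree = _read("((a,b),(c,d),e);")
        with pytest.raises(TreeValidationError, match="monophyletic"):
            root_with_outgroup(tree, ["a", "c"])

    def test_unknown_outgroup_id_rejected(self):
        tree = _read("((a,b),(c,d),e);")
        with pytest.raises(TreeValidationError, match="not in tree"):
            root_with_outgroup(tree, ["z"])


def _toy_results():
    """Two 'genomes' with hand-set HSP stats for bootstrap tests."""
    res = PairwiseResults(ids=["x", "y"], gbdp_formula="d5")
    res.genome_lengths = {"x": 1000, "y": 1000}
    res.hsp_stats[("x", "y")] = [[(90, 100)] * 5, [(90, 100)] * 5]
    return res


class TestPseudoBootstrap:
    def test_fixed_seed_is_bit_identical(self, small_results):
        a = pseudo_bootstrap(small_results, replicates=5, seed=99)
        b = pseudo_bootstrap(small_results, replicates=5, seed=99)
        for ma, mb in zip(a, b):
            assert ma.equals(mb)

    def test_clonal_hsp_set_is_resampling_invariant(self):
        res = _toy_results()
        reps = pseudo_bootstrap(res, replicates=20, seed=1)
        expected = -np.log(0.9)
        for m in reps:
            assert m.loc["x", "y"] == pytest.approx(expected)

    def test_zero_hsp_pair_reports_capped_distance(self):
        res = _toy_results()
        res.hsp_stats[("x", "y")] = [[], []]
        reps = pseudo_bootstrap(res, replicates=3, seed=1)
        from genotax.constants import GBDP_MAX_DISTANCE

        assert reps[0].loc["x", "y"] == GBDP_MAX_DISTANCE["d5"]

    def test_invalid_replicate_count_rejected(self, small_results):
        with pytest.raises(ValueError):
            pseudo_bootstrap(small_results, replicates=0, seed=1)

    def test_deep_split_support_high_on_planted_clades(self, small_clade_set, small_results, small_support_tree):
        _, _, truth = small_clade_set
        genera = {}
        for gid, genus in truth.genus_partition.items():
            genera.setdefault(genus, set()).add(gid)
        by_side = {
            frozenset(t.name for t in node.tips()): node.name
            for node in small_support_tree.non_tips(include_self=False)
        }
        leaves = frozenset(truth.genus_partition)
        for members in genera.values():
            side = frozenset(members)
            sup = by_side.get(side, by_side.get(leaves - side))
            assert sup is not None
            assert int(sup) >= 95
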