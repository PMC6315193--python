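import io
import itertools

import numpy as np
import pytest
from skbio import TreeNode

from genotax.indexes import PairwiseComparison, PairwiseResults
from genotax.io import StrainMetadata
from genotax.taxonomy import (
    DelimitationThresholds,
    TaxonCluster,
    classify_new_genome,
    delimit_taxa,
    detect_phyly_problems,
    infer_genus_clusters,
    infer_species_clusters,
    is_monophyletic,
    reclassification_actions,
    resolve_names,
)

from helpers import brute_force_clades, rand_index


def _read(newick):
    return TreeNode.read(io.StringIO(newick))


def _results(ids, pair_values):
    """Build PairwiseResults from {(a,b): dict(ani=..., dddh=..., aai=...,
    gc_diff=...)}; unspecified pairs get clearly-failing values."""
    res = PairwiseResults(ids=list(ids))
    for a, b in itertools.combinations(ids, 2):
        vals = pair_values.get((a, b), pair_values.get((b, a), {}))
        res.comparisons[(a, b)] = PairwiseComparison(
            genome_a=a,
            genome_b=b,
            ani=vals.get("ani", 70.0),
            dddh=vals.get("dddh", 20.0),
            aai=vals.get("aai", 60.0),
            gc_diff=vals.get("gc_diff", 0.1),
            pocp=vals.get("pocp"),
        )
    return res


class TestMonophyly:
    def test_singleton_and_full_ingroup_are_clades(self):
        tree = _read("(((a,b),c),(d,e));")
        assert is_monophyletic(tree, {"a"})
        assert is_monophyletic(tree, {"a", "b", "c"})
        assert not is_monophyletic(tree, {"b", "c", "d"})

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError):
            is_monophyletic(_read("((a,b),c);"), {"z"})

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_exhaustive_clade_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("abcdef")
        # random rooted 6-leaf tree
        nodes = list(labels)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
            x = nodes.pop(i)
            y = nodes.pop(j)
            nodes.append(f"({x},{y})")
        tree = _read(nodes[0] + ";")
        clades = brute_force_clades(tree)
        for r in range(1, 7):
            for subset in itertools.combinations(labels, r):
                expected = len(subset) == 1 or frozenset(subset) in clades
                assert is_monophyletic(tree, set(subset)) == expected


class TestSpeciesClusters:
    def test_high_dddh_high_ani_pair_merges(self):
        # mirrors the marinus/whittenburyi pattern: 89% dDDH, 99% ANI
        tree = _read("((m1,m2),(x,y));")
        res = _results(
            ["m1", "m2", "x", "y"],
            {("m1", "m2"): dict(dddh=89, ani=99, gc_diff=0.2)},
        )
        clusters = infer_species_clusters(tree, res)
        members = {c.members for c in clusters}
        assert frozenset({"m1", "m2"}) in members

    def test_borderline_ani_but_low_dddh_stays_split(self):
        # the 20Z/5G pattern: ANI at the 95 threshold, dDDH only 63
        tree = _read("((m1,m2),(x,y));")
        res = _results(
            ["m1", "m2", "x", "y"],
            {("m1", "m2"): dict(dddh=63, ani=95, gc_diff=0.2)},
        )
        clusters = infer_species_clusters(tree, res)
        assert frozenset({"m1", "m2"}) not in {c.members for c in clusters}

    def test_high_dddh_but_low_ani_nonmonophyletic_stays_split(self):
        # the TMED282/TMED69 pattern: dDDH 78 with ANI 61 across the tree
        tree = _read("((t1,x),(t2,y));")
        res = _results(
            ["t1", "t2", "x", "y"],
            {("t1", "t2"): dict(dddh=78, ani=61, gc_diff=4.0)},
        )
        clusters = infer_species_clusters(tree, res)
        assert all(len(c.members) == 1 for c in clusters)

    def test_gc_difference_of_one_point_blocks_merging(self):
        tree = _read("((m1,m2),(x,y));")
        res = _results(
            ["m1", "m2", "x", "y"],
            {("m1", "m2"): dict(dddh=90, ani=99, gc_diff=1.0)},
        )
        clusters = infer_species_clusters(tree, res)
        assert frozenset({"m1", "m2"}) not in {c.members for c in clusters}

    def test_complete_linkage_blocks_threshold_chaining(self):
        # a-b and b-c pass but a-c fails: no 3-member cluster may form
        tree = _read("(((a,b),c),(x,y));")
        good = dict(dddh=80, ani=97, gc_diff=0.1)
        res = _results(
            ["a", "b", "c", "x", "y"],
            {("a", "b"): good, ("b", "c"): good},
        )
        clusters = infer_species_clusters(tree, res)
        by_member = {m: c.members for c in clusters for m in c.members}
        assert len(by_member["a"]) <= 2
        assert not (by_member["a"] == by_member["b"] == by_member["c"])

    def test_partition_property(self):
        tree = _read("(((a,b),c),(x,y));")
        res = _results(["a", "b", "c", "x", "y"], {})
        clusters = infer_species_clusters(tree, res)
        seen = [m for c in clusters for m in c.members]
        assert sorted(seen) == ["a", "b", "c", "x", "y"]

    def test_raising_thresholds_never_merges(self):
        tree = _read("((m1,m2),(x,y));")
        res = _results(
            ["m1", "m2", "x", "y"],
            {("m1", "m2"): dict(dddh=75, ani=96, gc_diff=0.2)},
        )
        lo = infer_species_clusters(tree, res, DelimitationThresholds())
        hi = infer_species_clusters(
            tree, res, DelimitationThresholds(dddh_species_min=80)
        )
        size = lambda cs: sorted(len(c.members) for c in cs)
        assert max(size(hi)) <= max(size(lo))


class TestGenusClusters:
    def test_low_between_clade_aai_keeps_genera_apart(self):
        # 66-67% AAI between clades -> different genera
        tree = _read("(((a1,a2),(b1,b2)),(o1,o2));")
        vals = {}
        for pair in [("a1", "a2"), ("b1", "b2"), ("o1", "o2")]:
            vals[pair] = dict(aai=85)
        for x in ("a1", "a2"):
            for y in ("b1", "b2"):
                vals[(x, y)] = dict(aai=66.5)
        res = _results(["a1", "a2", "b1", "b2", "o1", "o2"], vals)
        clusters = infer_genus_clusters(tree, res)
        members = {c.members for c in clusters}
        assert frozenset({"a1", "a2"}) in members
        assert frozenset({"b1", "b2"}) in members

    def test_aai_69_pair_splits(self):
        tree = _read("((p,q),(x,y));")
        res = _results(["p", "q", "x", "y"], {("p", "q"): dict(aai=69)})
        clusters = infer_genus_clusters(tree, res)
        assert frozenset({"p", "q"}) not in {c.members for c in clusters}

    def test_planted_two_genus_structure_recovered(self):
        # within-AAI 85, between-AAI 65 on a 6-leaf tree
        tree = _read("(((a1,a2),a3),((b1,b2),b3));")
        vals = {}
        for grp in (("a1", "a2", "a3"), ("b1", "b2", "b3")):
            for pair in itertools.combinations(grp, 2):
                vals[pair] = dict(aai=85)
        res = _results(["a1", "a2", "a3", "b1", "b2", "b3"], vals)
        clusters = infer_genus_clusters(tree, res)
        assert {c.members for c in clusters} == {
            frozenset({"a1", "a2", "a3"}),
            frozenset({"b1", "b2", "b3"}),
        }

    def test_missing_proteome_yields_flagged_singleton(self):
        tree = _read("((a,b),(c,d));")
        vals = {("a", "b"): dict(aai=85), ("c", "d"): dict(aai=85)}
        res = _results(["a", "b", "c", "d"], vals)
        for key, comp in res.comparisons.items():
            if "d" in key:
                comp.aai = None
        clusters = infer_genus_clusters(tree, res)
        flagged = [c for c in clusters if c.members == frozenset({"d"})]
        assert flagged and "no_proteome" in flagged[0].flags

    def test_species_partition_refines_genus_partition(self, small_results, small_support_tree, small_clade_set):
        _, _, truth = small_clade_set
        genus, species = delimit_taxa(small_support_tree, small_results)
        genus_of = {m: i for i, c in enumerate(genus) for m in c.members}
        for cl in species:
            assert len({genus_of[m] for m in cl.members}) == 1
        est_genus = {m: str(i) for i, c in enumerate(genus) for m in c.members}
        est_species = {m: str(i) for i, c in enumerate(species) for m in c.members}
        assert rand_index(est_genus, truth.genus_partition) == 1.0
        assert rand_index(est_species, truth.species_partition) == 1.0


def _md(name, year=None, page=None, type_species=False, mag=False, valid=True):
    return StrainMetadata(
        name=name,
        is_type_species=type_species,
        validly_published=valid,
        publication_year=year,
        page_rank=page,
        is_mag=mag,
    )


class TestResolveNames:
    def test_same_publication_page_priority(self):
        # two names from one publication: the earlier page wins
        meta = {
            "g1": _md("Methylobacter marinus", 1985, page=1),
            "g2": _md("Methylobacter whittenburyi", 1985, page=2),
        }
        cl = TaxonCluster(rank="species", members=frozenset(meta))
        out = resolve_names([cl], meta)[0]
        assert out.resolved_name == "Methylobacter marinus"
        assert out.name_basis == "page_order"
        assert out.synonyms == [
            ("Methylobacter whittenburyi", "Methylobacter marinus")
        ]

    def test_publication_date_priority(self):
        meta = {
            "g1": _md("Methylomonas methanica", 1970),
            "g2": _md("Methylomonas denitrificans", 2016),
        }
        cl = TaxonCluster(rank="species", members=frozenset(meta))
        out = resolve_names([cl], meta)[0]
        assert out.resolved_name == "Methylomonas methanica"
        assert out.name_basis == "publication_date"

    def test_type_species_retention_beats_dates(self):
        meta = {
            "g1": _md("Methylomicrobium agile", 1995, type_species=True),
            "g2": _md("Methylomicrobium album", 1985),
        }
        cl = TaxonCluster(rank="species", members=frozenset(meta))
        out = resolve_names([cl], meta)[0]
        assert out.resolved_name == "Methylomicrobium agile"
        assert out.name_basis == "type_species_priority"

    def test_mag_only_cluster_gets_placeholder(self):
        meta = {"m1": _md("", mag=True), "m2": _md("", mag=True)}
        cl = TaxonCluster(rank="species", members=frozenset(meta))
        out = resolve_names([cl], meta, placeholder="Methylococcaceae bacterium")[0]
        assert out.resolved_name == "Methylococcaceae bacterium"
        assert out.name_basis == "placeholder_mag"
        assert out.synonyms == []

    def test_missing_years_flagged_never_guessed(self):
        meta = {"g1": _md("Alpha one"), "g2": _md("Beta two")}
        cl = TaxonCluster(rank="species", members=frozenset(meta))
        out = resolve_names([cl], meta)[0]
        assert out.unresolved
        assert out.resolved_name is None

    def test_idempotent_when_name_already_senior(self):
        meta = {
            "g1": _md("Methylomonas methanica", 1970),
            "g2": _md("Methylomonas methanica", 1970),
        }
        cl = TaxonCluster(rank="species", members=frozenset(meta))
        out = resolve_names([cl], meta)[0]
        assert out.resolved_name == "Methylomonas methanica"
        assert out.name_basis == "unchanged"
        assert out.synonyms == []

    def test_reclassification_actions(self):
        meta = {
            "g1": _md("Methylobacter marinus", 1985, page=1),
            "g2": _md("Methylobacter whittenburyi", 1985, page=2),
            "g3": _md("Methylobacter somethingelse", 2000),
        }
        cl = TaxonCluster(rank="species", members=frozenset({"g1", "g2"}))
        out = resolve_names([cl], meta)
        actions = reclassification_actions(out, meta)
        assert actions["g1"] == "unchanged"
        assert actions["g2"] == "synonymized"


class TestPhylyProblems:
    def test_clean_label_is_monophyletic(self):
        tree = _read("((a1,a2),(b1,b2));")
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert detect_phyly_problems(tree, labels) == {
            "A": "monophyletic",
            "B": "monophyletic",
        }

    def test_interleaved_named_labels_are_polyphyletic(self):
        tree = _read("((a1,(a2,b1)),b2);")
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        verdict = detect_phyly_problems(tree, labels)
        assert verdict["A"] == "polyphyletic"
        assert verdict["B"] == "polyphyletic"

    def test_label_diluted_by_unnamed_leaves_is_paraphyletic(self):
        tree = _read("((v1,(v2,m1)),x);")
        labels = {"v1": "V", "v2": "V", "m1": "", "x": "X"}
        assert detect_phyly_problems(tree, labels)["V"] == "paraphyletic"

    @pytest.mark.parametrize("seed", range(10))
    def test_monophyly_verdict_matches_clade_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        leaves = [f"l{i}" for i in range(8)]
        nodes = list(leaves)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
            nodes.append(f"({nodes.pop(i)},{nodes.pop(j)})")
        tree = _read(nodes[0] + ";")
        labels = {l: rng.choice(["A", "B"]) for l in leaves}
        clades = brute_force_clades(tree)
        verdict = detect_phyly_problems(tree, labels)
        for lab in set(labels.values()):
            members = frozenset(l for l, x in labels.items() if x == lab)
            expected_mono = len(members) == 1 or members in clades
            assert (verdict[lab] == "monophyletic") == expected_mono


class TestClassifyNewGenome:
    SPECIES = [TaxonCluster(rank="species", members=frozenset({"r1", "r2"}))]
    GENUS = [TaxonCluster(rank="genus", members=frozenset({"r1", "r2", "r3"}))]

    def test_identical_to_reference_joins_its_species(self):
        idx = {"r1": dict(ani=100.0, dddh=99.9, aai=100.0, gc_diff=0.0)}
        out = classify_new_genome("q", idx, self.SPECIES, self.GENUS)
        assert out["verdict"] == "species"
        assert out["representative"] == "r1"

    def test_ten_percent_divergence_is_novel_species_within_genus(self):
        idx = {"r1": dict(ani=90.0, dddh=40.0, aai=88.0, gc_diff=0.3)}
        out = classify_new_genome("q", idx, self.SPECIES, self.GENUS)
        assert out["verdict"] == "novel species"

    def test_low_aai_everywhere_is_novel_genus(self):
        idx = {"r1": dict(ani=None, dddh=21.0, aai=60.0, gc_diff=2.0)}
        out = classify_new_genome("q", idx, self.SPECIES, self.GENUS)
        assert out["verdict"] == "novel genus (within dataset)"
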