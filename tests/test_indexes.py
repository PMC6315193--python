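import math

import numpy as np
import pytest

from genotax import constants
from genotax.align import HSP
from genotax.indexes import (
    compute_aai,
    compute_ani,
    compute_pocp,
    distance_from_stats,
    distance_to_dddh,
    fragment_genome,
    gbdp_distance,
    gbdp_hsp_stats,
    greedy_trim,
)
from genotax.io import GenomeRecord
from genotax.simulate import (
    evolve,
    simulate_ancestor,
    simulate_proteome_pair,
    truth_index,
)

from helpers import random_dna


class TestFragmentGenome:
    def test_exact_division(self):
        g = GenomeRecord(id="g", contigs=["A" * 5100])
        frags = fragment_genome(g)
        assert len(frags) == 5
        assert all(len(f.seq) == 1020 for f in frags)

    def test_trailing_window_kept_at_100(self):
        g = GenomeRecord(id="g", contigs=["A" * 5200])
        frags = fragment_genome(g)
        assert len(frags) == 6
        assert len(frags[-1].seq) == 100

    def test_trailing_window_below_100_dropped(self):
        g = GenomeRecord(id="g", contigs=["A" * 5199])
        assert len(fragment_genome(g)) == 5
        g99 = GenomeRecord(id="g", contigs=["A" * 99])
        assert fragment_genome(g99) == []

    def test_fragments_are_per_contig(self):
        g = GenomeRecord(id="g", contigs=["A" * 1020, "C" * 1020])
        frags = fragment_genome(g)
        assert [(f.contig_index, f.offset) for f in frags] == [(0, 0), (1, 0)]


class TestPOCP:
    def _prot(self, n):
        from genotax.io import ProteomeRecord

        return ProteomeRecord(genome_id="x", proteins=[(f"p{i}", "M") for i in range(n)])

    def test_printed_formula_is_exact(self):
        assert compute_pocp(self._prot(1000), self._prot(500), 300) == 40.0

    def test_identical_proteomes_give_exactly_100(self):
        assert compute_pocp(self._prot(7), self._prot(7), 7) == 100.0

    def test_zero_shared_gives_zero(self):
        assert compute_pocp(self._prot(10), self._prot(20), 0) == 0.0

    def test_shared_exceeding_smaller_proteome_is_inconsistent(self):
        with pytest.raises(ValueError):
            compute_pocp(self._prot(10), self._prot(5), 6)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            compute_pocp(self._prot(0), self._prot(5), 0)


class TestANI:
    def test_identical_genomes_give_100(self):
        g = simulate_ancestor(20_000, 50, seed=1)
        h = GenomeRecord(id="h", contigs=list(g.contigs))
        ani, n = compute_ani(g, h)
        assert ani == pytest.approx(100.0)
        assert n > 0

    def test_symmetric_by_construction(self):
        g = simulate_ancestor(20_000, 50, seed=2)
        h, _ = evolve(g, 0.05, 0.0, 3, seed=3)
        assert compute_ani(g, h)[0] == compute_ani(h, g)[0]

    def test_invariant_under_contig_order(self):
        g = simulate_ancestor(20_400, 50, seed=4)
        seq = g.sequence
        a = GenomeRecord(id="a", contigs=[seq[:10_200], seq[10_200:]])
        b = GenomeRecord(id="b", contigs=[seq[10_200:], seq[:10_200]])
        assert compute_ani(a, b)[0] == pytest.approx(100.0)

    def test_unrelated_genomes_have_undefined_ani(self):
        rng = np.random.default_rng(5)
        a = GenomeRecord(id="a", contigs=[random_dna(5000, rng)])
        b = GenomeRecord(id="b", contigs=[random_dna(5000, rng)])
        ani, n = compute_ani(a, b)
        assert ani is None
        assert n == 0

    def test_two_percent_divergence_recovered(self):
        # oracle: realized mismatch fraction from the mutation log
        g = simulate_ancestor(50_000, 50, seed=6)
        h, log = evolve(g, 0.02, 0.0, 3, seed=7)
        ani, _ = compute_ani(g, h)
        assert ani == pytest.approx(100 * (1 - log["realized_sub_fraction"]), abs=0.3)

    def test_robust_to_missing_half_of_one_genome(self):
        # clonal pair, one genome truncated to half: ANI must stay ~100
        g = simulate_ancestor(40_800, 50, seed=8)
        half = GenomeRecord(id="half", contigs=[g.sequence[: g.total_length // 2]])
        ani, _ = compute_ani(g, half)
        assert ani == pytest.approx(100.0, abs=1.0)


class TestAAI:
    def test_identical_proteomes(self, small_clade_set):
        _, proteomes, _ = small_clade_set
        p = next(iter(proteomes.values()))
        aai, n = compute_aai(p, p)
        assert aai == pytest.approx(100.0)
        assert n == p.count

    def test_no_homology_gives_absent(self):
        rng = np.random.default_rng(9)
        AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        from genotax.io import ProteomeRecord

        mk = lambda gid: ProteomeRecord(
            genome_id=gid,
            proteins=[
                (f"{gid}{i}", "".join(AA[rng.integers(0, 20, 80)])) for i in range(5)
            ],
        )
        aai, n = compute_aai(mk("a"), mk("b"))
        assert aai is None and n == 0

    def test_twenty_percent_divergence_recovered(self):
        a, b, realized = simulate_proteome_pair(
            t1=120, t2=120, shared=120, divergence=0.20, seed=10, gene_length_aa=200
        )
        aai, n = compute_aai(a, b)
        assert n == 120
        assert aai == pytest.approx(100 * (1 - realized), abs=1.0)


class TestGreedyTrim:
    def _hsp(self, q0, q1, s0, s1, ident, score):
        length = max(q1 - q0, s1 - s0)
        return HSP(
            query_id="q", subject_id="s", q_start=q0, q_end=q1, s_start=s0,
            s_end=s1, strand="+", length=length, identities=ident,
            raw_score=score, bitscore=score,
        )

    def test_disjoint_hsps_all_retained(self):
        hsps = [self._hsp(0, 100, 0, 100, 95, 90), self._hsp(200, 300, 200, 300, 80, 60)]
        assert len(greedy_trim(hsps)) == 2

    def test_duplicate_hsp_dropped(self):
        h = self._hsp(0, 100, 0, 100, 95, 90)
        assert len(greedy_trim([h, h])) == 1

    def test_partial_overlap_trimmed_proportionally(self):
        big = self._hsp(0, 100, 0, 100, 100, 100)
        part = self._hsp(60, 160, 60, 160, 100, 80)  # 40% overlap -> trimmed
        stats = greedy_trim([big, part])
        assert stats[0] == (100, 100)
        assert stats[1] == (60, 60)

    def test_majority_overlap_dropped(self):
        big = self._hsp(0, 100, 0, 100, 100, 100)
        worse = self._hsp(20, 100, 20, 100, 60, 40)  # 100% of its span covered
        assert len(greedy_trim([big, worse])) == 1


class TestGBDPDistance:
    def test_self_distance_zero(self):
        g = simulate_ancestor(20_000, 50, seed=11)
        assert gbdp_distance(g, g) == 0.0

    def test_symmetric_contract(self):
        g = simulate_ancestor(20_000, 50, seed=12)
        h, _ = evolve(g, 0.08, 0.0, 3, seed=13)
        assert gbdp_distance(g, h) == pytest.approx(gbdp_distance(h, g))

    def test_monotone_in_divergence_ladder(self):
        g = simulate_ancestor(30_000, 50, seed=14)
        dists = []
        for i, f in enumerate((0.01, 0.05, 0.10)):
            h, _ = evolve(g, f, 0.0, 3, seed=20 + i)
            dists.append(gbdp_distance(g, h))
        assert dists[0] < dists[1] < dists[2]

    def test_no_hsps_reports_capped_maximum(self):
        rng = np.random.default_rng(15)
        a = GenomeRecord(id="a", contigs=[random_dna(3000, rng)])
        b = GenomeRecord(id="b", contigs=[random_dna(3000, rng)])
        assert gbdp_distance(a, b) == constants.GBDP_MAX_DISTANCE["d5"]

    def test_formula_values_from_known_stats(self):
        stats = [(900, 1000)]  # 90% identity over 1000 columns
        assert distance_from_stats(stats, 2000, 2000, "d6") == pytest.approx(0.1)
        assert distance_from_stats(stats, 2000, 2000, "d5") == pytest.approx(-math.log(0.9))
        assert distance_from_stats(stats, 2000, 2000, "d0") == pytest.approx(0.5)
        assert distance_from_stats(stats, 2000, 2000, "d4") == pytest.approx(-math.log(0.5))


class TestDDDH:
    def test_strictly_monotone_decreasing(self):
        ds = np.linspace(0, 0.5, 40)
        vals = [distance_to_dddh(d) for d in ds]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_identical_genomes_exceed_99(self):
        assert distance_to_dddh(0.0) > 99.0

    def test_range_is_zero_to_hundred(self):
        assert 0.0 < distance_to_dddh(5.0) < distance_to_dddh(1e-9) < 100.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_to_dddh(-0.1)

    def test_species_threshold_sits_between_published_anchors(self):
        # dDDH ~90 at d=0.01 (ANI 99) and ~63 at d=0.05 (ANI 95): the
        # calibration reproduces the published pairings
        assert distance_to_dddh(0.01) == pytest.approx(90.0, abs=2.0)
        assert distance_to_dddh(0.05) == pytest.approx(63.0, abs=2.0)


class TestAllPairwise(object):
    def test_all_unordered_pairs_present(self, small_results):
        n = len(small_results.ids)
        assert len(small_results.comparisons) == n * (n - 1) // 2

    def test_matrices_symmetric_with_fixed_diagonal(self, small_results):
        for index, diag in [("ani", 100.0), ("aai", 100.0), ("gbdp_distance", 0.0)]:
            m = small_results.matrix(index)
            assert np.allclose(m.values, m.values.T, equal_nan=True)
            assert np.allclose(np.diag(m.values), diag)

    def test_indexes_within_bounds(self, small_results):
        for comp in small_results.comparisons.values():
            for v in (comp.ani, comp.aai, comp.pocp, comp.dddh):
                if v is not None:
                    assert 0.0 <= v <= 100.0
            assert comp.gbdp_distance >= 0.0

    def test_estimates_match_truth_oracle(self, small_clade_set, small_results):
        genomes, _, truth = small_clade_set
        for pair, comp in small_results.comparisons.items():
            exp_ani, exp_aai, exp_pocp = truth_index(truth, pair)
            if exp_ani is not None and exp_ani >= 70 and comp.ani is not None:
                assert comp.ani == pytest.approx(exp_ani, abs=0.5)
            if exp_aai is not None and comp.aai is not None and exp_aai >= 60:
                assert comp.aai == pytest.approx(exp_aai, abs=1.0)
            if exp_aai is not None and exp_aai >= 80:
                assert comp.pocp == pytest.approx(exp_pocp)


class TestOneDirectionalPOCP:
    def test_identical_proteomes_give_100(self, small_clade_set):
        from genotax.indexes import compute_pocp_one_directional

        _, proteomes, _ = small_clade_set
        p = next(iter(proteomes.values()))
        assert compute_pocp_one_directional(p, p) == pytest.approx(100.0)

    def test_counts_unreciprocated_hits(self):
        # B holds two near-copies of one A protein: the one-directional
        # variant counts both B proteins as conserved, RBH-based S only one
        from genotax.io import ProteomeRecord
        from genotax.indexes import compute_aai, compute_pocp_one_directional

        rng = np.random.default_rng(44)
        AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        base = "".join(AA[rng.integers(0, 20, 200)])
        variant = base[:100] + "".join(AA[rng.integers(0, 20, 3)]) + base[103:]
        a = ProteomeRecord(genome_id="a", proteins=[("a1", base)])
        b = ProteomeRecord(genome_id="b", proteins=[("b1", base), ("b2", variant)])
        _, s_rbh = compute_aai(a, b)
        assert s_rbh == 1
        pocp_one_way = compute_pocp_one_directional(a, b)
        assert pocp_one_way == pytest.approx((1 + 2) / (1 + 2) * 100)
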