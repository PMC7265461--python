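"""Protein collapse, weighted running-sum ES, and the permutation null."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from hipquant import (RankedGeneList, collapse_to_proteins, enrichment_score,
                      filter_significant, permutation_null, read_gmt,
                      read_rnk, write_rnk)


def brute_force_es(genes, scores, gene_set, weight=1.0):
    """Independent oracle: literal walk down the list, tracking the sum."""
    n = len(genes)
    hits = [g in gene_set for g in genes]
    n_hits = sum(hits)
    total = sum(abs(s) ** weight for g, s, h in zip(genes, scores, hits) if h)
    running, trace = 0.0, []
    for g, s, h in zip(genes, scores, hits):
        if h:
            running += (abs(s) ** weight) / total if total > 0 \
                else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        trace.append(running)
    hi, lo = max(trace), min(trace)
    # same near-tie rule as the implementation: positive extreme wins
    return hi if hi >= -lo - 1e-9 else lo


class TestCollapse:
    def test_positive_direction_takes_max(self):
        ranked = collapse_to_proteins(
            {"pepA": 2.0, "pepB": 0.5}, {"pepA": "G", "pepB": "G"},
            "positive")
        assert ranked.genes == ["G"] and ranked.scores[0] == 2.0

    def test_negative_direction_takes_min(self):
        ranked = collapse_to_proteins(
            {"pepA": -1.2, "pepB": 0.3}, {"pepA": "G", "pepB": "G"},
            "negative")
        assert ranked.scores[0] == -1.2

    def test_single_peptide_gene_keeps_its_score(self):
        ranked = collapse_to_proteins({"pepA": 0.7}, {"pepA": "G"})
        assert ranked.scores[0] == 0.7

    def test_sorted_descending_with_name_tiebreak(self):
        ranked = collapse_to_proteins(
            {"a": 1.0, "b": 1.0, "c": 2.0},
            {"a": "ZZZ", "b": "AAA", "c": "MMM"})
        assert ranked.genes == ["MMM", "AAA", "ZZZ"]

    def test_unmapped_peptides_dropped(self):
        ranked = collapse_to_proteins({"a": 1.0, "b": 2.0}, {"a": "G"})
        assert ranked.genes == ["G"]

    def test_empty_map_is_error(self):
        with pytest.raises(ValueError):
            collapse_to_proteins({"a": 1.0}, {})


class TestEnrichmentScore:
    def test_top_block_of_all_positive_list_scores_one(self):
        ranked = RankedGeneList(["a", "b", "c", "d"],
                                np.array([4.0, 3.0, 2.0, 1.0]))
        es, running = enrichment_score(ranked, {"a", "b"})
        assert es == pytest.approx(1.0)
        assert running[1] == pytest.approx(1.0)

    def test_whole_list_set_is_degenerate(self):
        ranked = RankedGeneList(["a", "b"], np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="whole list"):
            enrichment_score(ranked, {"a", "b"})

    def test_empty_intersection_flagged(self):
        ranked = RankedGeneList(["a", "b"], np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="intersection"):
            enrichment_score(ranked, {"zzz"})

    def test_matches_brute_force_on_random_list(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        scores = np.sort(rng.normal(0, 1, 10))[::-1]
        ranked = RankedGeneList(genes, scores)
        gene_set = {"g1", "g4", "g7"}
        es, _ = enrichment_score(ranked, gene_set)
        assert es == pytest.approx(
            brute_force_es(genes, scores, gene_set))

    def test_exhaustive_equivalence_on_short_lists(self):
        """Every proper subset of every list of length <= 8."""
        rng = np.random.default_rng(1)
        for n in (3, 5, 8):
            genes = [f"g{i}" for i in range(n)]
            scores = np.sort(rng.normal(0.2, 1.0, n))[::-1]
            ranked = RankedGeneList(genes, scores)
            for k in range(1, n):
                for combo in itertools.combinations(genes, k):
                    es, _ = enrichment_score(ranked, set(combo))
                    assert es == pytest.approx(
                        brute_force_es(genes, scores, set(combo))), combo

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(20)]
        scores = np.sort(rng.normal(0, 1, 20))[::-1]
        gene_set = set(rng.choice(genes, 6, replace=False))
        es1, _ = enrichment_score(RankedGeneList(genes, scores), gene_set)
        es2, _ = enrichment_score(
            RankedGeneList(genes, scores * 7.3), gene_set)
        assert es1 == pytest.approx(es2)


class TestPermutationNull:
    def _ranked(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        return RankedGeneList(genes, scores)

    def test_same_seed_reproduces_exactly(self):
        ranked = self._ranked()
        sets = {"s1": set(ranked.genes[5:15]), "s2": set(ranked.genes[20:32])}
        r1 = permutation_null(ranked, sets, 200, seed=7)
        r2 = permutation_null(ranked, sets, 200, seed=7)
        assert [(a.p_nominal, a.nes) for a in r1] == \
               [(b.p_nominal, b.nes) for b in r2]

    def test_extreme_concordance_hits_p_floor(self):
        ranked = self._ranked()
        top = {"top": set(ranked.genes[:10])}
        (res,) = permutation_null(ranked, top, 500, seed=1)
        assert res.p_nominal <= 1 / 100     # reported at/near the 1/n floor
        assert res.es > 0.8

    def test_small_overlap_not_testable(self):
        ranked = self._ranked()
        (res,) = permutation_null(ranked, {"tiny": set(ranked.genes[:3])},
                                  200, seed=0)
        assert not res.testable

    def test_null_p_values_roughly_uniform(self):
        """Random sets on random scores: nominal p passes a KS test."""
        rng = np.random.default_rng(3)
        pvals = []
        for i in range(60):
            ranked = self._ranked(n=30, seed=100 + i)
            members = set(rng.choice(ranked.genes, 10, replace=False))
            (res,) = permutation_null(ranked, {"s": members}, 200,
                                      seed=200 + i)
            pvals.append(res.p_nominal)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_reporting_filter_thresholds(self):
        ranked = self._ranked()
        sets = {"top": set(ranked.genes[:10]),
                "rand": set(ranked.genes[10:25:2]
                            ) | set(ranked.genes[30:35])}
        results = permutation_null(ranked, sets, 300, seed=5)
        kept = filter_significant(results)
        for r in kept:
            assert r.p_nominal <= 0.05 and r.fdr_q <= 0.25


class TestInterchangeFiles:
    def test_gmt_reader(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET_A\tdesc\tG1\tG2\tG3\nSET_B\t-\tG2\tG9\n")
        sets = read_gmt(p)
        assert sets == {"SET_A": {"G1", "G2", "G3"}, "SET_B": {"G2", "G9"}}

    def test_malformed_gmt_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("ONLY_NAME\n")
        with pytest.raises(ValueError):
            read_gmt(p)

    def test_rnk_round_trip(self, tmp_path):
        ranked = RankedGeneList(["B", "A", "C"], np.array([2.0, 1.0, -0.5]))
        p = tmp_path / "list.rnk"
        write_rnk(ranked, p)
        back = read_rnk(p)
        assert back.genes == ranked.genes
        assert np.allclose(back.scores, ranked.scores)
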