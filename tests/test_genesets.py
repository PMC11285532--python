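from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from cellvuln import genesets
from cellvuln.containers import GeneSetCollection, GwasTable


def enum_hypergeom_upper(k, q, t, N):
    """Exhaustive-enumeration oracle for P(X >= k) over all C(N, q) draws."""
    num = sum(Fraction(comb(t, i) * comb(N - t, q - i)) for i in range(k, min(q, t) + 1))
    return float(num / comb(N, q))


class TestHypergeomFisher:
    def test_zero_overlap_is_one(self):
        assert genesets.hypergeom_upper(0, 5, 5, 20) == 1.0
        assert genesets.fisher_overlap(0, 5, 5, 20) == 1.0

    def test_forced_overlap_is_one(self):
        assert genesets.hypergeom_upper(6, 6, 6, 6) == pytest.approx(1.0)

    def test_named_example_matches_enumeration(self):
        p = genesets.hypergeom_upper(4, 6, 7, 20)
        assert p == pytest.approx(enum_hypergeom_upper(4, 6, 7, 20), rel=1e-12)

    def test_enumeration_sweep_small_universe(self):
        for N in range(1, 13):
            for q in range(N + 1):
                for t in range(N + 1):
                    for k in range(max(0, q + t - N), min(q, t) + 1):
                        e = enum_hypergeom_upper(k, q, t, N)
                        assert genesets.hypergeom_upper(k, q, t, N) == pytest.approx(e, abs=1e-12)
                        assert genesets.fisher_overlap(k, q, t, N) == pytest.approx(e, abs=1e-10)

    def test_fisher_equals_hypergeom_on_same_margins(self):
        for args in [(3, 10, 8, 40), (1, 4, 4, 12), (7, 9, 11, 30)]:
            assert genesets.fisher_overlap(*args) == pytest.approx(
                genesets.hypergeom_upper(*args), rel=1e-9)

    def test_invalid_margins_rejected(self):
        with pytest.raises(ValueError):
            genesets.hypergeom_upper(5, 4, 4, 10)
        with pytest.raises(ValueError):
            genesets.fisher_overlap(0, 3, 3, 4)  # derived cell < 0


class TestBhAdjust:
    def test_hand_stepped_example(self):
        adj = genesets.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert genesets.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(genesets.bh_adjust([0.2] * 5), 0.2)

    def test_empty_input(self):
        assert genesets.bh_adjust([]).size == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st_h.lists(st_h.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=30),
           st_h.randoms(use_true_random=False))
    def test_permutation_invariance(self, pvals, rnd):
        order = list(range(len(pvals)))
        rnd.shuffle(order)
        base = genesets.bh_adjust(pvals)
        shuffled = genesets.bh_adjust([pvals[i] for i in order])
        realigned = np.empty_like(shuffled)
        realigned[order] = np.arange(len(order))
        np.testing.assert_allclose([shuffled[order.index(i)] for i in range(len(pvals))],
                                   base, rtol=1e-12)


class TestGwasSelect:
    def _table(self, rows):
        return GwasTable(records=pd.DataFrame(
            rows, columns=["snp", "gene", "disease", "p_value", "genic"]))

    def test_minimum_p_snp_retained(self):
        gt = self._table([("rs1", "A", "BP", 1e-6, True),
                          ("rs2", "A", "BP", 1e-9, True)])
        sel = genesets.gwas_select(gt, None, 1e-5)
        row = sel.per_disease["BP"].iloc[0]
        assert row["best_p"] == pytest.approx(1e-9)
        assert row["best_snp"] == "rs2"

    def test_threshold_and_intergenic_rules(self):
        gt = self._table([("rs1", "A", "BP", 2e-5, True),     # fails p
                          ("rs2", "B", "BP", 1e-7, False),    # intergenic
                          ("rs3", "C", "BP", 1e-6, True)])
        sel = genesets.gwas_select(gt, None, 1e-5)
        assert set(sel.per_disease["BP"]["gene"]) == {"C"}

    def test_background_intersection(self):
        from cellvuln.containers import ExpressedBackground
        gt = self._table([("rs1", "A", "BP", 1e-6, True),
                          ("rs2", "B", "BP", 1e-6, True)])
        bg = ExpressedBackground(scope="global", genes={"A", "Z"}, pctile=(10, 90))
        sel = genesets.gwas_select(gt, bg, 1e-5)
        assert set(sel.per_disease["BP"]["gene"]) == {"A"}

    def test_strict_tier_refilters(self):
        gt = self._table([("rs1", "A", "BP", 1e-9, True),
                          ("rs2", "B", "BP", 1e-6, True)])
        sel = genesets.gwas_select(gt, None, 1e-5)
        strict = sel.strict(1e-8)
        assert set(strict.per_disease["BP"]["gene"]) == {"A"}


class TestEnrichTable:
    def test_query_equals_target_gets_minimal_p(self):
        universe = [f"G{i}" for i in range(50)]
        q = set(universe[:8])
        table = genesets.enrich_table({"q": q}, {"t": q}, universe)
        row = table.iloc[0]
        assert row["k"] == row["q"] == row["t"] == 8
        assert row["pvalue"] == pytest.approx(
            enum_hypergeom_upper(8, 8, 8, 50), rel=1e-9)

    def test_null_sets_control_false_positives(self):
        rng = np.random.default_rng(12)
        universe = [f"G{i}" for i in range(400)]
        n_sig = 0
        n_tests = 0
        for rep in range(200):
            q = set(rng.choice(universe, size=25, replace=False))
            t = set(rng.choice(universe, size=25, replace=False))
            tab = genesets.enrich_table({"q": q}, {"t": t}, universe)
            n_sig += int((tab["padj"] < 0.05).sum())
            n_tests += len(tab)
        assert n_sig / n_tests <= 0.05

    def test_score_monotone_in_adjusted_p(self):
        universe = [f"G{i}" for i in range(60)]
        rng = np.random.default_rng(3)
        queries = {f"q{j}": set(rng.choice(universe, size=10, replace=False))
                   for j in range(5)}
        targets = {f"t{j}": set(rng.choice(universe, size=12, replace=False))
                   for j in range(4)}
        tab = genesets.enrich_table(queries, targets, universe)
        tab = tab.sort_values("padj")
        assert (np.diff(tab["score"]) <= 1e-12).all()

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty background"):
            genesets.enrich_table({"q": {"A"}}, {"t": {"A"}}, [])


class TestOraPathways:
    def test_disjoint_pathway_p_one(self):
        universe = [f"G{i}" for i in range(100)]
        paths = GeneSetCollection(sets={"P": frozenset(universe[50:60])})
        tab = genesets.ora_pathways(universe[:5], paths, universe)
        assert tab["pvalue"].iloc[0] == 1.0

    def test_toy_matches_enumeration(self):
        universe = [f"G{i}" for i in range(100)]
        query = set(universe[:5])
        pathway = set(universe[2:12])  # overlap = 3
        paths = GeneSetCollection(sets={"P": frozenset(pathway)})
        tab = genesets.ora_pathways(query, paths, universe)
        assert tab["k"].iloc[0] == 3
        assert tab["pvalue"].iloc[0] == pytest.approx(
            enum_hypergeom_upper(3, 5, 10, 100), rel=1e-9)

    def test_query_equal_to_background_gives_p_one(self):
        universe = [f"G{i}" for i in range(40)]
        paths = GeneSetCollection(sets={"P": frozenset(universe[:10])})
        tab = genesets.ora_pathways(universe, paths, universe)
        assert tab["pvalue"].iloc[0] == pytest.approx(1.0)


class TestGseaPreranked:
    def _ranking(self):
        genes = list("ABCDEFGHIJ")
        stats = [5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.4, 0.3, 0.2, 0.1]
        return pd.Series(stats, index=genes)

    @staticmethod
    def _stepped_es(ranked, members, weight=1.0):
        """Literal step-by-step running-sum oracle."""
        genes = list(ranked.index)
        w = np.abs(ranked.to_numpy()) ** weight
        hit_sum = sum(w[i] for i, g in enumerate(genes) if g in members)
        miss = 1.0 / (len(genes) - len(members))
        running, best = 0.0, 0.0
        for i, g in enumerate(genes):
            if g in members:
                running += w[i] / hit_sum
            else:
                running -= miss
            if abs(running) > abs(best):
                best = running
        return best

    def test_hand_stepped_ten_gene_oracle(self):
        ranked = self._ranking()
        members = {"A", "B", "F"}
        sets = GeneSetCollection(sets={"S": frozenset(members)})
        res = genesets.gsea_preranked(ranked, sets, nperm=200, seed=0, min_size=2)
        es = res.set_index("pathway").loc["S", "es"]
        assert es == pytest.approx(self._stepped_es(ranked, members), abs=1e-12)
        # hand value: after hits A and B the running sum is (5+4)/9.5 = 18/19
        assert es == pytest.approx(18 / 19, abs=1e-12)

    def test_top_block_positive_and_floor_p(self):
        ranked = self._ranking()
        sets = GeneSetCollection(sets={"TOP": frozenset({"A", "B", "C"})})
        nperm = 99
        res = genesets.gsea_preranked(ranked, sets, nperm=nperm, seed=1, min_size=2)
        row = res.set_index("pathway").loc["TOP"]
        assert row["es"] > 0
        assert row["pvalue"] == pytest.approx(1 / (nperm + 1))

    def test_bottom_block_negative_es(self):
        ranked = self._ranking()
        sets = GeneSetCollection(sets={"BOT": frozenset({"H", "I", "J"})})
        res = genesets.gsea_preranked(ranked, sets, nperm=99, seed=2, min_size=2)
        assert res.set_index("pathway").loc["BOT", "es"] < 0

    def test_weight_zero_reduces_to_classic_ks(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(40)]
        ranked = pd.Series(rng.normal(size=40), index=genes)
        members = set(rng.choice(genes, size=8, replace=False))
        sets = GeneSetCollection(sets={"S": frozenset(members)})
        res = genesets.gsea_preranked(ranked, sets, nperm=10, weight=0.0, seed=0)
        es = res.set_index("pathway").loc["S", "es"]
        # direct unweighted KS statistic on the deterministic ranking
        order = sorted(genes, key=lambda g: (-ranked[g], g.upper()))
        running, best = 0.0, 0.0
        for g in order:
            running += (1 / 8) if g.upper() in {m.upper() for m in members} else -(1 / 32)
            if abs(running) > abs(best):
                best = running
        assert es == pytest.approx(best, abs=1e-12)


class TestChisqProportions:
    def test_identical_compositions_give_zero_statistic(self):
        counts = pd.DataFrame({"TL": [30, 60], "FL": [30, 60]}, index=["A", "B"])
        res = genesets.chisq_proportions(counts)
        np.testing.assert_allclose(res["chi2"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["pvalue"], 1.0)

    def test_hand_computed_two_by_two(self):
        counts = pd.DataFrame({"TL": [30, 10], "FL": [10, 30]}, index=["A", "B"])
        res = genesets.chisq_proportions(counts).set_index("celltype")
        # margins 40/40, expected 20 per cell: chi2 = 4 * (10^2 / 20) = 20
        assert res.loc["A", "chi2"] == pytest.approx(20.0)

    def test_count_doubling_increases_statistic(self):
        counts = pd.DataFrame({"TL": [30, 10], "FL": [10, 30]}, index=["A", "B"])
        res1 = genesets.chisq_proportions(counts).set_index("celltype")
        res2 = genesets.chisq_proportions(counts * 2).set_index("celltype")
        assert res2.loc["A", "chi2"] == pytest.approx(2 * res1.loc["A", "chi2"])
        assert res2.loc["A", "pvalue"] < res1.loc["A", "pvalue"]

    def test_zero_margin_rejected(self):
        counts = pd.DataFrame({"TL": [0, 0], "FL": [10, 30]}, index=["A", "B"])
        with pytest.raises(ValueError, match="zero margin"):
            genesets.chisq_proportions(counts)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, p = genesets.pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_textbook_formula_on_small_fixture(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        r, p = genesets.pearson_test(x, y)
        rx = x - x.mean()
        ry = y - y.mean()
        r_hand = (rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum())
        assert r == pytest.approx(r_hand, rel=1e-12)
        from scipy.stats import t as t_dist
        t_stat = r_hand * np.sqrt(3 / (1 - r_hand**2))
        assert p == pytest.approx(2 * t_dist.sf(abs(t_stat), 3), rel=1e-9)

    def test_sign_flip_negates_r_keeps_p(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r1, p1 = genesets.pearson_test(x, y)
        r2, p2 = genesets.pearson_test(x, -y)
        assert r1 == pytest.approx(-r2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            genesets.pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
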