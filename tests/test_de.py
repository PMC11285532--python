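import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cellvuln import de, qc
from cellvuln.simulate import simulate_nb_groups

from conftest import make_count_matrix


class TestTmmFactors:
    def test_identical_columns_all_one(self):
        y = np.tile(np.arange(1, 21)[:, None], (1, 4))
        np.testing.assert_allclose(de.tmm_factors(y), 1.0, atol=1e-12)

    def test_factors_multiply_to_one(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(5.0, size=(300, 6)) * rng.integers(1, 4, size=6)
        f = de.tmm_factors(y)
        assert np.prod(f) == pytest.approx(1.0, abs=1e-12)

    def test_pure_depth_doubling_gives_unit_factor(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(20.0, size=200) + 1
        y = np.column_stack([base, base * 2, base, base])
        f = de.tmm_factors(y)
        # M values against the reference are constant, so the trimmed mean is 0
        assert f[1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_reference_implementation(self):
        # expected factors computed with edgeR 4.0.16 calcNormFactors(method="TMM")
        rng = np.random.default_rng(42)
        y = rng.poisson(rng.lognormal(1.5, 1.0, size=(200, 1))
                        * np.array([0.5, 1, 2, 1.5]), size=(200, 4))
        expected = [1.095312921, 0.963487354, 0.980685015, 0.966242712]
        np.testing.assert_allclose(de.tmm_factors(y), expected, rtol=1e-6)

    def test_zero_total_column_rejected(self):
        y = np.ones((10, 3))
        y[:, 1] = 0
        with pytest.raises(ValueError, match="zero-total column"):
            de.tmm_factors(y)


class TestFitDispersion:
    def test_poisson_data_yields_near_zero_common(self):
        counts, groups, _ = simulate_nb_groups(2000, 20, seed=6, phi=0.0,
                                               mean_count=5.0)
        fit = de.fit_dispersion(counts, groups)
        assert fit.common < 0.05

    def test_planted_dispersion_recovered(self):
        counts, groups, _ = simulate_nb_groups(2000, 100, seed=7, phi=0.4,
                                               mean_count=2.0)
        fit = de.fit_dispersion(counts, groups)
        assert 0.3 <= fit.common <= 0.5

    def test_infinite_prior_collapses_tagwise_to_common(self):
        counts, groups, _ = simulate_nb_groups(200, 30, seed=8, phi=0.2,
                                               mean_count=3.0)
        fit = de.fit_dispersion(counts, groups, prior_df=np.inf)
        np.testing.assert_allclose(fit.tagwise, fit.common)

    def test_single_replicate_group_rejected(self):
        counts = np.ones((10, 3), dtype=int)
        with pytest.raises(ValueError, match="replicates"):
            de.fit_dispersion(counts, np.array(["A", "A", "B"]))


class TestNbDeTest:
    def test_label_swap_negates_logfc_and_keeps_p(self):
        counts, groups, _ = simulate_nb_groups(400, 30, seed=9, phi=0.2,
                                               mean_count=4.0)
        a = de.nb_de_test(counts, groups, group_order=("A", "B"))
        b = de.nb_de_test(counts, groups, group_order=("B", "A"))
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-6)
        np.testing.assert_allclose(a["pvalue"], b["pvalue"], rtol=1e-6)

    def test_invariant_to_gene_and_cell_order(self):
        counts, groups, _ = simulate_nb_groups(300, 25, seed=10, phi=0.3,
                                               mean_count=3.0)
        res = de.nb_de_test(counts, groups, group_order=("A", "B"))
        rng = np.random.default_rng(0)
        gperm = rng.permutation(counts.shape[0])
        cperm = rng.permutation(counts.shape[1])
        res_p = de.nb_de_test(counts[gperm][:, cperm], groups[cperm],
                              gene_ids=[f"g{i}" for i in gperm],
                              group_order=("A", "B"))
        a = res.set_index("gene").sort_index()
        b = res_p.set_index("gene").sort_index()
        np.testing.assert_allclose(a["log2fc"], b["log2fc"], atol=1e-8)
        np.testing.assert_allclose(a["pvalue"], b["pvalue"], rtol=1e-6)

    def test_all_zero_genes_excluded(self):
        counts, groups, _ = simulate_nb_groups(50, 10, seed=11, phi=0.1,
                                               mean_count=2.0)
        counts[7, :] = 0
        res = de.nb_de_test(counts, groups, group_order=("A", "B"))
        assert "g7" not in set(res["gene"])

    def test_small_group_rejected(self):
        counts = np.ones((10, 5), dtype=int)
        groups = np.array(["A", "A", "B", "B", "B"])
        with pytest.raises(ValueError, match=">= 3 cells"):
            de.nb_de_test(counts, groups, group_order=("A", "B"))


class TestFindMarkers:
    def _toy(self, seed=0, n_in=60, n_out=60):
        rng = np.random.default_rng(seed)
        n = n_in + n_out
        counts = rng.poisson(2.0, size=(30, n))
        counts[0, :n_in] += rng.poisson(20.0, size=n_in)   # marker of T
        counts[1, :] = rng.binomial(1, 0.05, size=n)       # rare everywhere
        counts[28, :] += 1                                 # keep totals positive
        labels = np.array(["T"] * n_in + ["R"] * n_out)
        cm = make_count_matrix(counts)
        return cm, qc.lognormalize(cm), labels

    def test_exclusive_gene_is_significant_positive_marker(self):
        cm, norm, labels = self._toy()
        res = de.find_markers(cm, norm, labels)
        hit = res[(res["celltype"] == "T") & (res["gene"] == "G0")]
        assert len(hit) == 1
        assert hit["padj"].iloc[0] < 0.05
        assert hit["log2fc"].iloc[0] > 0

    def test_low_detection_gene_excluded_before_testing(self):
        cm, norm, labels = self._toy()
        res = de.find_markers(cm, norm, labels, min_pct=0.1)
        assert "G1" not in set(res["gene"])  # ~5% detection on both sides

    def test_all_reported_markers_have_positive_logfc(self):
        cm, norm, labels = self._toy(seed=3)
        res = de.find_markers(cm, norm, labels)
        assert (res["log2fc"] > 0).all()

    def test_lr_statistic_matches_mle_oracle(self):
        # 20-cell single-gene toy: compare against statsmodels Logit fits
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        x = rng.normal(1.0, 1.0, size=20)
        y = (rng.random(20) < 1 / (1 + np.exp(-(x - 1.0)))).astype(float)
        chi2 = de._logistic_lr_vectorized(x[None, :], y)[0]
        full = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        null = sm.Logit(y, np.ones((20, 1))).fit(disp=0)
        oracle = 2 * (full.llf - null.llf)
        assert chi2 == pytest.approx(oracle, abs=1e-6)

    def test_tiny_group_rejected(self):
        cm, norm, _ = self._toy()
        labels = np.array(["T"] * 2 + ["R"] * 118)
        with pytest.raises(ValueError, match="fewer than 3"):
            de.find_markers(cm, norm, labels)


class TestDownsampleBalanced:
    def _cm(self, n_tl=120, n_fl=80):
        n = n_tl + n_fl
        counts = np.ones((5, n), dtype=int)
        return make_count_matrix(
            counts,
            region=["TL"] * n_tl + ["FL"] * n_fl,
            subtype=["X"] * n,
        )

    def test_min_rule(self):
        cm = self._cm(120, 80)
        out = de.downsample_balanced(cm, "X", seed=0)
        counts = out.cell_meta["region"].value_counts()
        assert counts["TL"] == 80 and counts["FL"] == 80

    def test_equal_counts_unchanged(self):
        cm = self._cm(50, 50)
        out = de.downsample_balanced(cm, "X", seed=0)
        assert set(out.cell_ids) == set(cm.cell_ids)

    def test_seed_reproducible(self):
        cm = self._cm()
        a = de.downsample_balanced(cm, "X", seed=5)
        b = de.downsample_balanced(cm, "X", seed=5)
        assert list(a.cell_ids) == list(b.cell_ids)

    def test_too_few_cells_rejected(self):
        cm = self._cm(40, 2)
        with pytest.raises(ValueError, match="too few"):
            de.downsample_balanced(cm, "X", seed=0)


class TestClusterLogfc:
    def test_two_block_profiles_recovered(self):
        up = pd.DataFrame(np.tile([2.0, 2.0, 0.0], (10, 1)),
                          index=[f"U{i}" for i in range(10)])
        down = pd.DataFrame(np.tile([0.0, -2.0, -2.0], (8, 1)),
                            index=[f"D{i}" for i in range(8)])
        mat = pd.concat([up, down])
        assign, profiles = de.cluster_logfc(mat, k=2)
        assert assign.loc[[f"U{i}" for i in range(10)]].nunique() == 1
        assert assign.loc[[f"D{i}" for i in range(8)]].nunique() == 1
        assert assign.nunique() == 2
        assert len(profiles) == 2

    def test_identical_rows_cluster_together(self):
        mat = pd.DataFrame([[1.0, 0.0]] * 5 + [[9.0, 9.0]],
                           index=[f"A{i}" for i in range(5)] + ["B"])
        assign, _ = de.cluster_logfc(mat, k=2)
        assert assign.loc[[f"A{i}" for i in range(5)]].nunique() == 1

    def test_k_one_puts_everything_together(self):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3)))
        assign, _ = de.cluster_logfc(mat, k=1)
        assert assign.nunique() == 1

    def test_k_larger_than_genes_rejected(self):
        mat = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            de.cluster_logfc(mat, k=5)
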