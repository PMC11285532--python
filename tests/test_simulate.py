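import numpy as np
import pandas as pd
import pytest

from cellvuln.config import DISEASES, SimConfig
from cellvuln.genesets import gwas_select
from cellvuln.simulate import (
    simulate_counts,
    simulate_disease_degs,
    simulate_gwas_table,
    simulate_nb_groups,
    simulate_study,
)


class TestSimulateCounts:
    def test_same_seed_identical_matrices(self, small_sim_config):
        a, _ = simulate_counts(small_sim_config, seed=5)
        b, _ = simulate_counts(small_sim_config, seed=5)
        assert (a.counts != b.counts).nnz == 0
        assert list(a.cell_ids) == list(b.cell_ids)

    def test_planted_marker_shift_recovered(self):
        cfg = SimConfig()  # default: 3000 cells, EX-L2-3 has ~459 cells
        cm, truth = simulate_counts(cfg, seed=3)
        leaf = "EX-L2-3"
        markers = sorted(truth.marker_map[leaf])
        pos = {g: i for i, g in enumerate(cm.gene_ids)}
        dense = cm.counts.toarray().astype(float)
        rel = dense / dense.sum(axis=0, keepdims=True)
        in_t = (cm.cell_meta["subtype"] == leaf).to_numpy()
        idx = [pos[g] for g in markers]
        ratio = np.log2(rel[np.ix_(idx, np.flatnonzero(in_t))].mean(axis=1)
                        / rel[np.ix_(idx, np.flatnonzero(~in_t))].mean(axis=1))
        assert in_t.sum() >= 300
        assert abs(np.median(ratio) - cfg.marker_shift_log2) <= 0.3

    def test_zero_doublet_rate_gives_empty_truth(self, small_sim_config):
        import dataclasses
        cfg = dataclasses.replace(small_sim_config, doublet_rate=0.0)
        cm, truth = simulate_counts(cfg, seed=1)
        assert truth.doublets == frozenset()
        assert not cm.cell_meta["doublet"].any()

    def test_overdispersion_variance_exceeds_mean(self, small_counts):
        cm, _ = small_counts
        dense = cm.counts.toarray().astype(float)
        assert dense.shape[1] >= 900
        mean = dense.mean(axis=1)
        var = dense.var(axis=1, ddof=1)
        expressed = mean > 0.5
        # NB with phi > 0: Var = mu + phi mu^2 > mu for the vast majority
        assert (var[expressed] > mean[expressed]).mean() > 0.9

    def test_too_few_cells_per_region_rejected(self):
        cfg = SimConfig(n_genes=300, cells_per_subject=30)
        with pytest.raises(ValueError, match="cells"):
            simulate_counts(cfg, seed=0)

    def test_planted_genes_exist_and_are_finite(self, small_counts):
        cm, truth = small_counts
        genes = set(cm.gene_ids)
        for mapping in (truth.marker_map, truth.regional_map):
            for sub in mapping.values():
                assert set(sub) <= genes
                assert all(np.isfinite(v) and v != 0 for v in sub.values())


class TestSimulateGwasTable:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_selection_recovers_planted_map_exactly(self, seed):
        rng = np.random.default_rng(seed)
        gene_ids = [f"G{i}" for i in range(300)]
        planted = {d: sorted(rng.choice(gene_ids, size=15, replace=False))
                   for d in DISEASES}
        table, truth = simulate_gwas_table(gene_ids, DISEASES, n_snps=200,
                                           planted_map=planted, seed=seed)
        sel = gwas_select(table, background=None, p_max=1e-5)
        for d in DISEASES:
            assert sorted(sel.per_disease[d]["gene"]) == sorted(planted[d])
            merged = sel.per_disease[d].merge(truth[d], on="gene")
            np.testing.assert_allclose(merged["best_p_x"], merged["best_p_y"])

    def test_retained_p_is_minimum_over_snps(self):
        gene_ids = ["A", "B"]
        table, truth = simulate_gwas_table(gene_ids, ["BP"], n_snps=0,
                                           planted_map={"BP": ["A", "B"]}, seed=4)
        rec = table.records
        for g in ("A", "B"):
            best = rec[(rec["gene"] == g) & rec["genic"]]["p_value"].min()
            t = truth["BP"].set_index("gene").loc[g, "best_p"]
            assert best == pytest.approx(t)

    def test_pan_disorder_intersection_matches_plan(self):
        gene_ids = [f"G{i}" for i in range(200)]
        common = [f"G{i}" for i in range(10)]
        planted = {d: common + [f"G{20 + 10 * j + i}" for i in range(5)]
                   for j, d in enumerate(DISEASES)}
        table, _ = simulate_gwas_table(gene_ids, DISEASES, n_snps=100,
                                       planted_map=planted, seed=0)
        sel = gwas_select(table, None, 1e-5)
        assert sel.intersection == frozenset(common)

    def test_planted_gene_absent_from_universe_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            simulate_gwas_table(["A"], ["BP"], 10, {"BP": ["NOT_THERE"]}, seed=0)


class TestSimulateDiseaseDegs:
    def _regional_truth(self, n=600):
        rng = np.random.default_rng(9)
        signs = rng.choice([-1.0, 1.0], size=n)
        return {f"G{i}": signs[i] * 1.5 for i in range(n)}

    def test_full_concordance_all_signs_agree(self):
        truth_reg = self._regional_truth()
        gene_ids = [f"G{i}" for i in range(1500)]
        _, tables, truth = simulate_disease_degs(gene_ids, truth_reg, 1.0, seed=0,
                                                 diseases=["BP"], n_shared=200)
        shared = truth["BP"].dropna(subset=["sign_agree"])
        assert shared["sign_agree"].astype(bool).all()

    def test_full_anticoncordance_no_sign_agrees(self):
        truth_reg = self._regional_truth()
        gene_ids = [f"G{i}" for i in range(1500)]
        _, _, truth = simulate_disease_degs(gene_ids, truth_reg, -1.0, seed=0,
                                            diseases=["BP"], n_shared=200)
        shared = truth["BP"].dropna(subset=["sign_agree"])
        assert not shared["sign_agree"].astype(bool).any()

    def test_partial_concordance_matches_binomial_expectation(self):
        # concordance 0.2 over 500 shared genes: agreement ~ 0.6 +- 0.05
        truth_reg = self._regional_truth(600)
        gene_ids = [f"G{i}" for i in range(2000)]
        _, _, truth = simulate_disease_degs(gene_ids, truth_reg, 0.2, seed=1,
                                            diseases=["BP"], n_shared=500)
        shared = truth["BP"].dropna(subset=["sign_agree"])
        assert len(shared) == 500
        assert abs(shared["sign_agree"].mean() - 0.6) <= 0.05

    def test_planted_genes_pass_thresholds(self):
        truth_reg = self._regional_truth(100)
        gene_ids = [f"G{i}" for i in range(500)]
        sets, tables, _ = simulate_disease_degs(gene_ids, truth_reg, 0.5, seed=2,
                                                diseases=["BP"], n_shared=50,
                                                n_own=30, n_null=100)
        df = tables["BP"]
        planted = sets["BP"]
        sub = df[df["gene"].isin(planted)]
        assert (sub["log2fc"].abs() > 0.25).all()
        assert (sub["padj"] < 0.05).all()
        nulls = df[~df["gene"].isin(planted)]
        assert not ((nulls["log2fc"].abs() > 0.25) & (nulls["padj"] < 0.05)).any()

    def test_bad_concordance_rejected(self):
        with pytest.raises(ValueError, match="concordance"):
            simulate_disease_degs(["A"], {"A": 1.0}, 1.5, seed=0)


class TestSimulateNbGroups:
    def test_poisson_limit_variance_close_to_mean(self):
        counts, _, _ = simulate_nb_groups(500, 200, seed=0, phi=0.0, mean_count=5.0)
        ratio = counts.var(axis=1, ddof=1) / counts.mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.1

    def test_planted_fold_change_in_group_means(self):
        counts, groups, _ = simulate_nb_groups(300, 400, seed=1, log2fc=1.0,
                                               phi=0.1, mean_count=10.0)
        in_a = groups == "A"
        ratio = counts[:, in_a].mean(axis=1) / counts[:, ~in_a].mean(axis=1)
        assert np.median(np.log2(ratio)) == pytest.approx(1.0, abs=0.1)


def test_study_bundle_writes_all_interfaces(tmp_path, small_study):
    small_study.write(tmp_path / "study")
    d = tmp_path / "study"
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv", "cell_meta.tsv",
                 "gwas.tsv", "drugs.gmt", "pathways.gmt"):
        assert (d / name).exists(), name
    assert len(list((d / "disease_degs").glob("*.tsv"))) == 3
    assert (d / "truth" / "regional.tsv").exists()
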