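"""Stage orchestration: wires QC, DE, gene-set and network stages together.

Each ``stage_*`` function is a thin composition of library calls returning
plain tables; ``run_all`` executes the full pipeline on a study (synthetic or
read from disk) and writes every result table plus a manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import de, genesets, networks, qc, vulnerability
from .config import RunConfig
from .containers import CountMatrix, GeneSetCollection, GwasTable
from .genesets import GwasSelection, bh_adjust

logger = logging.getLogger(__name__)


def _timed(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - self.t0)

    return _Timer()


def analysis_types(cm: CountMatrix, min_per_region: int = 3) -> list:
    """Subtype labels with enough cells in both regions for the regional contrast."""
    meta = cm.cell_meta
    out = []
    for leaf in sorted(meta["subtype"].unique()):
        sub = meta[meta["subtype"] == leaf]
        n_tl = int((sub["region"] == "TL").sum())
        n_fl = int((sub["region"] == "FL").sum())
        if min(n_tl, n_fl) >= min_per_region:
            out.append(leaf)
        else:
            logger.warning("skipping %s: TL=%d FL=%d cells", leaf, n_tl, n_fl)
    return out


def stage_backgrounds(cm: CountMatrix, cfg: RunConfig) -> Dict[str, FrozenSet[str]]:
    """Expressed-gene universes: global plus one per subtype and major type."""
    scopes = (["global"]
              + sorted(cm.cell_meta["major_type"].unique())
              + sorted(cm.cell_meta["subtype"].unique()))
    out: Dict[str, FrozenSet[str]] = {}
    for scope in dict.fromkeys(scopes):
        try:
            bg = qc.expressed_background(cm, scope, cfg.expr_pctile,
                                         mode=cfg.expr_filter_mode)
            out[scope] = bg.genes
        except ValueError as e:
            logger.warning("background %s skipped: %s", scope, e)
    return out


def stage_regional_de(
    cm: CountMatrix,
    cfg: RunConfig,
    types: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Region-balanced NB differential expression, one table row per gene x type."""
    types = list(types) if types is not None else analysis_types(cm)
    frames = []
    for i, leaf in enumerate(types):
        with _timed(f"regional-de:{leaf}"):
            try:
                sub = de.downsample_balanced(cm, leaf, seed=cfg.seed + i, column="subtype")
            except ValueError as e:
                logger.warning("regional DE skipped for %s: %s", leaf, e)
                continue
            groups = sub.cell_meta["region"].to_numpy()
            counts = sub.counts
            factors = de.tmm_factors(counts)
            res = de.nb_de_test(counts, groups, gene_ids=sub.gene_ids,
                                factors=factors, group_order=("TL", "FL"),
                                prior_df=cfg.prior_df)
            res.insert(0, "celltype", leaf)
            frames.append(res)
    if not frames:
        raise ValueError("no cell type admitted a regional contrast")
    return pd.concat(frames, ignore_index=True)


def regional_deg_tables(regional: pd.DataFrame, cfg: RunConfig) -> Dict[str, pd.DataFrame]:
    """Thresholded DEGs per subtype (|log2FC| > cut, FDR < cut)."""
    out = {}
    for leaf, sub in regional.groupby("celltype"):
        out[leaf] = de.significant_degs(sub, cfg.de_logfc, cfg.de_fdr)
    return out


def tl_up_sets(deg_tables: Mapping[str, pd.DataFrame]) -> Dict[str, FrozenSet[str]]:
    """TL-upregulated genes per subtype (log2FC(TL/FL) above threshold, already filtered)."""
    return {leaf: frozenset(t[t["log2fc"] > 0]["gene"])
            for leaf, t in deg_tables.items()}


def per_type_enrichment(
    query_by_type: Mapping[str, Iterable[str]],
    target_sets: Mapping[str, Iterable[str]],
    backgrounds: Mapping[str, Iterable[str]],
    fallback_scope: str = "global",
) -> pd.DataFrame:
    """Hypergeometric enrichment with a type-specific background per query.

    Like :func:`cellvuln.genesets.enrich_table` but each query (a cell type's
    gene list) is tested inside its own expressed-gene universe; BH adjustment
    spans the whole table.
    """
    rows = []
    for ct in sorted(query_by_type):
        bg = backgrounds.get(ct, backgrounds.get(fallback_scope))
        if bg is None:
            raise ValueError(f"no background for scope {ct!r}")
        universe = frozenset(str(g).upper() for g in bg)
        q = frozenset(str(g).upper() for g in query_by_type[ct]) & universe
        for tname in sorted(target_sets):
            t = frozenset(str(g).upper() for g in target_sets[tname]) & universe
            k = len(q & t)
            p = genesets.hypergeom_upper(k, len(q), len(t), len(universe)) if q and t else 1.0
            rows.append((ct, tname, k, len(q), len(t), len(universe), p))
    out = pd.DataFrame(rows, columns=["query", "target", "k", "q", "t", "N", "pvalue"])
    out["padj"] = bh_adjust(out["pvalue"]) if len(out) else []
    out["score"] = -np.log10(out["padj"].clip(lower=np.finfo(float).tiny))
    out["proportion"] = np.where(out["t"] > 0, out["k"] / out["t"].clip(lower=1), 0.0)
    return out


@dataclass
class VulnerabilityRun:
    """Everything the integrative (vulnerability) stage produces."""

    regional: pd.DataFrame
    deg_tables: Dict[str, pd.DataFrame]
    tl_up: Dict[str, FrozenSet[str]]
    gwas_sel: GwasSelection
    gwas_enrichment: pd.DataFrame
    drug_enrichment: pd.DataFrame
    contrast: pd.DataFrame
    backgrounds: Dict[str, FrozenSet[str]]

    def ranking(self, target: str = "GWAS_union") -> pd.DataFrame:
        """Subtypes ordered by enrichment score for the given target."""
        tab = self.gwas_enrichment if target.startswith("GWAS") else self.drug_enrichment
        sub = tab[tab["target"] == target]
        return sub.sort_values(["score", "query"], ascending=[False, True],
                               kind="mergesort").reset_index(drop=True)


def run_vulnerability(
    cm: CountMatrix,
    gwas: GwasTable,
    drugs: GeneSetCollection,
    cfg: RunConfig,
    types: Optional[Iterable[str]] = None,
) -> VulnerabilityRun:
    """QC'd matrix -> regional DE -> GWAS/drug enrichment -> fold contrast.

    This is the integrative core shared by the ``vulnerability`` subcommand
    and the end-to-end recovery checks.
    """
    backgrounds = stage_backgrounds(cm, cfg)
    regional = stage_regional_de(cm, cfg, types)
    deg_tables = regional_deg_tables(regional, cfg)
    up = tl_up_sets(deg_tables)

    global_bg = qc.expressed_background(cm, "global", cfg.expr_pctile,
                                        mode=cfg.expr_filter_mode)
    gwas_sel = genesets.gwas_select(gwas, global_bg, cfg.gwas_p)

    gwas_targets = {f"GWAS_{d}": frozenset(df["gene"])
                    for d, df in gwas_sel.per_disease.items() if len(df)}
    gwas_targets["GWAS_union"] = gwas_sel.union
    gwas_enr = per_type_enrichment(up, gwas_targets, backgrounds)

    drug_targets = {f"DRUG_{c}": s for c, s in drugs.sets.items()}
    drug_targets["DRUG_union"] = drugs.union()
    drug_enr = per_type_enrichment(up, drug_targets, backgrounds)

    contrast = vulnerability.vulnerability_contrast(
        up, {d: frozenset(df["gene"]) for d, df in gwas_sel.per_disease.items()},
        dict(drugs.sets))
    return VulnerabilityRun(
        regional=regional, deg_tables=deg_tables, tl_up=up, gwas_sel=gwas_sel,
        gwas_enrichment=gwas_enr, drug_enrichment=drug_enr, contrast=contrast,
        backgrounds=backgrounds,
    )


def run_all(
    study,
    out_dir,
    cfg: Optional[RunConfig] = None,
    input_paths: Optional[dict] = None,
) -> dict:
    """Execute every stage on a study bundle and write all result files.

    ``study`` is a :class:`cellvuln.simulate.SimStudy`-like object exposing
    ``cm``, ``gwas``, ``drugs``, ``pathways`` and ``disease_degs``. Returns a
    summary dict (also written as JSON pieces under ``out_dir``).
    """
    cfg = cfg or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _timed("qc"):
        cm_f, report = qc.filter_cells(study.cm, cfg)
        norm = qc.lognormalize(cm_f)
        with open(out / "qc_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        backgrounds = stage_backgrounds(cm_f, cfg)
        bg_dir = out / "backgrounds"
        bg_dir.mkdir(exist_ok=True)
        for scope, genes in backgrounds.items():
            (bg_dir / f"{scope}.txt").write_text("\n".join(sorted(genes)) + "\n")

    with _timed("proportions"):
        counts = (cm_f.cell_meta.groupby(["major_type", "region"]).size()
                  .unstack(fill_value=0).reindex(columns=["TL", "FL"], fill_value=0))
        props = genesets.chisq_proportions(counts)
        props.to_csv(out / "proportions.tsv", sep="\t", index=False)

    with _timed("markers"):
        labels = cm_f.cell_meta["subtype"].to_numpy()
        markers = de.find_markers(cm_f, norm, labels,
                                  min_pct=cfg.marker_min_pct, logfc_min=cfg.marker_logfc)
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        msets = de.marker_sets(markers)

    with _timed("regional-de"):
        regional = stage_regional_de(cm_f, cfg)
        regional.to_csv(out / "regional_de.tsv", sep="\t", index=False,
                        float_format="%.6g")
        deg_tables = regional_deg_tables(regional, cfg)
        union_degs = sorted(set().union(*[set(t["gene"]) for t in deg_tables.values()]) or set())
        if union_degs:
            mat = pd.DataFrame(0.0, index=union_degs, columns=sorted(deg_tables))
            for leaf, t in deg_tables.items():
                mat.loc[t["gene"].tolist(), leaf] = t["log2fc"].to_numpy()
            k = min(cfg.n_logfc_clusters, len(mat))
            assign, profiles = de.cluster_logfc(mat, k=k)
            cl = assign.rename_axis("gene").reset_index()
            cl.to_csv(out / "logfc_clusters.tsv", sep="\t", index=False)

    with _timed("gwas-select"):
        global_bg = qc.expressed_background(cm_f, "global", cfg.expr_pctile,
                                            mode=cfg.expr_filter_mode)
        gwas_sel = genesets.gwas_select(study.gwas, global_bg, cfg.gwas_p)
        gwas_sel.to_frame().to_csv(out / "gwas_genes.tsv", sep="\t", index=False)

    with _timed("enrich"):
        gwas_marker = per_type_enrichment(
            msets, {f"GWAS_{d}": frozenset(df["gene"])
                    for d, df in gwas_sel.per_disease.items() if len(df)},
            backgrounds)
        gwas_marker.insert(0, "family", "gwas_x_markers")
        up = tl_up_sets(deg_tables)
        gwas_up = per_type_enrichment(
            up, {"GWAS_union": gwas_sel.union}, backgrounds)
        gwas_up.insert(0, "family", "gwas_x_tl_up")
        drug_up = per_type_enrichment(
            up, {f"DRUG_{c}": s for c, s in study.drugs.sets.items()} |
            {"DRUG_union": study.drugs.union()}, backgrounds)
        drug_up.insert(0, "family", "drug_x_tl_up")
        enrichment = pd.concat([gwas_marker, gwas_up, drug_up], ignore_index=True)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                          float_format="%.6g")

    with _timed("gsea"):
        gsea_frames = []
        for major in ("EX", "INH"):
            sub = markers[markers["celltype"].str.startswith(major)]
            if not len(sub):
                continue
            ranked = (sub.groupby("gene")["log2fc"].mean())
            res = genesets.gsea_preranked(
                ranked, study.pathways, nperm=cfg.gsea_nperm,
                weight=cfg.gsea_weight, seed=cfg.seed,
                min_size=cfg.gsea_min_size, max_size=cfg.gsea_max_size)
            res.insert(0, "ranking", major)
            gsea_frames.append(res)
        if gsea_frames:
            pd.concat(gsea_frames, ignore_index=True).to_csv(
                out / "gsea.tsv", sep="\t", index=False, float_format="%.6g")

    with _timed("network"):
        ora = genesets.ora_pathways(gwas_sel.union, study.pathways,
                                    backgrounds["global"], alpha=cfg.enrich_alpha)
        ora.to_csv(out / "pathway_ora.tsv", sep="\t", index=False, float_format="%.6g")
        pnet = networks.pathway_network(ora, dict(study.pathways.sets),
                                        alpha=cfg.enrich_alpha)
        networks.write_graph(pnet, out / "pathway_network_edges.tsv",
                             out / "pathway_network.graphml")

        strict = gwas_sel.strict(cfg.gwas_strict_p)
        vuln_leaf = getattr(getattr(study, "truth", None), "vulnerable_subtype", None)
        scope = vuln_leaf if vuln_leaf in set(cm_f.cell_meta["subtype"]) else None
        if scope is None:
            scope = sorted(cm_f.cell_meta["subtype"].unique())[0]
        coexpr_genes = sorted((strict.union & set(cm_f.gene_ids))
                              or list(gwas_sel.union & set(cm_f.gene_ids))[:30])
        if len(coexpr_genes) >= 2:
            cnet = networks.coexpression_network(
                norm, cm_f, coexpr_genes, scope, alpha=cfg.spearman_alpha)
            networks.write_graph(cnet, out / "network_edges.tsv", out / "network.graphml")

    with _timed("concordance"):
        conc = vulnerability.concordance(
            deg_tables, study.disease_degs, backgrounds,
            gwas_genes=gwas_sel.union, drug_genes=study.drugs.union(),
            disease_logfc_min=cfg.disease_logfc, disease_fdr_max=cfg.disease_fdr)
        conc.to_csv(out / "concordance.tsv", sep="\t", index=False, float_format="%.6g")

    with _timed("vulnerability"):
        contrast = vulnerability.vulnerability_contrast(
            up, {d: frozenset(df["gene"]) for d, df in gwas_sel.per_disease.items()},
            dict(study.drugs.sets))
        payload = contrast.to_dict(orient="records")
        with open(out / "vulnerability.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        contrast.drop(columns=["breakdown"]).to_csv(
            out / "vulnerability.tsv", sep="\t", index=False, float_format="%.6g")

    from .io import write_manifest
    write_manifest(out, cfg.to_dict(), input_paths or {})
    return {
        "qc": report.to_dict(),
        "n_markers": int(len(markers)),
        "n_regional_degs": int(sum(len(t) for t in deg_tables.values())),
        "n_gwas_genes": int(len(gwas_sel.union)),
    }
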