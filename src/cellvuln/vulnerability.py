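"""Integration of regional DE with disease DEGs, GWAS sets and drug targets.

Three summaries come out of this stage:

* concordance — for each (cell subtype, disease): the enrichment of the
  subtype's regional DEGs in the disease's case-control DEGs, and the
  sign-agreement quadrant fractions of the shared genes;
* vulnerability — for each subtype: the fraction of its TL-upregulated genes
  that are GWAS genes and the fraction that are psychoactive-drug targets,
  with the drug/GWAS fold contrast;
* proportion reporting — plain percentage formatting with half-up rounding,
  used wherever a "k of n (x%)" figure is printed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .genesets import bh_adjust, hypergeom_upper

logger = logging.getLogger(__name__)


def proportion_report(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage 100 * numerator / denominator with half-up rounding.

    Default one decimal place; pass ``decimals=0`` for whole-percent display.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def disease_deg_filter(
    table: pd.DataFrame,
    logfc_min: float = 0.25,
    fdr_max: float = 0.05,
) -> Dict[str, FrozenSet[str]]:
    """Split a case-control DEG table into up/down gene sets.

    Keeps genes with |log2FC| above ``logfc_min`` and adjusted p below
    ``fdr_max``; the sign of log2FC routes each kept gene to "up" or "down".
    """
    for col in ("gene", "log2fc", "padj"):
        if col not in table.columns:
            raise ValueError(f"DEG table missing column {col!r}")
    kept = table[(table["log2fc"].abs() > logfc_min) & (table["padj"] < fdr_max)]
    genes = kept["gene"].astype(str).str.upper()
    return {
        "up": frozenset(genes[kept["log2fc"] > 0]),
        "down": frozenset(genes[kept["log2fc"] < 0]),
    }


@dataclass
class ConcordanceRow:
    celltype: str
    disease: str
    shared: pd.DataFrame           # gene, log2fc_region, log2fc_disease
    quadrants: Tuple[float, float, float, float]  # up-up, up-down, down-up, down-down
    k: int
    q: int
    t: int
    N: int
    pvalue: float


def concordance(
    regional_degs: Mapping[str, pd.DataFrame],
    disease_degs: Mapping[str, pd.DataFrame],
    backgrounds: Mapping[str, Iterable[str]],
    gwas_genes: Optional[Iterable[str]] = None,
    drug_genes: Optional[Iterable[str]] = None,
    disease_logfc_min: float = 0.25,
    disease_fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Overlap enrichment and sign-concordance of regional vs disease DEGs.

    ``regional_degs`` maps cell (sub)type -> thresholded regional DE table
    (columns gene, log2fc); ``disease_degs`` maps disease -> full case-control
    DEG table (gene, log2fc, padj); ``backgrounds`` maps cell type -> its
    expressed-gene universe. The enrichment p is hypergeometric on the overlap
    within the type's background and BH-adjusted across all (type, disease)
    pairs. Quadrant fractions are computed over shared genes with nonzero fold
    changes on both axes (unsigned genes are excluded from the denominator and
    logged). Genes additionally present in the GWAS or drug sets are flagged.
    """
    gwas_set = frozenset(str(g).upper() for g in gwas_genes) if gwas_genes else frozenset()
    drug_set = frozenset(str(g).upper() for g in drug_genes) if drug_genes else frozenset()

    rows = []
    for ct in sorted(regional_degs):
        reg = regional_degs[ct]
        universe = frozenset(str(g).upper() for g in backgrounds[ct])
        reg_genes = frozenset(reg["gene"].astype(str).str.upper()) & universe
        reg_fc = dict(zip(reg["gene"].astype(str).str.upper(), reg["log2fc"]))
        for disease in sorted(disease_degs):
            dd = disease_degs[disease]
            sets = disease_deg_filter(dd, disease_logfc_min, disease_fdr_max)
            dis_genes = (sets["up"] | sets["down"]) & universe
            dis_fc = dict(zip(dd["gene"].astype(str).str.upper(), dd["log2fc"]))
            if not dis_genes:
                logger.warning("concordance: disease %s empty after filtering in %s", disease, ct)
                rows.append((ct, disease, 0, len(reg_genes), 0, len(universe),
                             np.nan, np.nan, np.nan, np.nan, np.nan, 0, 0))
                continue
            shared = sorted(reg_genes & dis_genes)
            k = len(shared)
            p = hypergeom_upper(k, len(reg_genes), len(dis_genes), len(universe))
            signed = [(g, reg_fc[g], dis_fc[g]) for g in shared
                      if reg_fc.get(g, 0) != 0 and dis_fc.get(g, 0) != 0]
            n_dropped = k - len(signed)
            if n_dropped:
                logger.info("concordance: %s/%s dropped %d zero-FC shared genes",
                            ct, disease, n_dropped)
            if signed:
                uu = sum(1 for _, a, b in signed if a > 0 and b > 0) / len(signed)
                ud = sum(1 for _, a, b in signed if a > 0 and b < 0) / len(signed)
                du = sum(1 for _, a, b in signed if a < 0 and b > 0) / len(signed)
                dd_frac = sum(1 for _, a, b in signed if a < 0 and b < 0) / len(signed)
            else:
                uu = ud = du = dd_frac = np.nan
            n_gwas = sum(1 for g in shared if g in gwas_set)
            n_drug = sum(1 for g in shared if g in drug_set)
            rows.append((ct, disease, k, len(reg_genes), len(dis_genes), len(universe),
                         p, uu, ud, du, dd_frac, n_gwas, n_drug))

    out = pd.DataFrame(rows, columns=[
        "celltype", "disease", "k", "q", "t", "N", "pvalue",
        "frac_up_up", "frac_up_down", "frac_down_up", "frac_down_down",
        "n_shared_gwas", "n_shared_drug",
    ])
    tested = out["pvalue"].notna()
    out["padj"] = np.nan
    if tested.any():
        out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "pvalue"])
    return out


def vulnerability_contrast(
    tl_up_by_type: Mapping[str, Iterable[str]],
    gwas_sets: Mapping[str, Iterable[str]],
    drug_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Fraction of TL-upregulated genes hitting GWAS genes vs drug targets.

    For each cell (sub)type: the number and fraction of its TL-upregulated
    genes inside the GWAS union (across diseases) and inside the drug-target
    union (across classes), the drug/GWAS fold contrast (defined only when the
    GWAS fraction is positive), and a per-class / per-disease breakdown in the
    ``breakdown`` column (JSON-serializable dict). Unions deduplicate, so
    listing a drug class twice cannot inflate the contrast.
    """
    gwas_union: FrozenSet[str] = frozenset()
    for genes in gwas_sets.values():
        gwas_union |= frozenset(str(g).upper() for g in genes)
    drug_union: FrozenSet[str] = frozenset()
    for genes in drug_sets.values():
        drug_union |= frozenset(str(g).upper() for g in genes)

    rows = []
    for ct in sorted(tl_up_by_type):
        up = frozenset(str(g).upper() for g in tl_up_by_type[ct])
        n_up = len(up)
        if n_up == 0:
            rows.append((ct, 0, 0, np.nan, 0, np.nan, np.nan, {}))
            continue
        n_gwas = len(up & gwas_union)
        n_drug = len(up & drug_union)
        f_gwas = n_gwas / n_up
        f_drug = n_drug / n_up
        fold = (f_drug / f_gwas) if f_gwas > 0 else np.nan
        breakdown = {
            "gwas": {d: len(up & frozenset(str(g).upper() for g in genes))
                     for d, genes in sorted(gwas_sets.items())},
            "drug": {c: len(up & frozenset(str(g).upper() for g in genes))
                     for c, genes in sorted(drug_sets.items())},
        }
        rows.append((ct, n_up, n_gwas, f_gwas, n_drug, f_drug, fold, breakdown))

    return pd.DataFrame(rows, columns=[
        "celltype", "n_tl_up", "n_gwas", "frac_gwas",
        "n_drug", "frac_drug", "fold_contrast", "breakdown",
    ])
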