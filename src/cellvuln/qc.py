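"""Cell-level quality control, log-normalization and expressed-gene backgrounds.

The QC filter chain removes, in order: cells outside the UMI band
[min_umi, max_umi]; cells with mitochondrial content above 10%; cells whose
detected-gene count falls outside the 5th-95th percentile of the
post-previous-filter distribution; and flagged doublets. Each cell is counted
against the first rule it fails, so the report categories partition removals.

"Expressed" backgrounds — the gene universes behind every enrichment test —
keep genes whose detection count (cells with at least one UMI) lies inside a
percentile band of the nonzero detection-count distribution, computed either
globally or within one cell (sub)type.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .config import RunConfig
from .containers import CountMatrix, ExpressedBackground, QcReport


def filter_cells(cm: CountMatrix, cfg: Optional[RunConfig] = None) -> Tuple[CountMatrix, QcReport]:
    """Apply the four QC rules in order and return the kept cells plus a tally."""
    cfg = cfg or RunConfig()
    meta = cm.cell_meta
    total = meta["total_umi"].to_numpy()
    mito = meta["mito_fraction"].to_numpy()
    ngenes = meta["n_genes_detected"].to_numpy()
    doublet = meta["doublet"].to_numpy()

    n_in = cm.n_cells
    alive = np.ones(n_in, dtype=bool)

    fail_umi = (total < cfg.min_umi) | (total > cfg.max_umi)
    n_umi = int(np.sum(alive & fail_umi))
    alive &= ~fail_umi

    fail_mito = mito > cfg.mito_max
    n_mito = int(np.sum(alive & fail_mito))
    alive &= ~fail_mito

    if alive.any():
        lo, hi = np.percentile(ngenes[alive], cfg.gene_pctile)
        fail_pct = (ngenes < lo) | (ngenes > hi)
    else:
        fail_pct = np.zeros(n_in, dtype=bool)
    n_pct = int(np.sum(alive & fail_pct))
    alive &= ~fail_pct

    n_dbl = int(np.sum(alive & doublet))
    alive &= ~doublet

    if not alive.any():
        raise ValueError("empty matrix after QC: all cells removed")

    report = QcReport(
        n_cells_in=n_in,
        n_removed_umi=n_umi,
        n_removed_mito=n_mito,
        n_removed_gene_pctile=n_pct,
        n_removed_doublet=n_dbl,
        n_cells_out=int(alive.sum()),
        thresholds={
            "min_umi": cfg.min_umi, "max_umi": cfg.max_umi,
            "mito_max": cfg.mito_max, "gene_pctile": list(cfg.gene_pctile),
        },
    )
    return cm.subset_cells(alive), report


def lognormalize(cm: CountMatrix, scale: float = 1e4) -> sp.csc_matrix:
    """Library-size normalize to ``scale`` counts per cell, then ln(1 + x).

    Returns a sparse genes x cells matrix aligned with ``cm``; zeros stay zero,
    so sparsity is preserved. Doubling every count in a cell leaves its
    normalized vector unchanged.
    """
    totals = np.asarray(cm.counts.sum(axis=0), dtype=float).ravel()
    if (totals == 0).any():
        bad = cm.cell_ids[int(np.flatnonzero(totals == 0)[0])]
        raise ValueError(f"cannot normalize: cell {bad!r} has zero total counts")
    mat = cm.counts.astype(float).tocsc(copy=True)
    # scale column c by scale / total_c, then log1p on stored entries
    col_scale = scale / totals
    mat.data *= np.repeat(col_scale, np.diff(mat.indptr))
    np.log1p(mat.data, out=mat.data)
    return mat


def detection_counts(cm: CountMatrix, cell_idx: Optional[np.ndarray] = None) -> np.ndarray:
    """Number of cells (within the given subset) with at least one UMI, per gene."""
    counts = cm.counts if cell_idx is None else cm.counts[:, cell_idx]
    return np.asarray((counts > 0).sum(axis=1)).ravel()


def expressed_background(
    cm: CountMatrix,
    scope: str = "global",
    pctile: Tuple[float, float] = (10.0, 90.0),
    mode: str = "gene_detection",
) -> ExpressedBackground:
    """Genes counted as expressed within a scope, by the detection-percentile rule.

    ``scope`` is "global" or the name of a major type / subtype. In the default
    ``gene_detection`` mode, a gene is kept when its detection count lies inside
    [P_low, P_high] of the detection-count distribution over genes detected at
    least once in the scope. The alternative ``cell_percentile`` mode instead
    restricts to cells whose detected-gene count and total UMI both lie inside
    the per-cell percentile band, and keeps genes detected in at least one of
    those cells.
    """
    if scope == "global":
        idx = np.arange(cm.n_cells)
    else:
        meta = cm.cell_meta
        mask = (meta["subtype"].to_numpy() == scope) | (meta["major_type"].to_numpy() == scope)
        idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"no cells in scope {scope!r}")
    if idx.size < 10:
        raise ValueError(f"scope {scope!r} has only {idx.size} cells; need >= 10")

    if mode == "gene_detection":
        det = detection_counts(cm, idx)
        nonzero = det[det > 0]
        if nonzero.size == 0:
            raise ValueError(f"no detected genes in scope {scope!r}")
        lo, hi = np.percentile(nonzero, pctile)
        keep = (det > 0) & (det >= lo) & (det <= hi)
    elif mode == "cell_percentile":
        meta = cm.cell_meta.iloc[idx]
        ng = meta["n_genes_detected"].to_numpy()
        tu = meta["total_umi"].to_numpy()
        ng_lo, ng_hi = np.percentile(ng, pctile)
        tu_lo, tu_hi = np.percentile(tu, pctile)
        cell_keep = (ng >= ng_lo) & (ng <= ng_hi) & (tu >= tu_lo) & (tu <= tu_hi)
        det = detection_counts(cm, idx[cell_keep])
        keep = det > 0
    else:
        raise ValueError(f"unknown expressed-background mode {mode!r}")

    genes = frozenset(np.asarray(cm.gene_ids)[keep])
    return ExpressedBackground(scope=scope, genes=genes, pctile=tuple(pctile))
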