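"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp

CELL_META_COLUMNS = ("subject", "region", "major_type", "subtype", "doublet")
UNKNOWN = "unknown"


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with per-cell and per-gene metadata.

    ``cell_meta`` carries subject, region, major_type, subtype and doublet flag
    plus derived columns (total_umi, n_genes_detected, mito_fraction) that are
    recomputed from the counts on construction. ``gene_meta`` carries the
    mitochondrial flag (symbols starting with "MT-").
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame = None
    gene_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.nnz and not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids must be unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell barcodes must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        else:
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)
        for col in CELL_META_COLUMNS:
            if col not in self.cell_meta.columns:
                self.cell_meta[col] = False if col == "doublet" else UNKNOWN
        self.cell_meta["doublet"] = self.cell_meta["doublet"].fillna(False).astype(bool)
        for col in ("subject", "region", "major_type", "subtype"):
            self.cell_meta[col] = self.cell_meta[col].fillna(UNKNOWN).astype(str)

        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=self.gene_ids)
        else:
            self.gene_meta = self.gene_meta.reindex(self.gene_ids)
        if "mito" not in self.gene_meta.columns:
            self.gene_meta["mito"] = [g.upper().startswith("MT-") for g in self.gene_ids]
        self.gene_meta["mito"] = self.gene_meta["mito"].fillna(False).astype(bool)

        self._refresh_derived()

    def _refresh_derived(self) -> None:
        counts = self.counts
        total = np.asarray(counts.sum(axis=0)).ravel()
        ngenes = np.asarray((counts > 0).sum(axis=0)).ravel()
        mito_mask = self.gene_meta["mito"].to_numpy()
        if mito_mask.any():
            mito_total = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()
        else:
            mito_total = np.zeros_like(total)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
        self.cell_meta["total_umi"] = total.astype(int)
        self.cell_meta["n_genes_detected"] = ngenes.astype(int)
        self.cell_meta["mito_fraction"] = mito_frac

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_meta=self.gene_meta.copy(),
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[idx, :],
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids.copy(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.iloc[idx].copy(),
        )

    def cells_of(self, label: str, column: str = "subtype") -> np.ndarray:
        """Indices of cells whose subtype (or other metadata column) equals label."""
        return np.flatnonzero(self.cell_meta[column].to_numpy() == label)

    def to_anndata(self):
        import anndata
        return anndata.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.copy(),
        )


VALID_CATEGORIES = ("pathway", "drug", "marker_reference", "disease_deg", "gwas")


@dataclass
class GeneSetCollection:
    """Named gene sets with a provenance category.

    Symbols are uppercase-normalized so that GWAS tables, GMT files and the
    expression matrix agree on gene identity.
    """

    sets: Dict[str, FrozenSet[str]]
    category: str = "pathway"

    def __post_init__(self) -> None:
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        norm = {}
        for name, genes in self.sets.items():
            genes = frozenset(str(g).upper() for g in genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            norm[name] = genes
        self.sets = norm

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> FrozenSet[str]:
        return self.sets[name]

    def names(self) -> list:
        return list(self.sets)

    def union(self) -> FrozenSet[str]:
        out: FrozenSet[str] = frozenset()
        for genes in self.sets.values():
            out = out | genes
        return out

    def restricted_to(self, universe: Iterable[str], drop_empty: bool = True) -> "GeneSetCollection":
        uni = frozenset(str(g).upper() for g in universe)
        kept = {}
        for name, genes in self.sets.items():
            inter = genes & uni
            if inter or not drop_empty:
                kept[name] = inter if inter else genes
        return GeneSetCollection(sets=kept, category=self.category)


@dataclass
class GwasTable:
    """SNP-to-gene association records for one or more diseases.

    ``records`` has one row per (snp, gene) pair after multi-gene SNP rows are
    expanded: columns snp, gene, disease, p_value, genic.
    """

    records: pd.DataFrame

    REQUIRED = ("snp", "gene", "disease", "p_value", "genic")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"GwasTable missing columns: {missing}")
        rec = self.records.copy()
        rec["gene"] = rec["gene"].astype(str).str.upper()
        p = pd.to_numeric(rec["p_value"], errors="raise")
        if ((p <= 0) | (p > 1)).any():
            bad = int(np.flatnonzero((p <= 0) | (p > 1))[0])
            raise ValueError(f"p_value outside (0, 1] at record {bad}")
        rec["p_value"] = p
        rec["genic"] = rec["genic"].astype(bool)
        self.records = rec.reset_index(drop=True)

    @property
    def diseases(self) -> list:
        return sorted(self.records["disease"].unique())


@dataclass
class ExpressedBackground:
    """Genes considered "expressed" within a scope, used as enrichment universe."""

    scope: str
    genes: FrozenSet[str]
    pctile: tuple

    def __post_init__(self) -> None:
        self.genes = frozenset(str(g).upper() for g in self.genes)
        if not self.genes:
            raise ValueError(f"empty expressed background for scope {self.scope!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in self.genes


@dataclass
class QcReport:
    """Per-rule cell-removal tally; each cell is counted once, at its first failing rule."""

    n_cells_in: int
    n_removed_umi: int
    n_removed_mito: int
    n_removed_gene_pctile: int
    n_removed_doublet: int
    n_cells_out: int
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        removed = (self.n_removed_umi + self.n_removed_mito
                   + self.n_removed_gene_pctile + self.n_removed_doublet)
        if self.n_cells_out != self.n_cells_in - removed:
            raise ValueError("QcReport counts are inconsistent")

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_removed_umi": self.n_removed_umi,
            "n_removed_mito": self.n_removed_mito,
            "n_removed_gene_pctile": self.n_removed_gene_pctile,
            "n_removed_doublet": self.n_removed_doublet,
            "n_cells_out": self.n_cells_out,
            "thresholds": self.thresholds,
        }
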