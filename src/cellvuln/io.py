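"""Readers and writers for the external formats the pipeline touches.

Count matrices use the 10x MatrixMarket triplet convention (matrix.mtx +
features.tsv + barcodes.tsv, genes x cells) with an optional cell_meta.tsv
keyed by barcode. Gene sets use GMT. GWAS associations use a flat TSV with
one row per SNP and comma-separated mapped genes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, GeneSetCollection, GwasTable

PathLike = Union[str, Path]

_TRUTHY = {"1", "true", "yes", "genic", "t"}
_FALSY = {"0", "false", "no", "intergenic", "f"}


def _dedupe_symbols(symbols) -> list:
    """Disambiguate duplicate symbols with ``.1``, ``.2`` suffixes in file order."""
    seen: dict = {}
    out = []
    for s in symbols:
        n = seen.get(s, 0)
        out.append(s if n == 0 else f"{s}.{n}")
        seen[s] = n + 1
    return out


def read_10x(dir_path: PathLike) -> CountMatrix:
    """Read a 10x-convention MatrixMarket triplet directory into a CountMatrix.

    Expects ``matrix.mtx`` (genes x cells), ``features.tsv`` (one gene per
    line; symbol in the second column if present, else the first) and
    ``barcodes.tsv``. An optional ``cell_meta.tsv`` keyed by barcode supplies
    subject / region / major_type / subtype / doublet; missing fields are
    filled with the explicit ``"unknown"`` sentinel.
    """
    d = Path(dir_path)
    mtx_path = d / "matrix.mtx"
    feat_path = d / "features.tsv"
    bc_path = d / "barcodes.tsv"
    for p in (mtx_path, feat_path, bc_path):
        if not p.exists():
            raise FileNotFoundError(f"missing {p}")

    mat = scipy.io.mmread(str(mtx_path))
    mat = sp.csc_matrix(mat)
    if mat.nnz and not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat.data, np.round(mat.data)):
            raise ValueError(f"non-integer values in {mtx_path}")
        mat = mat.astype(np.int64)

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].tolist() \
        if bc_path.stat().st_size else []
    if len(barcodes) == 0:
        raise ValueError(f"zero cells: {bc_path} is empty")
    symbol_col = 1 if feats.shape[1] >= 2 else 0
    symbols = [s.upper() for s in feats[symbol_col].tolist()]

    if mat.shape[0] != len(symbols):
        raise ValueError(
            f"dimension mismatch: matrix.mtx declares {mat.shape[0]} genes but "
            f"{feat_path} has {len(symbols)} lines")
    if mat.shape[1] != len(barcodes):
        raise ValueError(
            f"dimension mismatch: matrix.mtx declares {mat.shape[1]} cells but "
            f"{bc_path} has {len(barcodes)} lines")

    gene_ids = _dedupe_symbols(symbols)

    meta_path = d / "cell_meta.tsv"
    cell_meta = None
    if meta_path.exists():
        cell_meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        if "barcode" not in cell_meta.columns:
            raise ValueError(f"{meta_path} must have a 'barcode' column")
        cell_meta = cell_meta.set_index("barcode")
        if "doublet" in cell_meta.columns:
            cell_meta["doublet"] = cell_meta["doublet"].str.lower().isin(_TRUTHY)

    return CountMatrix(
        counts=mat,
        gene_ids=np.array(gene_ids, dtype=object),
        cell_ids=np.array(barcodes, dtype=object),
        cell_meta=cell_meta,
    )


def write_10x(cm: CountMatrix, dir_path: PathLike) -> None:
    """Write the triplet + cell_meta.tsv so that read_10x round-trips exactly."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(cm.counts), field="integer")
    feats = pd.DataFrame({
        0: cm.gene_ids,
        1: cm.gene_ids,
        2: ["Gene Expression"] * cm.n_genes,
    })
    feats.to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)
    meta = cm.cell_meta[["subject", "region", "major_type", "subtype", "doublet"]].copy()
    meta.insert(0, "barcode", cm.cell_ids)
    meta.to_csv(d / "cell_meta.tsv", sep="\t", index=False)


def read_gmt(path: PathLike, category: str = "pathway") -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``name<TAB>description<TAB>gene...`` lines."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = frozenset(g.upper() for g in genes)
    return GeneSetCollection(sets=sets, category=category)


def write_gmt(gsc: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name in sorted(gsc.sets):
            genes = "\t".join(sorted(gsc.sets[name]))
            fh.write(f"{name}\t{gsc.category}\t{genes}\n")


def read_gwas_table(path: PathLike) -> GwasTable:
    """Read a GWAS association TSV and expand multi-gene SNP rows.

    Columns: snp, genes (comma-separated symbols), disease, p_value,
    genic_flag. A SNP mapped to several genes yields one record per gene,
    because every mapped gene is a candidate.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp", "genes", "disease", "p_value", "genic_flag"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    rows = []
    for i, row in df.iterrows():
        try:
            p = float(row["p_value"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: non-numeric p_value {row['p_value']!r} at row {i}")
        if not np.isfinite(p) or not (0 < p <= 1):
            raise ValueError(f"{path}: p_value {p} outside (0, 1] at row {i}")
        flag = str(row["genic_flag"]).strip().lower()
        if flag in _TRUTHY:
            genic = True
        elif flag in _FALSY:
            genic = False
        else:
            raise ValueError(f"{path}: unrecognized genic_flag {row['genic_flag']!r} at row {i}")
        for gene in str(row["genes"]).split(","):
            gene = gene.strip()
            if gene:
                rows.append((row["snp"], gene.upper(), row["disease"], p, genic))
    rec = pd.DataFrame(rows, columns=["snp", "gene", "disease", "p_value", "genic"])
    return GwasTable(records=rec)


def write_gwas_table(gt: GwasTable, path: PathLike) -> None:
    """Write one row per (snp, disease), re-collapsing genes to a comma list."""
    rec = gt.records
    grouped = (rec.groupby(["snp", "disease", "p_value", "genic"], sort=True)["gene"]
               .apply(lambda g: ",".join(sorted(g))).reset_index())
    out = grouped.rename(columns={"gene": "genes", "genic": "genic_flag"})
    out = out[["snp", "genes", "disease", "p_value", "genic_flag"]]
    out["genic_flag"] = np.where(out["genic_flag"], "genic", "intergenic")
    out.to_csv(path, sep="\t", index=False)


def file_sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: PathLike, config_dict: dict, inputs: dict,
                   outputs: Optional[list] = None) -> Path:
    """Write manifest.json: config echo, seed, input checksums, output checksums."""
    import cellvuln
    out_dir = Path(out_dir)
    if outputs is None:
        outputs = sorted(p for p in out_dir.rglob("*")
                         if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "cellvuln",
        "version": getattr(cellvuln, "__version__", "unknown"),
        "config": config_dict,
        "inputs": {str(k): file_sha256(v) for k, v in inputs.items()},
        "outputs": {str(p.relative_to(out_dir)): file_sha256(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
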