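"""Pathway-similarity and gene co-expression networks.

Pathway networks connect significantly enriched pathways by Jaccard
similarity of their gene sets. Co-expression networks connect genes by
Spearman rank correlation computed across the cells of one compartment
(e.g. one inhibitory subtype), retaining edges with p below alpha; no
multiple-testing correction is applied to edges by default, matching the
raw-p convention of the analysis this package implements.
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st

from .containers import CountMatrix
from .genesets import bh_adjust

logger = logging.getLogger(__name__)


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A n B| / |A u B|."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def pathway_network(
    sig_pathways: pd.DataFrame,
    pathway_genes: Dict[str, Set[str]],
    annotations: Optional[Dict[str, str]] = None,
    alpha: float = 0.05,
) -> nx.Graph:
    """Jaccard similarity network over significantly enriched pathways.

    ``sig_pathways`` is an enrichment table with columns ``pathway`` and
    ``padj``; only rows with padj < alpha become nodes. Edges carry the
    Jaccard coefficient of the two gene sets and zero-similarity pairs are
    dropped. ``annotations`` maps pathway -> high-level category label.
    """
    keep = sig_pathways[sig_pathways["padj"] < alpha]["pathway"].tolist()
    g = nx.Graph()
    for name in keep:
        g.add_node(name, annotation=(annotations or {}).get(name, ""))
    if len(keep) < 2:
        logger.warning("pathway_network: only %d significant pathways, no edges", len(keep))
        return g
    for a, b in itertools.combinations(sorted(keep), 2):
        w = jaccard(pathway_genes[a], pathway_genes[b])
        if w > 0:
            g.add_edge(a, b, weight=w)
    return g


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    n = len(x)
    rx = st.rankdata(x)
    ry = st.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_edge(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Tie-corrected Spearman correlation with a two-sided p-value.

    Uses the t approximation with n-2 degrees of freedom for n > 9 and an
    exact permutation p for n <= 9 (where the approximation is poorest).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    rho = float(np.corrcoef(st.rankdata(x), st.rankdata(y))[0, 1])
    n = x.size
    if n <= 9:
        p = _spearman_exact_p(x, y, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * st.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def coexpression_network(
    norm: sp.spmatrix,
    cm: CountMatrix,
    genes: Sequence[str],
    cell_scope: str,
    alpha: float = 0.05,
    adjust: bool = False,
    annotations: Optional[Dict[str, str]] = None,
) -> nx.Graph:
    """Spearman co-expression network among ``genes`` within one cell scope.

    All gene pairs are tested across the cells of ``cell_scope`` (a subtype or
    major-type label); edges with (optionally BH-adjusted) p < alpha are
    retained with the correlation as weight. Pairwise p-values use the t
    approximation with n-2 df.
    """
    meta = cm.cell_meta
    mask = (meta["subtype"].to_numpy() == cell_scope) | (meta["major_type"].to_numpy() == cell_scope)
    idx = np.flatnonzero(mask)
    if idx.size < 4:
        raise ValueError(f"scope {cell_scope!r} has {idx.size} cells; need >= 4")

    genes = [str(g).upper() for g in genes]
    gene_pos = {g: i for i, g in enumerate(cm.gene_ids)}
    missing = [g for g in genes if g not in gene_pos]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    rows = [gene_pos[g] for g in genes]
    X = np.asarray(norm[rows][:, idx].todense(), dtype=float)

    n = idx.size
    ranks = np.apply_along_axis(st.rankdata, 1, X)
    sd = ranks.std(axis=1)
    constant = sd == 0
    rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 1.0)

    g = nx.Graph()
    for gene in genes:
        g.add_node(gene, annotation=(annotations or {}).get(gene, ""))

    iu, ju = np.triu_indices(len(genes), k=1)
    valid = ~(constant[iu] | constant[ju])
    r = np.clip(rho[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * st.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    if adjust and valid.any():
        p_adj = p.copy()
        p_adj[valid] = bh_adjust(p[valid])
        p = p_adj
    for a, b, rr, pp, ok in zip(iu, ju, r, p, valid):
        if ok and pp < alpha:
            g.add_edge(genes[a], genes[b], weight=float(rr), pvalue=float(pp))
    return g


def graph_to_edge_frame(g: nx.Graph) -> pd.DataFrame:
    """Edge list as a sorted TSV-ready frame (source, target, weight, pvalue)."""
    rows = []
    for a, b, data in g.edges(data=True):
        s, t = sorted((a, b))
        rows.append((s, t, data.get("weight", np.nan), data.get("pvalue", np.nan)))
    out = pd.DataFrame(rows, columns=["source", "target", "weight", "pvalue"])
    return out.sort_values(["source", "target"], kind="mergesort").reset_index(drop=True)


def write_graph(g: nx.Graph, edges_path, graphml_path=None) -> None:
    graph_to_edge_frame(g).to_csv(edges_path, sep="\t", index=False)
    if graphml_path is not None:
        h = nx.Graph()
        for node, data in sorted(g.nodes(data=True)):
            h.add_node(node, **{k: ("" if v is None else v) for k, v in data.items()})
        for a, b, data in sorted(g.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            clean = {k: v for k, v in data.items() if v is not None and np.isfinite(v)}
            h.add_edge(a, b, **clean)
        nx.write_graphml(h, graphml_path)
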