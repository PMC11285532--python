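"""Gene-set selection and enrichment statistics.

Covers GWAS candidate-gene selection (genic SNPs, p-value threshold, best SNP
per gene, expression-aware background), hypergeometric / Fisher overlap tests,
Benjamini-Hochberg adjustment, over-representation tables, preranked GSEA with
a gene-label permutation null, and the small auxiliary tests (chi-squared cell
proportions, Pearson correlation).

Every overlap test is upper-tail: the pipeline asks only whether a query set
is over-represented in a target, never depleted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .containers import ExpressedBackground, GeneSetCollection, GwasTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# primitive tests
# ---------------------------------------------------------------------------

def hypergeom_upper(k: int, q: int, t: int, N: int) -> float:
    """Upper-tail hypergeometric overlap p-value, P(X >= k).

    X counts the overlap when ``q`` query genes are drawn without replacement
    from a universe of ``N`` genes containing ``t`` target genes.
    """
    if not (0 <= k <= min(q, t) <= N):
        raise ValueError(f"invalid overlap margins k={k}, q={q}, t={t}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy handles the tail summation stably
    p = st.hypergeom.sf(k - 1, N, t, q)
    return float(min(1.0, max(p, 0.0)))


def fisher_overlap(k: int, q: int, t: int, N: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 overlap table.

    Identical margins to :func:`hypergeom_upper`; the two agree exactly.
    """
    a, b, c, d = k, q - k, t - k, N - q - t + k
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in 2x2 table derived from k={k}, q={q}, t={t}, N={N}")
    _, p = st.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(min(1.0, p))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return padj


def chisq_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-type 2x2 chi-squared test of regional composition differences.

    ``counts`` is a types x regions contingency table of cell numbers (two
    region columns). Each type is tested against the pooled rest, without
    continuity correction; BH adjustment across types.
    """
    if counts.shape[1] != 2:
        raise ValueError("expected a types x 2-regions table")
    col_tot = counts.sum(axis=0)
    if (col_tot == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    rows = []
    for t in counts.index:
        a = counts.loc[t].to_numpy(dtype=float)
        rest = (col_tot - a).to_numpy(dtype=float)
        stat, p, _, _ = st.chi2_contingency([a, rest], correction=False)
        rows.append((t, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["celltype", "chi2", "pvalue"])
    out["padj"] = bh_adjust(out["pvalue"])
    return out


def pearson_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = st.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# GWAS gene selection
# ---------------------------------------------------------------------------

@dataclass
class GwasSelection:
    """Per-disease GWAS gene sets after the selection rules.

    ``per_disease`` maps disease -> DataFrame (gene, best_p, best_snp);
    ``union`` and ``intersection`` are across diseases (the pan-disorder
    intersection is the genes detected in every disease).
    """

    per_disease: Dict[str, pd.DataFrame]
    p_max: float
    background_scope: Optional[str] = None

    @property
    def union(self) -> FrozenSet[str]:
        out: FrozenSet[str] = frozenset()
        for df in self.per_disease.values():
            out = out | frozenset(df["gene"])
        return out

    @property
    def intersection(self) -> FrozenSet[str]:
        sets = [frozenset(df["gene"]) for df in self.per_disease.values()]
        if not sets:
            return frozenset()
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out

    def as_collection(self) -> GeneSetCollection:
        sets = {d: frozenset(df["gene"]) for d, df in self.per_disease.items()
                if len(df)}
        return GeneSetCollection(sets=sets, category="gwas")

    def strict(self, p_strict: float) -> "GwasSelection":
        """Second-tier filter keeping only genes whose best SNP passes p_strict."""
        per = {d: df[df["best_p"] < p_strict].reset_index(drop=True)
               for d, df in self.per_disease.items()}
        return GwasSelection(per_disease=per, p_max=p_strict,
                             background_scope=self.background_scope)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for d in sorted(self.per_disease):
            df = self.per_disease[d].copy()
            df.insert(0, "disease", d)
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["disease", "gene", "best_p", "best_snp"])
        return pd.concat(frames, ignore_index=True)


def gwas_select(
    gwas: GwasTable,
    background: Optional[ExpressedBackground] = None,
    p_max: float = 1e-5,
) -> GwasSelection:
    """Apply the GWAS gene selection rules per disease.

    Rules, in order: drop intergenic records; drop associations with
    p > ``p_max``; per (disease, gene) retain the SNP with the lowest p-value;
    intersect with the expressed-gene background when one is given. A disease
    left with zero genes is kept as an empty set with a logged warning.
    """
    rec = gwas.records
    kept = rec[rec["genic"] & (rec["p_value"] <= p_max)]
    per_disease: Dict[str, pd.DataFrame] = {}
    for disease in gwas.diseases:
        sub = kept[kept["disease"] == disease]
        if len(sub):
            # best SNP per gene; deterministic tie-break on snp id
            sub = sub.sort_values(["gene", "p_value", "snp"], kind="mergesort")
            best = sub.groupby("gene", sort=True).first().reset_index()
            best = best.rename(columns={"p_value": "best_p", "snp": "best_snp"})
            best = best[["gene", "best_p", "best_snp"]]
            if background is not None:
                best = best[[g in background for g in best["gene"]]]
            best = best.reset_index(drop=True)
        else:
            best = pd.DataFrame(columns=["gene", "best_p", "best_snp"])
        if len(best) == 0:
            logger.warning("gwas_select: disease %s has no surviving genes", disease)
        per_disease[disease] = best
    return GwasSelection(
        per_disease=per_disease, p_max=p_max,
        background_scope=background.scope if background is not None else None,
    )


# ---------------------------------------------------------------------------
# over-representation tables
# ---------------------------------------------------------------------------

def enrich_table(
    query_sets: Mapping[str, Iterable[str]],
    target_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of every query in every target.

    All sets are intersected with the background universe before testing; BH
    adjustment is applied across the whole table. Columns: query, target, k,
    q, t, N, pvalue, padj, score (= -log10 padj), proportion (= k / t).
    """
    universe = frozenset(str(g).upper() for g in background)
    N = len(universe)
    if N == 0:
        raise ValueError("empty background universe")
    rows = []
    for qname in sorted(query_sets):
        qraw = frozenset(str(g).upper() for g in query_sets[qname])
        q = qraw & universe
        if len(q) < len(qraw):
            logger.warning("enrich_table: query %s loses %d/%d genes outside background",
                           qname, len(qraw) - len(q), len(qraw))
        for tname in sorted(target_sets):
            t = frozenset(str(g).upper() for g in target_sets[tname]) & universe
            k = len(q & t)
            p = hypergeom_upper(k, len(q), len(t), N) if t and q else 1.0
            rows.append((qname, tname, k, len(q), len(t), N, p))
    out = pd.DataFrame(rows, columns=["query", "target", "k", "q", "t", "N", "pvalue"])
    out["padj"] = bh_adjust(out["pvalue"]) if len(out) else []
    out["score"] = -np.log10(out["padj"].clip(lower=np.finfo(float).tiny))
    out["proportion"] = np.where(out["t"] > 0, out["k"] / out["t"].clip(lower=1), 0.0)
    return out


def ora_pathways(
    genes: Iterable[str],
    pathway_sets: GeneSetCollection,
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pathway over-representation of one query gene list; adds a `significant` flag."""
    table = enrich_table({"query": genes}, dict(pathway_sets.sets), background)
    table = table.drop(columns=["query"]).rename(columns={"target": "pathway"})
    table["significant"] = table["padj"] < alpha
    return table


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    """Enrichment score: extremum of the weighted running sum.

    ``positions`` are 0-based sorted ranks of the hits; ``weights`` their
    |stat|^weight increments. Misses decrement uniformly by 1/(n - n_hits).
    The running sum is piecewise linear between hits, so its extrema occur at
    each hit (after the increment) and immediately before each hit.
    """
    nh = positions.size
    wsum = weights.sum()
    if wsum == 0:
        # degenerate all-zero stats: fall back to unweighted increments
        weights = np.ones(nh)
        wsum = float(nh)
    miss = 1.0 / (n - nh)
    cum_hit = np.cumsum(weights) / wsum
    # running sum just after hit i (0-based): cum_hit[i] - miss * (positions[i] - i)
    misses_before = positions - np.arange(nh)
    after = cum_hit - miss * misses_before
    before = np.concatenate(([0.0], cum_hit[:-1])) - miss * misses_before
    lo = before.min()
    hi = after.max()
    return float(hi if hi >= -lo else lo)


def gsea_preranked(
    ranked_stats: pd.Series,
    pathway_sets: GeneSetCollection,
    nperm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked_stats`` maps gene -> ranking statistic; genes are ordered by the
    statistic descending with ties broken by gene symbol, which makes the
    ranking deterministic. For each gene set (restricted to ranked genes and
    within [min_size, max_size]), the enrichment score is the signed extremum
    of the weighted Kolmogorov-Smirnov running sum; the null permutes which
    ranks are hits; NES divides ES by the mean |null ES| of matching sign; the
    permutation p-value uses +1 smoothing so its floor is 1/(nperm + 1).
    """
    stats = ranked_stats.copy()
    stats.index = stats.index.astype(str).str.upper()
    order = sorted(stats.index, key=lambda g: (-stats[g], g))
    stats = stats.loc[order]
    genes = np.array(stats.index)
    absw = np.abs(stats.to_numpy(dtype=float)) ** weight
    n = len(genes)
    pos_of = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(pathway_sets.sets):
        members = pathway_sets.sets[name] & frozenset(genes)
        nh = len(members)
        if nh < min_size or nh > max_size or nh >= n:
            logger.info("gsea_preranked: skipping %s (size %d after intersection)", name, nh)
            continue
        positions = np.sort([pos_of[g] for g in members])
        es = _es_from_positions(positions, absw[positions], n)

        null_es = np.empty(nperm)
        for b in range(nperm):
            perm = np.sort(rng.choice(n, size=nh, replace=False))
            null_es[b] = _es_from_positions(perm, absw[perm], n)

        same = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        denom = np.abs(same).mean() if same.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        n_extreme = int(np.sum(np.abs(same) >= abs(es)))
        pval = (n_extreme + 1) / (nperm + 1)
        rows.append((name, nh, es, nes, pval))

    out = pd.DataFrame(rows, columns=["pathway", "size", "es", "nes", "pvalue"])
    out["padj"] = bh_adjust(out["pvalue"]) if len(out) else []
    return out
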