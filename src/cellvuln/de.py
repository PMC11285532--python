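"""Marker detection and negative-binomial regional differential expression.

The regional contrast (TL vs FL) follows the standard bulk-RNA NB workflow
applied at single-cell resolution: region-balanced downsampling per cell
type, TMM library-size factors, common + tagwise (empirical-Bayes shrunk)
dispersion estimation by adjusted profile likelihood, and a quasi-likelihood
F-test on the two-group NB GLM. Marker genes use one-vs-rest logistic
regression with a likelihood-ratio test, keeping positive markers only.

The NB model is mean/dispersion parameterized: Var = mu + phi * mu^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.special as sc
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import f as f_dist
from scipy.stats import rankdata as st_rankdata

from .containers import CountMatrix, ExpressedBackground, GeneSetCollection
from .genesets import bh_adjust, enrich_table

logger = logging.getLogger(__name__)

_ETA_MAX = 30.0


# ---------------------------------------------------------------------------
# vectorized two-group NB GLM
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi, include_y_const: bool = True) -> np.ndarray:
    """Row-wise NB log-likelihood (genes x cells inputs), Poisson limit at phi ~ 0.

    With ``include_y_const=False`` the -gammaln(y + 1) term, constant in both
    mu and phi, is omitted; profile-likelihood maximizations only compare
    likelihood differences, where it cancels. For scalar phi the
    gammaln(y + r) - gammaln(r) term is computed by a cumulative-log table
    over the integer counts, which is much faster than per-entry gammaln.
    """
    mu = np.maximum(mu, 1e-12)
    scalar_phi = np.ndim(phi) == 0 or np.size(phi) == 1
    if scalar_phi:
        phi_val = float(np.asarray(phi).ravel()[0])
        if phi_val < 1e-10:
            out = y * np.log(mu) - mu
        else:
            r = 1.0 / phi_val
            # table[k] = gammaln(k + r) - gammaln(r) = sum_{j<k} log(r + j)
            ymax = int(y.max())
            table = np.concatenate(([0.0], np.cumsum(np.log(r + np.arange(ymax)))))
            out = (table[y.astype(np.int64)]
                   + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
        if include_y_const:
            out = out - sc.gammaln(y + 1.0)
        return out.sum(axis=1)

    phi = np.broadcast_to(np.atleast_1d(np.asarray(phi, dtype=float))[:, None], y.shape)
    out = np.empty(y.shape)
    tiny = phi < 1e-10
    if np.any(~tiny):
        r = 1.0 / phi[~tiny]
        yy, mm = y[~tiny], mu[~tiny]
        out[~tiny] = (sc.gammaln(yy + r) - sc.gammaln(r)
                      + r * np.log(r / (r + mm)) + yy * np.log(mm / (r + mm)))
    if np.any(tiny):
        yy, mm = y[tiny], mu[tiny]
        out[tiny] = yy * np.log(mm) - mm
    if include_y_const:
        out = out - sc.gammaln(y + 1.0)
    return out.sum(axis=1)


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Row-wise NB deviance, 2 * (loglik at mu = y  minus  loglik at fitted mu)."""
    phi = np.broadcast_to(np.atleast_1d(np.asarray(phi, dtype=float))[:, None], y.shape)
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    tiny = phi < 1e-10
    term2 = np.empty(y.shape)
    if np.any(~tiny):
        r = 1.0 / phi[~tiny]
        yy, mm = y[~tiny], mu[~tiny]
        term2[~tiny] = (yy + r) * np.log((mm + r) / (yy + r))
    if np.any(tiny):
        term2[tiny] = mu[tiny] - y[tiny]
    return 2.0 * (term1 + term2).sum(axis=1)


def _fit_nb_glm(
    y: np.ndarray,
    x: Optional[np.ndarray],
    offset: np.ndarray,
    phi,
    max_iter: int = 40,
    tol: float = 1e-8,
    beta0: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fisher-scoring fit of mu = exp(b0 + b1*x + offset) for every gene at once.

    ``y`` is genes x cells; ``x`` a 0/1 cell covariate or None for the
    intercept-only model. Returns (beta, mu) with beta of shape (genes, p).
    Linear predictors are clipped to +-30 so fully separated genes (one group
    all zero) converge to a finite boundary fit.
    """
    G, n = y.shape
    phi_col = np.atleast_1d(np.asarray(phi, dtype=float))[:, None]
    eo = np.exp(offset)[None, :]

    if x is None:
        X = np.ones((n, 1))
        if beta0 is not None:
            beta = beta0.copy()
        else:
            beta = np.log(np.maximum(y.sum(1) / eo.sum(), 1e-8))[:, None]
    else:
        X = np.column_stack([np.ones(n), x.astype(float)])
        if beta0 is not None:
            beta = beta0.copy()
        else:
            in1 = x.astype(bool)
            m1 = np.maximum(y[:, in1].sum(1) / eo[:, in1].sum(), 1e-8)
            m0 = np.maximum(y[:, ~in1].sum(1) / eo[:, ~in1].sum(), 1e-8)
            beta = np.column_stack([np.log(m0), np.log(m1) - np.log(m0)])

    p = X.shape[1]
    active = np.arange(G)
    phi_all = np.broadcast_to(phi_col, (G, 1))
    for _ in range(max_iter):
        ya = y[active]
        ph = phi_all[active]
        ba = beta[active]
        eta = np.clip(ba @ X.T + offset[None, :], -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        denom = 1.0 + ph * mu
        w = mu / denom                                # Fisher weights
        resid = (ya - mu) / denom                     # working score component
        grad = resid @ X                              # (g, p)
        if p == 1:
            info = (w @ X[:, 0] ** 2)[:, None]
            step = grad / np.maximum(info, 1e-12)
        else:
            a = w @ (X[:, 0] * X[:, 0])
            b = w @ (X[:, 0] * X[:, 1])
            d = w @ (X[:, 1] * X[:, 1])
            det = np.maximum(a * d - b * b, 1e-12)
            step = np.column_stack([
                (d * grad[:, 0] - b * grad[:, 1]) / det,
                (a * grad[:, 1] - b * grad[:, 0]) / det,
            ])
        np.clip(step, -5.0, 5.0, out=step)
        new_beta = np.clip(ba + step, -_ETA_MAX, _ETA_MAX)
        moved = np.abs(new_beta - ba)                 # boundary genes stop moving
        beta[active] = new_beta
        keep = moved.max(axis=1) >= tol
        active = active[keep]
        if active.size == 0:
            break
    eta = np.clip(beta @ X.T + offset[None, :], -_ETA_MAX, _ETA_MAX)
    return beta, np.exp(eta)


def _adjusted_profile_loglik(y, x, offset, phi, beta0=None, return_beta=False):
    """Cox-Reid adjusted profile log-likelihood per gene at fixed dispersion."""
    beta, mu = _fit_nb_glm(y, x, offset, phi, beta0=beta0)
    ll = _nb_loglik(y, mu, phi, include_y_const=False)
    phi_col = np.atleast_1d(np.asarray(phi, dtype=float))[:, None]
    w = mu / (1.0 + phi_col * mu)
    if x is None:
        cr = 0.5 * np.log(np.maximum(w.sum(1), 1e-12))
    else:
        X = np.column_stack([np.ones(y.shape[1]), x.astype(float)])
        a = w @ (X[:, 0] * X[:, 0])
        b = w @ (X[:, 0] * X[:, 1])
        d = w @ (X[:, 1] * X[:, 1])
        cr = 0.5 * np.log(np.maximum(a * d - b * b, 1e-24))
    if return_beta:
        return ll - cr, beta
    return ll - cr


# ---------------------------------------------------------------------------
# TMM normalization factors
# ---------------------------------------------------------------------------

def _quantile_depth(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.array([np.quantile(counts[:, j], p) / lib[j] for j in range(counts.shape[1])])


def tmm_factors(
    counts,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values library scaling factors, geometric mean 1.

    The reference column is the one whose upper-quartile depth is closest to
    the mean upper-quartile. For each column, M (log ratio) and A (log
    abundance) are computed against the reference over genes nonzero in both;
    the most extreme ``trim_m`` of M and ``trim_a`` of A on each side are
    discarded and the factor is the precision-weighted mean of the surviving
    M values (binomial delta-method weights).
    """
    y = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a genes x cells matrix with >= 2 columns")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise ValueError(f"zero-total column at index {int(np.flatnonzero(lib == 0)[0])}")
    y = y[y.sum(axis=1) > 0]  # all-zero genes carry no information

    f75 = _quantile_depth(y, lib, 0.75)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    yr, nr = y[:, ref], lib[ref]

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yj, nj = y[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        if ok.sum() < 2:
            continue
        pj, pr = yj[ok] / nj, yr[ok] / nr
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        w = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        n = M.size
        rM = st_rankdata(M)
        rA = st_rankdata(A)
        loM, hiM = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        loA, hiA = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if keep.sum() == 0:
            continue
        f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        if abs(f) > 1e-6:
            factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionFit:
    """Common and per-gene (tagwise) NB dispersions with the shrinkage prior df."""

    common: float
    tagwise: np.ndarray
    prior_df: float

    def __post_init__(self) -> None:
        if self.common < 0 or np.any(self.tagwise < 0):
            raise ValueError("dispersions must be >= 0")


def _parabolic_peak(logx: np.ndarray, y0: np.ndarray, y1: np.ndarray, y2: np.ndarray,
                    j: np.ndarray, delta: float) -> np.ndarray:
    """Vertex of the parabola through three uniform grid points around argmax j."""
    denom = y0 - 2.0 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12,
                     0.5 * (y0 - y2) / np.where(np.abs(denom) > 1e-12, denom, 1.0), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    return logx[j] + shift * delta


def fit_dispersion(
    counts,
    groups: np.ndarray,
    offsets: Optional[np.ndarray] = None,
    prior_df: float = 10.0,
    grid_min: float = 1e-3,
    grid_max: float = 8.0,
    grid_points: int = 15,
) -> DispersionFit:
    """Estimate common and tagwise NB dispersions by adjusted profile likelihood.

    The Cox-Reid adjusted profile log-likelihood of every gene is evaluated on
    one log-spaced dispersion grid. The common dispersion maximizes the summed
    curve (with parabolic interpolation between grid points); tagwise values
    maximize a weighted likelihood that adds ``prior_df`` residual-df worth of
    the pooled curve to each gene's own, so they shrink toward the common
    value and collapse onto it as prior_df grows.
    """
    y = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has < 2 replicates")
    x = (groups == levels[0]).astype(float)
    if offsets is None:
        offsets = np.log(np.maximum(y.sum(axis=0), 1.0))

    keep = y.sum(axis=1) > 0
    yk = y[keep]

    grid = np.exp(np.linspace(np.log(grid_min), np.log(grid_max), grid_points))
    loggrid = np.log(grid)
    delta = loggrid[1] - loggrid[0]
    cols = []
    beta0 = None
    for g in grid:
        col, beta0 = _adjusted_profile_loglik(yk, x, offsets, g,
                                              beta0=beta0, return_beta=True)
        cols.append(col)
    apl = np.stack(cols, axis=1)  # (genes, grid)

    total = apl.sum(axis=0)
    j = int(np.argmax(total))
    if 0 < j < grid_points - 1:
        common = float(np.exp(_parabolic_peak(
            loggrid, total[j - 1], total[j], total[j + 1], np.array(j), delta)))
    else:
        common = float(grid[j])

    G = y.shape[0]
    tagwise = np.full(G, common)
    if np.isfinite(prior_df):
        n = y.shape[1]
        df_res = max(n - 2, 1)
        prior_n = prior_df / df_res
        shared = apl.mean(axis=0)  # pooled curve across the grid
        wl = apl + prior_n * shared[None, :]
        jg = np.argmax(wl, axis=1)
        inner = (jg > 0) & (jg < grid_points - 1)
        tw = grid[jg].astype(float)
        if inner.any():
            ji = jg[inner]
            tw[inner] = np.exp(_parabolic_peak(
                loggrid, wl[inner, ji - 1], wl[inner, ji], wl[inner, ji + 1], ji, delta))
        tagwise[keep] = tw
    return DispersionFit(common=common, tagwise=tagwise, prior_df=prior_df)


# ---------------------------------------------------------------------------
# quasi-likelihood F-test
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float, iters: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = sc.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / sc.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float, floor_df: float = 3.0) -> Tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of scaled-chi-square variances (moment matching).

    Returns (posterior s2, prior df d0, prior value s0^2). The prior df is
    estimated by matching the moments of log(s2) to a scaled F distribution
    and floored at ``floor_df``.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), np.inf, float(np.mean(s2[ok]) if ok.any() else 1.0)
    z = np.log(s2[ok])
    e = z - sc.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - sc.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = float(np.exp(np.mean(e) + sc.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0, s20 = np.inf, float(np.exp(np.mean(e)))
    if d0 < floor_df:
        d0 = floor_df
    if np.isfinite(d0):
        post = (d0 * s20 + df * s2) / (d0 + df)
    else:
        post = np.full_like(s2, s20)
    return post, float(d0), s20


def nb_de_test(
    counts,
    groups: np.ndarray,
    gene_ids: Optional[Sequence[str]] = None,
    factors: Optional[np.ndarray] = None,
    dispersion: Optional[DispersionFit] = None,
    group_order: Optional[Tuple[str, str]] = None,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Two-group NB differential expression with a quasi-likelihood F-test.

    log2FC is positive when expression is higher in the first-named group
    (``group_order[0]``). Per gene, the full (two-group) and reduced
    (intercept-only) NB GLMs are fitted with tagwise dispersions and offsets
    log(library size x TMM factor); the deviance drop is tested against an
    empirical-Bayes moderated quasi-dispersion with an F(1, df_res + d0)
    reference. Genes with all-zero counts are excluded (logFC undefined).
    """
    y = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    G, n = y.shape
    groups = np.asarray(groups)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(G)]
    gene_ids = np.asarray(gene_ids, dtype=object)
    if group_order is None:
        group_order = tuple(pd.unique(groups)[:2])
    g1, g2 = group_order
    n1, n2 = int((groups == g1).sum()), int((groups == g2).sum())
    if n1 < 3 or n2 < 3:
        raise ValueError(f"each group needs >= 3 cells (got {g1}:{n1}, {g2}:{n2})")

    lib = y.sum(axis=0)
    if factors is None:
        factors = tmm_factors(y)
    offsets = np.log(np.maximum(lib * factors, 1e-8))

    nonzero = y.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("nb_de_test: excluding %d all-zero genes", int((~nonzero).sum()))
    yk = y[nonzero]
    x = (groups == g1).astype(float)

    if dispersion is None:
        dispersion = fit_dispersion(y, groups, offsets, prior_df=prior_df)
    phi = dispersion.tagwise[nonzero]

    beta_full, mu_full = _fit_nb_glm(yk, x, offsets, phi)
    _, mu_red = _fit_nb_glm(yk, None, offsets, phi)
    dev_full = _nb_deviance(yk, mu_full, phi)
    dev_red = _nb_deviance(yk, mu_red, phi)

    df_res = n - 2
    s2 = np.maximum(dev_full, 0.0) / df_res
    s2_post, d0, _ = _squeeze_var(s2, df_res)
    fstat = np.maximum(dev_red - dev_full, 0.0) / np.maximum(s2_post, 1e-12)
    df2 = df_res + d0 if np.isfinite(d0) else df_res
    pvals = np.clip(f_dist.sf(fstat, 1, df2), np.finfo(float).tiny, 1.0)

    log2fc = beta_full[:, 1] / np.log(2.0)
    pct1 = (yk[:, x.astype(bool)] > 0).mean(axis=1)
    pct2 = (yk[:, ~x.astype(bool)] > 0).mean(axis=1)
    norm = np.log1p(yk / lib[None, :] * 1e4)
    out = pd.DataFrame({
        "gene": gene_ids[nonzero],
        "log2fc": log2fc,
        "pvalue": pvals,
        "padj": bh_adjust(pvals),
        "pct_group1": pct1,
        "pct_group2": pct2,
        "mean_norm": norm.mean(axis=1),
    })
    out.attrs["contrast"] = f"{g1}_vs_{g2}"
    out.attrs["prior_df_ql"] = d0
    return out.reset_index(drop=True)


def significant_degs(de: pd.DataFrame, logfc_min: float = 0.5, fdr_max: float = 0.05) -> pd.DataFrame:
    """Threshold a DE table: |log2FC| above the cut and BH-adjusted p below it."""
    return de[(de["log2fc"].abs() > logfc_min) & (de["padj"] < fdr_max)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# region-balanced downsampling
# ---------------------------------------------------------------------------

def downsample_balanced(
    cm: CountMatrix,
    celltype: str,
    seed: int = 0,
    column: str = "subtype",
) -> CountMatrix:
    """Equalize TL and FL cell numbers for one cell (sub)type by random subsetting."""
    meta = cm.cell_meta
    in_type = meta[column].to_numpy() == celltype
    regions = meta["region"].to_numpy()
    idx_by_region = {}
    for r in ("TL", "FL"):
        idx_by_region[r] = np.flatnonzero(in_type & (regions == r))
    n_min = min(len(idx_by_region["TL"]), len(idx_by_region["FL"]))
    if n_min < 3:
        raise ValueError(
            f"type {celltype!r} has too few cells in a region "
            f"(TL={len(idx_by_region['TL'])}, FL={len(idx_by_region['FL'])})")
    rng = np.random.default_rng(seed)
    chosen = []
    for r in ("TL", "FL"):
        idx = idx_by_region[r]
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        chosen.append(np.sort(idx))
    return cm.subset_cells(np.concatenate(chosen))


# ---------------------------------------------------------------------------
# one-vs-rest marker detection
# ---------------------------------------------------------------------------

def _logistic_lr_vectorized(xmat: np.ndarray, y: np.ndarray, max_iter: int = 40) -> np.ndarray:
    """LR-test chi2 statistic of logistic membership ~ expression, per gene.

    ``xmat`` is genes x cells of predictors, ``y`` the shared 0/1 membership.
    Newton iterations run on all genes simultaneously; the null model is the
    closed-form intercept-only fit.
    """
    G, n = xmat.shape
    pbar = y.mean()
    ll0 = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))

    def loglik(b0, b1):
        eta = np.clip(b0[:, None] + b1[:, None] * xmat, -_ETA_MAX, _ETA_MAX)
        return np.sum(y[None, :] * eta - np.log1p(np.exp(eta)), axis=1)

    b0 = np.full(G, np.log(pbar / (1 - pbar)))
    b1 = np.zeros(G)
    ll = loglik(b0, b1)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * xmat, -_ETA_MAX, _ETA_MAX)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        r = y[None, :] - p
        g0 = r.sum(axis=1)
        g1 = (r * xmat).sum(axis=1)
        a = w.sum(axis=1)
        b = (w * xmat).sum(axis=1)
        d = (w * xmat * xmat).sum(axis=1)
        det = np.maximum(a * d - b * b, 1e-12)
        s0 = np.clip((d * g0 - b * g1) / det, -10, 10)
        s1 = np.clip((a * g1 - b * g0) / det, -10, 10)
        # damped update: halve any step that decreases the likelihood
        scale = np.ones(G)
        for _half in range(8):
            t0 = b0 + scale * s0
            t1 = b1 + scale * s1
            ll_new = loglik(t0, t1)
            bad = ll_new < ll - 1e-12
            if not bad.any():
                break
            scale[bad] *= 0.5
        improved = ll_new >= ll
        b0 = np.where(improved, t0, b0)
        b1 = np.where(improved, t1, b1)
        ll = np.maximum(ll_new, ll)
        accepted = scale * np.maximum(np.abs(s0), np.abs(s1)) * improved
        if accepted.max() < 1e-9:
            break
    return np.maximum(2.0 * (ll - ll0), 0.0)


def find_markers(
    cm: CountMatrix,
    norm: sp.spmatrix,
    labels: np.ndarray,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    positive_only: bool = True,
) -> pd.DataFrame:
    """One-vs-rest marker genes per label, by logistic-regression LR test.

    A gene enters testing for type t when it is detected in at least
    ``min_pct`` of cells inside or outside t and its average log2 fold change
    (on expm1 of the normalized values, pseudocount 1) is at least
    ``logfc_min``; positive markers only. p-values are BH-adjusted within
    each type.
    """
    labels = np.asarray(labels)
    types = sorted(pd.unique(labels))
    if len(types) < 2:
        raise ValueError("need at least 2 label groups")
    for t in types:
        if (labels == t).sum() < 3:
            raise ValueError(f"group {t!r} has fewer than 3 cells")

    X = np.asarray(norm.todense(), dtype=float)  # genes x cells
    expm = np.expm1(X)
    detected = X > 0

    frames = []
    for t in types:
        in_t = labels == t
        pct_in = detected[:, in_t].mean(axis=1)
        pct_out = detected[:, ~in_t].mean(axis=1)
        mean_in = expm[:, in_t].mean(axis=1)
        mean_out = expm[:, ~in_t].mean(axis=1)
        logfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))

        pre = (np.maximum(pct_in, pct_out) >= min_pct) & (logfc >= logfc_min)
        if not positive_only:
            pre = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(logfc) >= logfc_min)
        idx = np.flatnonzero(pre)
        if idx.size == 0:
            continue
        chi2 = _logistic_lr_vectorized(X[idx], in_t.astype(float))
        pvals = np.clip(sc.chdtrc(1, chi2), np.finfo(float).tiny, 1.0)
        df = pd.DataFrame({
            "celltype": t,
            "gene": cm.gene_ids[idx],
            "log2fc": logfc[idx],
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
        })
        frames.append(df.sort_values(["pvalue", "gene"], kind="mergesort"))
    if not frames:
        return pd.DataFrame(columns=["celltype", "gene", "log2fc", "pvalue",
                                     "padj", "pct_in", "pct_out"])
    return pd.concat(frames, ignore_index=True)


def marker_sets(markers: pd.DataFrame, fdr_max: float = 0.05) -> Dict[str, frozenset]:
    """Significant marker genes per cell type, as plain sets."""
    sig = markers[markers["padj"] < fdr_max]
    return {t: frozenset(sub["gene"]) for t, sub in sig.groupby("celltype") if len(sub)}


def marker_overlap_check(
    markers: Mapping[str, Iterable[str]],
    reference_sets: GeneSetCollection,
    background: ExpressedBackground,
) -> pd.DataFrame:
    """Hypergeometric corroboration of data-driven markers against a reference panel."""
    if reference_sets.category != "marker_reference":
        raise ValueError("reference collection must have category 'marker_reference'")
    return enrich_table(dict(markers), dict(reference_sets.sets), background.genes)


# ---------------------------------------------------------------------------
# hierarchical clustering of the logFC matrix
# ---------------------------------------------------------------------------

def cluster_logfc(logfc_matrix: pd.DataFrame, k: int = 6) -> Tuple[pd.Series, pd.DataFrame]:
    """Cluster the genes x celltypes log2FC matrix (missing = 0).

    Hierarchical clustering with Euclidean distance and complete linkage, cut
    at ``k`` clusters. Returns (assignment indexed by gene, cluster mean
    profiles). Cluster ids are relabelled 1..k by decreasing size with ties
    broken by first gene, so the labelling is deterministic.
    """
    mat = logfc_matrix.fillna(0.0)
    n = len(mat)
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        Z = linkage(mat.to_numpy(), method="complete", metric="euclidean")
        raw = fcluster(Z, t=k, criterion="maxclust")
    # deterministic relabel by cluster size, largest first
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], int(np.argmax(raw == c))))
    remap = {c: i + 1 for i, c in enumerate(order)}
    assign = pd.Series([remap[c] for c in raw], index=mat.index, name="cluster")
    profiles = mat.groupby(assign).mean()
    return assign, profiles
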