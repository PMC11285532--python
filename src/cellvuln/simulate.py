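"""Synthetic study generator with planted, recorded ground truth.

Every downstream stage of the pipeline has a recovery test against the truth
tables produced here: NB-distributed UMI counts with cell-type marker
structure and region-specific fold changes concentrated in a designated
"vulnerable" subtype; a GWAS association table whose post-selection gene sets
equal the planted map exactly; seven psychoactive drug-target classes with a
planted 2:1 drug:GWAS overlap into the vulnerable subtype's TL-upregulated
genes; pathway collections seeded from marker sets; and case-control disease
DEG tables whose sign agreement with the regional fold changes is controlled
by a single concordance parameter.

Counts follow a gamma-Poisson (negative binomial) model with per-gene
dispersion phi and Var = mu + phi * mu^2. Doublets are average-and-resample
composites of two parent cells, flagged in both the truth and cell metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import DISEASES, DRUG_CLASSES, EX_SUBTYPES, INH_SUBTYPES, SimConfig
from .containers import CountMatrix, GeneSetCollection, GwasTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Planted ground truth of one synthetic study."""

    marker_map: Dict[str, Dict[str, float]] = field(default_factory=dict)
    regional_map: Dict[str, Dict[str, float]] = field(default_factory=dict)
    gwas_truth: Dict[str, pd.DataFrame] = field(default_factory=dict)
    drug_truth: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    disease_deg_truth: Dict[str, pd.DataFrame] = field(default_factory=dict)
    doublets: FrozenSet[str] = frozenset()
    vulnerable_subtype: str = "INH-PVALB"

    def vulnerable_tl_up(self) -> FrozenSet[str]:
        """Planted TL-upregulated genes of the vulnerable subtype."""
        sub = self.regional_map.get(self.vulnerable_subtype, {})
        return frozenset(g for g, fc in sub.items() if fc > 0)

    def write(self, dir_path) -> None:
        d = Path(dir_path)
        d.mkdir(parents=True, exist_ok=True)
        rows = [(t, g, fc) for t, gs in sorted(self.marker_map.items())
                for g, fc in sorted(gs.items())]
        pd.DataFrame(rows, columns=["celltype", "gene", "log2_shift"]).to_csv(
            d / "markers.tsv", sep="\t", index=False)
        rows = [(t, g, fc) for t, gs in sorted(self.regional_map.items())
                for g, fc in sorted(gs.items())]
        pd.DataFrame(rows, columns=["celltype", "gene", "log2fc_tl_vs_fl"]).to_csv(
            d / "regional.tsv", sep="\t", index=False)
        frames = []
        for disease in sorted(self.gwas_truth):
            df = self.gwas_truth[disease].copy()
            df.insert(0, "disease", disease)
            frames.append(df)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(d / "gwas.tsv", sep="\t", index=False)
        rows = [(c, g) for c, gs in sorted(self.drug_truth.items()) for g in sorted(gs)]
        pd.DataFrame(rows, columns=["drug_class", "gene"]).to_csv(
            d / "drugs.tsv", sep="\t", index=False)
        frames = []
        for disease in sorted(self.disease_deg_truth):
            df = self.disease_deg_truth[disease].copy()
            df.insert(0, "disease", disease)
            frames.append(df)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                d / "disease_degs.tsv", sep="\t", index=False)
        pd.Series(sorted(self.doublets)).to_csv(
            d / "doublets.tsv", sep="\t", index=False, header=False)


def _leaf_fractions(cfg: SimConfig) -> Dict[str, float]:
    """Flatten major-type composition into leaf (subtype-level) fractions."""
    leaves: Dict[str, float] = {}
    for major, frac in cfg.composition.items():
        if major == "EX":
            for st, sfrac in cfg.ex_subtype_split.items():
                leaves[st] = frac * sfrac
        elif major == "INH":
            for st, sfrac in cfg.inh_subtype_split.items():
                leaves[st] = frac * sfrac
        else:
            leaves[major] = frac
    return leaves


def _major_of(leaf: str) -> str:
    if leaf in EX_SUBTYPES:
        return "EX"
    if leaf in INH_SUBTYPES:
        return "INH"
    return leaf


def _allocate(n: int, fractions: Dict[str, float]) -> Dict[str, int]:
    """Largest-remainder integer allocation of n cells to leaves."""
    names = sorted(fractions)
    raw = np.array([fractions[k] * n for k in names])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(names, base))


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def simulate_counts(cfg: Optional[SimConfig] = None, seed: int = 0) -> Tuple[CountMatrix, SimTruth]:
    """Generate the synthetic UMI count matrix and its planted truth.

    Per cell of leaf type t in region r, gene g:
    count ~ NB(mean = baseline_g * 2^(marker shift if g marks t or its major
    type) * 2^(regional log2FC if r = TL and g planted in t), scaled to the
    cell's log-normal library size; dispersion phi_g). Mitochondrial counts
    are allocated to the designated MT- genes to hit a per-cell beta-
    distributed mitochondrial fraction. Doublets are resampled averages of
    two parents, flagged in the truth.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    truth = SimTruth(vulnerable_subtype=cfg.vulnerable_subtype)

    n_mito = cfg.n_mito_genes
    n_nuc = cfg.n_genes - n_mito
    gene_ids = np.array([f"G{i:05d}" for i in range(n_nuc)]
                        + [f"MT-G{i}" for i in range(n_mito)], dtype=object)
    nuc_idx = np.arange(n_nuc)
    mito_idx = np.arange(n_nuc, cfg.n_genes)

    leaves = _leaf_fractions(cfg)
    if cfg.vulnerable_subtype not in leaves:
        raise ValueError(f"vulnerable subtype {cfg.vulnerable_subtype!r} not in composition")

    # design: subjects and their regions
    subjects = ([("TL", f"TL{i + 1}") for i in range(cfg.n_subjects_tl)]
                + [("FL", f"FL{i + 1}") for i in range(cfg.n_subjects_fl)])
    alloc = _allocate(cfg.cells_per_subject, leaves)
    region_cells = {"TL": cfg.n_subjects_tl, "FL": cfg.n_subjects_fl}
    for leaf, n_leaf in alloc.items():
        for region, n_subj in region_cells.items():
            if n_leaf * n_subj < 2:
                raise ValueError(
                    f"leaf {leaf!r} would have {n_leaf * n_subj} cells in {region}; "
                    "increase cells_per_subject or its composition fraction")

    # baseline relative abundances
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_nuc)
    mito_w = rng.lognormal(mean=0.0, sigma=0.5, size=n_mito)
    mito_w /= mito_w.sum()
    phi = rng.lognormal(mean=cfg.dispersion_meanlog, sigma=cfg.dispersion_sdlog,
                        size=cfg.n_genes)

    # plant markers: one disjoint block per leaf, plus EX/INH major-type blocks
    free = list(rng.permutation(nuc_idx))
    marker_groups = sorted(leaves) + ["EX", "INH"]
    for t in marker_groups:
        take, free = free[:cfg.n_markers_per_type], free[cfg.n_markers_per_type:]
        truth.marker_map[t] = {gene_ids[i]: cfg.marker_shift_log2 for i in take}

    # plant regional fold changes, concentrated in the vulnerable subtype;
    # restricted to mid-expression genes so the planted signal stays inside
    # the percentile-banded "expressed" background the enrichment tests use
    lo_w, hi_w = np.percentile(baseline, [20, 80])
    mid = [i for i in free if lo_w <= baseline[i] <= hi_w]
    rest = [i for i in free if not (lo_w <= baseline[i] <= hi_w)]
    free = mid + rest
    n_vuln = int(round(cfg.n_regional_degs * cfg.vulnerable_fraction))
    take, free = free[:n_vuln], free[n_vuln:]
    truth.regional_map[cfg.vulnerable_subtype] = {
        gene_ids[i]: cfg.regional_logfc for i in take}
    others = [t for t in sorted(leaves) if t != cfg.vulnerable_subtype]
    n_rest = cfg.n_regional_degs - n_vuln
    take, free = free[:n_rest], free[n_rest:]
    for j, i in enumerate(take):
        t = others[j % len(others)]
        sign = 1.0 if j % 3 else -1.0  # two thirds TL-up, one third FL-up
        truth.regional_map.setdefault(t, {})[gene_ids[i]] = sign * cfg.regional_logfc

    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # assemble cells group by group
    blocks: List[np.ndarray] = []
    barcodes: List[str] = []
    meta_rows: List[tuple] = []
    for region, subject in subjects:
        for leaf in sorted(leaves):
            n_cells = alloc[leaf]
            if n_cells == 0:
                continue
            w = baseline.copy()
            for scope in (leaf, _major_of(leaf)):
                for g, shift in truth.marker_map.get(scope, {}).items():
                    if gene_pos[g] < n_nuc:
                        w[gene_pos[g]] *= 2.0 ** shift
            if region == "TL":
                for g, fc in truth.regional_map.get(leaf, {}).items():
                    w[gene_pos[g]] *= 2.0 ** fc
            w = w / w.sum()

            lib = rng.lognormal(np.log(cfg.target_umi), cfg.libsize_sdlog, size=n_cells)
            mf_mean = cfg.mito_fraction_mean
            a = mf_mean * 60
            mf = rng.beta(a, 60 - a, size=n_cells)

            mu = np.empty((cfg.n_genes, n_cells))
            mu[nuc_idx] = np.outer(w, lib * (1.0 - mf))
            mu[mito_idx] = np.outer(mito_w, lib * mf)
            lam = rng.gamma(shape=1.0 / phi[:, None], scale=mu * phi[:, None])
            blocks.append(rng.poisson(lam))
            for c in range(n_cells):
                barcodes.append(f"{subject}-{leaf}-{c:04d}")
                meta_rows.append((subject, region, _major_of(leaf), leaf, False))

    counts = np.concatenate(blocks, axis=1)
    meta = pd.DataFrame(meta_rows, index=barcodes,
                        columns=["subject", "region", "major_type", "subtype", "doublet"])

    # doublets: replace a random subset with resampled parent averages
    n_total = counts.shape[1]
    n_dbl = int(round(cfg.doublet_rate * n_total))
    if n_dbl > 0:
        slots = rng.choice(n_total, size=n_dbl, replace=False)
        partners = rng.choice(n_total, size=n_dbl, replace=False)
        for s, p in zip(slots, partners):
            counts[:, s] = rng.poisson((counts[:, s] + counts[:, p]) / 2.0)
        meta.iloc[slots, meta.columns.get_loc("doublet")] = True
        truth.doublets = frozenset(np.array(barcodes, dtype=object)[slots])

    cm = CountMatrix(
        counts=sp.csc_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=np.array(barcodes, dtype=object),
        cell_meta=meta,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# direct two-group NB draws (used for calibration / recovery checks)
# ---------------------------------------------------------------------------

def simulate_nb_groups(
    n_genes: int,
    n_per_group: int,
    seed: int = 0,
    log2fc: float | np.ndarray = 0.0,
    phi: float | np.ndarray = 0.1,
    mean_count: float = 5.0,
    libsize_sdlog: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a genes x cells NB matrix for two equal groups with planted log2FC.

    Group "A" (the first ``n_per_group`` columns) has mean 2^log2fc times the
    group "B" mean, so positive values are up in A. ``phi = 0`` gives Poisson
    data. Returns (counts, group labels, per-gene true log2FC).
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = np.array(["A"] * n_per_group + ["B"] * n_per_group, dtype=object)
    base = rng.lognormal(np.log(mean_count), 0.8, size=n_genes)
    fc = np.broadcast_to(np.asarray(log2fc, dtype=float), (n_genes,)).copy()
    lib = rng.lognormal(0.0, libsize_sdlog, size=n) if libsize_sdlog > 0 else np.ones(n)
    mu = base[:, None] * lib[None, :]
    mu[:, :n_per_group] *= 2.0 ** fc[:, None]
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (n_genes,))
    if np.all(phi_arr == 0):
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / np.maximum(phi_arr, 1e-12)[:, None]
        lam = np.where(phi_arr[:, None] > 0,
                       rng.gamma(shape, np.maximum(mu, 1e-12) / shape), mu)
        counts = rng.poisson(lam)
    return counts, groups, fc


# ---------------------------------------------------------------------------
# GWAS table
# ---------------------------------------------------------------------------

def _log_uniform(rng, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_gwas_table(
    gene_ids: Sequence[str],
    diseases: Sequence[str],
    n_snps: int,
    planted_map: Mapping[str, Iterable[str]],
    seed: int = 0,
    strict_fraction: float = 0.5,
    intergenic_fraction: float = 0.3,
) -> Tuple[GwasTable, Dict[str, pd.DataFrame]]:
    """Generate a GWAS association table whose selected gene sets equal the plan.

    Planted genes receive one to three genic SNPs with minimum p below 1e-5
    (a ``strict_fraction`` of genes below 1e-8); ``n_snps`` background SNPs
    get p above the threshold or an intergenic flag, so they are removed by
    the selection rules. Returns the table plus the per-disease truth
    (gene, retained best p).
    """
    gene_set = set(str(g).upper() for g in gene_ids)
    rng = np.random.default_rng(seed)
    rows = []
    truth: Dict[str, pd.DataFrame] = {}
    snp_counter = 0

    for disease in diseases:
        planted = sorted(str(g).upper() for g in planted_map.get(disease, []))
        missing = [g for g in planted if g not in gene_set]
        if missing:
            raise ValueError(f"planted genes absent from gene_ids: {missing[:5]}")
        t_rows = []
        for g in planted:
            strict = rng.random() < strict_fraction
            best = (_log_uniform(rng, 1e-12, 1e-8) if strict
                    else _log_uniform(rng, 1e-8, 0.99e-5))
            n_extra = rng.integers(0, 3)
            ps = [best] + list(_log_uniform(rng, best, 0.99e-5, size=n_extra))
            for p in ps:
                rows.append((f"rs{snp_counter}", g, disease, float(p), True))
                snp_counter += 1
            t_rows.append((g, float(best)))
        truth[disease] = pd.DataFrame(t_rows, columns=["gene", "best_p"])

    # background SNPs: fail either the p threshold or the genic rule
    all_genes = sorted(gene_set)
    for _ in range(n_snps):
        disease = diseases[rng.integers(len(diseases))]
        intergenic = rng.random() < intergenic_fraction
        if intergenic:
            p = float(_log_uniform(rng, 1e-9, 1.0))  # may look strong, still dropped
        else:
            p = float(rng.uniform(1.01e-5, 1.0))
        n_mapped = 2 if rng.random() < 0.15 else 1
        mapped = rng.choice(all_genes, size=n_mapped, replace=False)
        for g in mapped:
            rows.append((f"rs{snp_counter}", g, disease, p, not intergenic))
        snp_counter += 1

    table = GwasTable(records=pd.DataFrame(
        rows, columns=["snp", "gene", "disease", "p_value", "genic"]))
    return table, truth


# ---------------------------------------------------------------------------
# disease DEG tables
# ---------------------------------------------------------------------------

def simulate_disease_degs(
    gene_ids: Sequence[str],
    regional_truth: Mapping[str, float],
    concordance: float,
    seed: int = 0,
    diseases: Sequence[str] = DISEASES[:3],
    n_shared: int = 100,
    n_own: int = 100,
    n_null: int = 300,
    logfc_min: float = 0.25,
    fdr_max: float = 0.05,
) -> Tuple[GeneSetCollection, Dict[str, pd.DataFrame], Dict[str, pd.DataFrame]]:
    """Case-control DEG tables correlated with the regional fold changes.

    ``regional_truth`` maps gene -> planted regional (TL vs FL) log2FC. Each
    disease table contains ``n_shared`` genes drawn from the regional DEGs
    whose sign agrees with the regional sign with probability
    (1 + concordance) / 2, ``n_own`` significant genes independent of region,
    and ``n_null`` filler genes failing the thresholds. Returns the planted
    significant sets (category disease_deg), the per-disease DEG tables, and
    the per-disease truth with the planted sign agreement.
    """
    if not -1 <= concordance <= 1:
        raise ValueError("concordance must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    regional_genes = sorted(str(g).upper() for g in regional_truth)
    gene_pool = sorted(set(str(g).upper() for g in gene_ids) - set(regional_genes))
    p_agree = (1.0 + concordance) / 2.0

    tables: Dict[str, pd.DataFrame] = {}
    truth: Dict[str, pd.DataFrame] = {}
    sets: Dict[str, FrozenSet[str]] = {}
    for disease in diseases:
        n_sh = min(n_shared, len(regional_genes))
        shared = rng.choice(regional_genes, size=n_sh, replace=False)
        rows, t_rows = [], []
        for g in shared:
            reg_sign = np.sign(regional_truth[g])
            agree = rng.random() < p_agree
            sign = reg_sign if agree else -reg_sign
            fc = float(sign * rng.uniform(max(logfc_min + 0.05, 0.3), 2.0))
            padj = float(_log_uniform(rng, 1e-8, fdr_max * 0.98))
            rows.append((g, fc, padj))
            t_rows.append((g, fc, bool(agree)))
        own = rng.choice(gene_pool, size=min(n_own, len(gene_pool)), replace=False)
        for g in own:
            fc = float(rng.choice([-1, 1]) * rng.uniform(max(logfc_min + 0.05, 0.3), 2.0))
            padj = float(_log_uniform(rng, 1e-8, fdr_max * 0.98))
            rows.append((g, fc, padj))
            t_rows.append((g, fc, None))
        remaining = sorted(set(gene_pool) - set(own))
        nulls = rng.choice(remaining, size=min(n_null, len(remaining)), replace=False)
        for g in nulls:
            # fail at least one threshold, most fail both
            fc = float(rng.uniform(-logfc_min, logfc_min))
            padj = float(rng.uniform(fdr_max * 1.2, 1.0))
            rows.append((g, fc, padj))
        df = pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])
        tables[disease] = df.sample(frac=1.0, random_state=int(rng.integers(2**31))) \
                            .reset_index(drop=True)
        truth[disease] = pd.DataFrame(t_rows, columns=["gene", "log2fc", "sign_agree"])
        sets[disease] = frozenset(np.concatenate([shared, own]))
    collection = GeneSetCollection(sets=sets, category="disease_deg")
    return collection, tables, truth


# ---------------------------------------------------------------------------
# whole-study bundle
# ---------------------------------------------------------------------------

@dataclass
class SimStudy:
    """All inputs of one synthetic run, plus the combined truth."""

    cm: CountMatrix
    truth: SimTruth
    gwas: GwasTable
    drugs: GeneSetCollection
    pathways: GeneSetCollection
    disease_degs: Dict[str, pd.DataFrame]

    def write(self, dir_path) -> None:
        from . import io as cvio
        d = Path(dir_path)
        d.mkdir(parents=True, exist_ok=True)
        cvio.write_10x(self.cm, d)
        cvio.write_gwas_table(self.gwas, d / "gwas.tsv")
        cvio.write_gmt(self.drugs, d / "drugs.gmt")
        cvio.write_gmt(self.pathways, d / "pathways.gmt")
        deg_dir = d / "disease_degs"
        deg_dir.mkdir(exist_ok=True)
        for disease, df in sorted(self.disease_degs.items()):
            df.to_csv(deg_dir / f"{disease}.tsv", sep="\t", index=False)
        self.truth.write(d / "truth")


def simulate_study(cfg: Optional[SimConfig] = None, seed: int = 0) -> SimStudy:
    """Generate counts, GWAS table, drug/pathway sets and disease DEG tables.

    The planted overlaps realize the study design: of the vulnerable
    subtype's TL-upregulated genes, ``gwas_overlap_vulnerable`` become GWAS
    genes (spread over diseases) and ``drug_overlap_vulnerable`` become drug
    targets (spread over the seven classes), a 2:1 drug:GWAS ratio by
    default. A pan-disorder block is planted in every disease.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    cm, truth = simulate_counts(cfg, seed=int(rng.integers(2**31)))

    planted_genes = set()
    for gs in truth.marker_map.values():
        planted_genes |= set(gs)
    for gs in truth.regional_map.values():
        planted_genes |= set(gs)
    filler_pool = sorted(set(cm.gene_ids) - planted_genes
                         - {g for g in cm.gene_ids if g.startswith("MT-")})

    vuln_up = sorted(truth.vulnerable_tl_up())
    n_gwas_overlap = min(cfg.gwas_overlap_vulnerable, len(vuln_up))
    n_drug_overlap = min(cfg.drug_overlap_vulnerable, len(vuln_up))
    v_gwas = list(rng.choice(vuln_up, size=n_gwas_overlap, replace=False))
    v_drug = list(rng.choice(sorted(set(vuln_up) - set(v_gwas)),
                             size=min(n_drug_overlap, len(vuln_up) - n_gwas_overlap),
                             replace=False))

    # pan-disorder genes: half from the vulnerable GWAS overlap, half elsewhere
    n_pan = cfg.n_pan_disorder_genes
    pan = list(v_gwas[: n_pan // 2])
    pan += list(rng.choice(filler_pool,
                           size=min(n_pan - len(pan), len(filler_pool)),
                           replace=False))
    used_filler = set(pan)

    planted_map: Dict[str, List[str]] = {d: list(pan) for d in DISEASES}
    for g in v_gwas:
        n_dis = int(rng.integers(1, 4))
        for d in rng.choice(DISEASES, size=n_dis, replace=False):
            if g not in planted_map[d]:
                planted_map[d].append(g)
    for d in DISEASES:
        need = cfg.n_gwas_genes_per_disease - len(planted_map[d])
        pool = sorted(set(filler_pool) - used_filler)
        if need > len(pool):
            logger.warning("simulate_study: GWAS filler pool exhausted for %s "
                           "(%d needed, %d left)", d, need, len(pool))
        extra = list(rng.choice(pool, size=min(max(need, 0), len(pool)),
                                replace=False))
        used_filler |= set(extra)
        planted_map[d].extend(extra)

    gwas, gwas_truth = simulate_gwas_table(
        cm.gene_ids, DISEASES, n_snps=cfg.n_background_snps,
        planted_map=planted_map, seed=int(rng.integers(2**31)),
        strict_fraction=cfg.gwas_strict_fraction,
        intergenic_fraction=cfg.intergenic_fraction,
    )
    truth.gwas_truth = gwas_truth

    # drug classes: vulnerable overlap round-robin, filled with background genes
    drug_sets: Dict[str, set] = {c: set() for c in DRUG_CLASSES}
    for j, g in enumerate(v_drug):
        drug_sets[DRUG_CLASSES[j % len(DRUG_CLASSES)]].add(g)
    pool = sorted(set(filler_pool) - used_filler)
    for c in DRUG_CLASSES:
        need = cfg.n_drug_targets_per_class - len(drug_sets[c])
        if need > len(pool):
            logger.warning("simulate_study: drug filler pool exhausted for %s", c)
        extra = list(rng.choice(pool, size=min(max(need, 0), len(pool)),
                                replace=False))
        pool = sorted(set(pool) - set(extra))
        drug_sets[c] |= set(extra)
    drugs = GeneSetCollection(
        sets={c: frozenset(s) for c, s in drug_sets.items()}, category="drug")
    truth.drug_truth = {c: frozenset(s) for c, s in drug_sets.items()}

    # pathways: a few seeded from marker blocks, the rest random, with overlap
    path_sets: Dict[str, FrozenSet[str]] = {}
    lo, hi = cfg.pathway_size
    seeded = sorted(truth.marker_map)[: max(cfg.n_pathways // 4, 1)]
    all_nuc = sorted(g for g in cm.gene_ids if not g.startswith("MT-"))
    for i, t in enumerate(seeded):
        members = set(truth.marker_map[t])
        members |= set(rng.choice(all_nuc, size=lo, replace=False))
        path_sets[f"PW{i:03d}_{t.replace('-', '_')}"] = frozenset(members)
    i0 = len(path_sets)
    prev: set = set()
    for i in range(i0, cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(all_nuc, size=size, replace=False))
        if prev and rng.random() < 0.5:  # share genes so the Jaccard net has edges
            members |= set(rng.choice(sorted(prev), size=min(5, len(prev)), replace=False))
        path_sets[f"PW{i:03d}"] = frozenset(members)
        prev = members
    pathways = GeneSetCollection(sets=path_sets, category="pathway")

    # disease DEG tables correlated with the regional truth
    regional_union: Dict[str, float] = {}
    for gs in truth.regional_map.values():
        for g, fc in gs.items():
            regional_union.setdefault(g, fc)
    _, deg_tables, deg_truth = simulate_disease_degs(
        cm.gene_ids, regional_union, cfg.disease_concordance,
        seed=int(rng.integers(2**31)), diseases=DISEASES[:3],
        n_shared=cfg.n_disease_shared, n_own=cfg.n_disease_own,
        n_null=cfg.n_disease_null,
    )
    truth.disease_deg_truth = deg_truth

    return SimStudy(cm=cm, truth=truth, gwas=gwas, drugs=drugs,
                    pathways=pathways, disease_degs=deg_tables)
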