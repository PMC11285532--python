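"""Run-level configuration: every threshold the pipeline applies.

All cut-offs live here so a run manifest can echo them and so CLI flags can
override any one of them without touching code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Tuple


@dataclass
class RunConfig:
    """Thresholds and conventions for a full pipeline run.

    Defaults are the cut-offs used throughout the analysis: UMI bounds and
    mitochondrial cap for cell QC, percentile bands defining "expressed"
    backgrounds, marker and differential-expression thresholds, GWAS p-value
    tiers, and the permutation/alpha settings of the enrichment stages.
    """

    seed: int = 0

    # cell QC
    min_umi: int = 300
    max_umi: int = 4000
    mito_max: float = 0.10
    gene_pctile: Tuple[float, float] = (5.0, 95.0)

    # marker detection (one-vs-rest logistic regression)
    marker_min_pct: float = 0.1
    marker_logfc: float = 0.25

    # regional differential expression (NB / quasi-likelihood)
    de_logfc: float = 0.5
    de_fdr: float = 0.05
    prior_df: float = 10.0
    n_logfc_clusters: int = 6

    # GWAS gene selection
    gwas_p: float = 1e-5
    gwas_strict_p: float = 1e-8

    # disease (case-control) DEG thresholds
    disease_logfc: float = 0.25
    disease_fdr: float = 0.05

    # expressed-gene background definition
    expr_pctile: Tuple[float, float] = (10.0, 90.0)
    expr_filter_mode: str = "gene_detection"  # or "cell_percentile"

    # enrichment machinery
    gsea_nperm: int = 1000
    gsea_weight: float = 1.0
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    spearman_alpha: float = 0.05
    enrich_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("gene_pctile", "expr_pctile"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= 100):
                raise ValueError(f"{name} must satisfy 0 <= low < high <= 100, got ({lo}, {hi})")
        positive = [
            "min_umi", "max_umi", "mito_max", "marker_min_pct", "marker_logfc",
            "de_logfc", "de_fdr", "gwas_p", "gwas_strict_p", "disease_logfc",
            "disease_fdr", "gsea_nperm", "spearman_alpha", "enrich_alpha",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_umi > self.max_umi:
            raise ValueError("min_umi must not exceed max_umi")
        if self.expr_filter_mode not in ("gene_detection", "cell_percentile"):
            raise ValueError(f"unknown expr_filter_mode {self.expr_filter_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_pctile"] = list(self.gene_pctile)
        d["expr_pctile"] = list(self.expr_pctile)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for name in ("gene_pctile", "expr_pctile"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


# canonical label sets used by the simulator and expected by the pipeline
MAJOR_TYPES = ("EX", "INH", "Olig", "Astro", "Micro", "OPC", "Endo")
EX_SUBTYPES = ("EX-L2-3", "EX-L4", "EX-L5", "EX-L6")
INH_SUBTYPES = ("INH-PVALB", "INH-SST", "INH-LAMP5", "INH-VIP")
REGIONS = ("TL", "FL")
DISEASES = ("BP", "ASD", "SCHI", "ADHD", "OCD", "UD", "CI")
DRUG_CLASSES = ("SSRI", "DA", "TCA", "BZD", "MAOI", "GABA", "ARA")


@dataclass
class SimConfig:
    """Parameters of the synthetic snRNA-seq study.

    The default design mirrors the study layout this package targets: two
    temporal-lobe (TL) subjects and one frontal-lobe (FL) subject, seven major
    cortical cell types with excitatory/inhibitory neuronal subtypes, and a
    designated "vulnerable" inhibitory subtype (PVALB) that concentrates the
    planted regional fold changes.

    Major-type composition defaults to the abundances typical of human
    cortex: excitatory neurons 38.3%, inhibitory neurons 23.6%,
    oligodendrocytes 22.1%, with the remainder split across glia and
    endothelium.
    """

    n_genes: int = 2000
    cells_per_subject: int = 1000
    n_subjects_tl: int = 2
    n_subjects_fl: int = 1

    composition: dict = field(default_factory=lambda: {
        "EX": 0.383, "INH": 0.236, "Olig": 0.221,
        "Astro": 0.06, "Micro": 0.04, "OPC": 0.035, "Endo": 0.025,
    })
    ex_subtype_split: dict = field(default_factory=lambda: {
        "EX-L2-3": 0.40, "EX-L4": 0.25, "EX-L5": 0.20, "EX-L6": 0.15,
    })
    inh_subtype_split: dict = field(default_factory=lambda: {
        "INH-PVALB": 0.30, "INH-SST": 0.30, "INH-LAMP5": 0.20, "INH-VIP": 0.20,
    })

    # per-gene NB dispersion phi ~ LogNormal(meanlog, sdlog); Var = mu + phi mu^2
    dispersion_meanlog: float = -1.2
    dispersion_sdlog: float = 0.5

    # per-cell library size ~ LogNormal around target_umi
    target_umi: float = 1500.0
    libsize_sdlog: float = 0.25

    n_mito_genes: int = 10
    mito_fraction_mean: float = 0.03
    doublet_rate: float = 0.02

    n_markers_per_type: int = 25
    marker_shift_log2: float = 3.0

    n_regional_degs: int = 200
    regional_logfc: float = 1.5
    vulnerable_subtype: str = "INH-PVALB"
    vulnerable_fraction: float = 0.5  # fraction of regional DEGs planted in it

    # planted cross-dataset overlaps
    n_gwas_genes_per_disease: int = 40
    n_pan_disorder_genes: int = 8
    gwas_overlap_vulnerable: int = 30   # GWAS genes drawn from vulnerable TL-up genes
    drug_overlap_vulnerable: int = 60   # drug targets drawn from the same pool (2:1)
    n_drug_targets_per_class: int = 40
    gwas_strict_fraction: float = 0.5   # fraction of planted SNPs below the strict tier
    intergenic_fraction: float = 0.3
    n_background_snps: int = 400

    # case-control disease DEG tables
    disease_concordance: float = 0.6    # sign agreement = (1 + c) / 2
    n_disease_shared: int = 100         # disease DEGs drawn from regional DEGs
    n_disease_own: int = 100            # disease DEGs independent of region
    n_disease_null: int = 300           # filler genes failing the thresholds

    # pathway collection
    n_pathways: int = 20
    pathway_size: Tuple[int, int] = (20, 60)

    def __post_init__(self) -> None:
        if abs(sum(self.composition.values()) - 1.0) > 1e-6:
            raise ValueError("composition fractions must sum to 1")
        for name, split in (("ex_subtype_split", self.ex_subtype_split),
                            ("inh_subtype_split", self.inh_subtype_split)):
            if abs(sum(split.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} fractions must sum to 1")
        if self.dispersion_sdlog < 0 or self.libsize_sdlog < 0:
            raise ValueError("log-normal sd must be >= 0")
        for name in ("doublet_rate", "vulnerable_fraction", "gwas_strict_fraction",
                     "intergenic_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1 <= self.disease_concordance <= 1:
            raise ValueError("disease_concordance must lie in [-1, 1]")
        if self.vulnerable_subtype not in set(EX_SUBTYPES) | set(INH_SUBTYPES) | set(MAJOR_TYPES):
            raise ValueError(f"unknown vulnerable_subtype {self.vulnerable_subtype!r}")
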