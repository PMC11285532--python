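# Methods

This note documents the statistical procedures implemented in `cellvuln`,
the defaults they run with, the design of the synthetic-data generator, and
what the passing test suite does and does not establish about real data.

## Study design and data model

The pipeline targets a two-region cortical snRNA-seq design: temporal-lobe
(TL) and frontal-lobe (FL) tissue from a small number of subjects (default
2 TL + 1 FL), with cells labelled by seven major types (EX, INH, Olig,
Astro, Micro, OPC, Endo) and neuronal subtypes (EX layers L2–3/L4/L5/L6;
INH PVALB/SST/LAMP5/VIP). Cell labels and doublet flags are inputs: the
package deliberately does not re-run embedding, graph clustering or doublet
detection, because the integrative analysis downstream is agnostic to how
labels were produced.

UMI counts are modelled as negative binomial with gene-wise dispersion
φ: Var(y) = μ + φμ². Gene identity is the uppercased symbol string
throughout; no alias translation is attempted, so symbol mismatches between
a GWAS table and the expression matrix silently reduce overlap (a warning
is logged when a query loses genes to the background universe).

## Quality control and normalization

Cells pass four filters, applied in a fixed order so the report categories
partition removals (each cell is counted at the first rule it fails):

1. total UMI inside [300, 4000] (inclusive bounds);
2. mitochondrial fraction ≤ 0.10 (genes whose symbol starts with `MT-`);
3. detected-gene count inside the [5th, 95th] percentile of the
   distribution over cells that survived rules 1–2;
4. flagged doublets removed.

Percentiles use linear interpolation between order statistics everywhere in
the package. Normalization is counts-per-10,000 followed by natural log1p;
zeros stay zero, and a cell's normalized vector is invariant to scaling its
depth.

### Expressed-gene backgrounds

Every enrichment test runs inside an "expressed" universe: genes whose
detection count (cells with ≥ 1 UMI) lies inside the [10th, 90th]
percentile band of the nonzero detection-count distribution, computed
globally or within one cell (sub)type. An alternative reading of this
filter — restrict to *cells* inside the per-cell percentile bands of both
detected genes and total UMI, then keep genes detected in at least one such
cell — is available as `expr_filter_mode="cell_percentile"`; the
gene-detection reading is the default because it is the operational form
stated for the replication analyses and is well defined at any scope.

## Marker detection

One-vs-rest logistic regression per gene and type on the log-normalized
values, likelihood-ratio test against the intercept-only model, BH-adjusted
within type, positive markers only. Pre-filters: detection ≥ 10% inside or
outside the type, and average log₂ fold change ≥ 0.25 computed on
expm1(normalized) means with pseudocount 1 (the single-cell convention; the
choice matters only near the threshold). The vectorized Newton solver uses
per-gene step halving on the log-likelihood, so completely separated genes
converge to a finite boundary fit instead of oscillating; the LR statistic
was checked against an independent MLE fit to 10⁻⁶.

## Regional differential expression

Per cell (sub)type, with both regions required:

* **Balanced downsampling.** TL and FL cell counts are equalized by seeded
  uniform subsampling to the smaller count (minimum 3 per side; types below
  that are skipped with a warning in pipeline mode).
* **TMM factors.** Trimmed mean of M-values against the column whose
  upper-quartile depth is closest to the mean: 30% two-sided trim on M, 5%
  on A, precision weights from the binomial delta method, factors scaled to
  geometric mean 1. All-zero genes are dropped first (they carry no
  information but shift quantile ranks). The implementation reproduces the
  reference R implementation (edgeR 4.0.16 `calcNormFactors`) exactly on
  test fixtures.
* **Dispersion.** The Cox–Reid adjusted profile log-likelihood of every
  gene is evaluated on one log-spaced grid of 15 dispersions spanning
  [10⁻³, 8]. The common dispersion maximizes the pooled curve (parabolic
  interpolation between grid points); tagwise dispersions maximize the
  gene's own curve plus `prior_df` (default 10) residual-df worth of the
  pooled curve, collapsing onto the common value as the prior grows.
* **Quasi-likelihood F-test.** Full (two-group) and reduced
  (intercept-only) NB GLMs are fitted by vectorized Fisher scoring with
  offsets log(library × factor) and linear predictors clipped at ±30.
  Gene-wise quasi-dispersions s²<sub>g</sub> = deviance / (n − 2) are
  shrunk by empirical Bayes: the prior df is estimated by moment matching
  on log s² (trigamma inversion) and floored at 3; the test statistic is
  the deviance drop over the moderated s², referred to F(1, df + d₀).
  log₂FC is the group coefficient over ln 2, positive = up in the
  first-named group (TL).
* **Thresholds.** DEGs satisfy |log₂FC| > 0.5 and BH-FDR < 0.05 (adjusted
  within type). The union logFC matrix (missing entries zero-filled:
  not-DE ≈ no change) is hierarchically clustered with Euclidean distance
  and complete linkage, cut at k = 6; cluster ids are relabelled by
  decreasing size for determinism.

Calibration and recovery, verified by the suite at the sizes noted: under
the null (identical NB groups, 2000 genes × 2 × 100 cells) the p-value
distribution has KS distance < 0.05 from uniform and a 5%-level
false-positive rate ≤ 0.07; planted 2-fold changes at 200 cells/side are
recovered with median |log₂FC error| ≈ 0.11; a planted dispersion of 0.4 is
estimated at ≈ 0.38–0.40.

## Gene-set machinery

* **GWAS selection.** Drop intergenic records; keep associations with
  p ≤ 10⁻⁵; per (disease, gene) retain the SNP with the lowest p
  (deterministic tie-break on SNP id); intersect with the expressed
  background. A strict tier (p < 10⁻⁸) is a second filter pass. Per-disease
  sets, the cross-disease union and the pan-disorder intersection are all
  emitted.
* **Overlap tests.** Upper-tail hypergeometric (P(X ≥ k)) everywhere; the
  one-sided Fisher test is provided and equals it on identical margins.
  Both agree with exact enumeration for every margin with N ≤ 25.
  BH adjustment is applied within one result table at a time (markers
  within type, regional DE within type, enrichment within analysis family),
  mirroring the reporting units of the analysis.
* **Enrichment score.** −log₁₀(BH-adjusted p). The raw k, q, t, N, p and
  k/t proportion are always emitted so any monotone rescaling can be
  recomputed.
* **Preranked GSEA.** Genes ranked by the statistic descending, ties broken
  by symbol (the ranking is therefore deterministic). ES is the signed
  extremum of the weighted running sum (hit increments ∝ |stat|^w, w = 1 by
  default; miss decrements uniform). The null permutes which ranks are hits
  (gene-label permutation — the input is a preranked list, so a phenotype
  null is unavailable); NES divides ES by the mean |null ES| of matching
  sign; the p-value is the +1-smoothed tail count over nperm (default
  1000), so its floor is 1/(nperm + 1). Set sizes outside [5, 500] after
  intersection are skipped. With w = 0 the statistic reduces to the classic
  unweighted Kolmogorov–Smirnov form (property-tested).
* **Composition test.** Per major type, a 2×2 chi-squared (type vs rest ×
  TL vs FL) without continuity correction, BH across types.

## Networks

* **Pathway network.** Nodes are pathways with BH-adjusted ORA p < 0.05;
  edges carry the Jaccard coefficient |A∩B|/|A∪B| of their gene sets;
  zero-similarity pairs are dropped, and no minimum-similarity threshold is
  imposed beyond that.
* **Co-expression network.** All pairs among the requested genes, within
  the cells of one compartment (subtype or major type, ≥ 4 cells).
  Tie-corrected Spearman correlation (Pearson on average ranks); two-sided
  p from the t approximation with n − 2 df, exact permutation p for n ≤ 9
  in the single-pair API. Edges retained at raw p < 0.05 by default — no
  multiple-testing correction, matching the convention of the analysis this
  package implements; a flag switches BH on. Both correlation signs are
  retained. Null calibration: for independent genes the edge retention rate
  is statistically indistinguishable from α (checked over 100 repeats with
  the between-repeat standard error, since pairs sharing a gene are
  correlated).

## Vulnerability integration

* **Disease DEG filter.** |log₂FC| > 0.25 and adjusted p < 0.05, split into
  up/down sets by sign.
* **Concordance.** Per (subtype, disease): hypergeometric overlap of the
  subtype's regional DEGs with the disease DEGs inside the subtype's
  expressed background (BH across all pairs), plus quadrant fractions of
  the shared genes by (regional sign, disease sign). Genes with an exactly
  zero fold change on either axis cannot be signed and are excluded from
  the quadrant denominator (logged). Shared genes in the GWAS union or drug
  union are counted per row.
* **Vulnerability contrast.** Per subtype: the fraction of TL-upregulated
  genes (log₂FC > +0.5, FDR < 0.05) in the GWAS union across diseases, the
  fraction in the drug-target union across classes, their ratio (defined
  only when the GWAS fraction is positive), and per-disease/per-class
  breakdowns. Unions deduplicate, so duplicated classes cannot inflate the
  contrast.
* **Proportion reporting.** Percentages use half-up rounding at 1 decimal
  by default (0-decimal display option) — e.g. 28/285 → 9.8, 17/38 → 44.7,
  displayed 45 at 0 d.p.

## Synthetic data: what it emulates, and what it does not

`simulate_study` generates every pipeline input with recorded truth:

| parameter | default | rationale |
|---|---|---|
| genes × cells | 2000 × 3000 (2 TL + 1 FL subjects × 1000) | desk-scale stand-in for the tissue design |
| composition | EX 38.3%, INH 23.6%, Olig 22.1%, rest split | typical human cortical proportions |
| library size | log-normal, median ≈ 1500, sdlog 0.25 | shallow snRNA-seq depth regime |
| dispersion φ | log-normal, median e^–1.2 ≈ 0.30, sdlog 0.5 | overdispersion typical of UMI counts |
| markers | 25 genes/type, +3 log₂ shift | strong identity programs |
| regional DEGs | 200 genes at |log₂FC| = 1.5; 50% planted in PVALB (TL-up) | vulnerability concentrated in one subtype |
| GWAS | 40 genes/disease, 7 disorders, 8 pan-disorder genes; 30 drawn from PVALB TL-up genes | genetic anchor overlapping the vulnerable subtype |
| drug targets | 7 classes × 40 genes; 60 drawn from PVALB TL-up genes | pharmacological anchor at a 2:1 drug:GWAS ratio |
| disease DEGs | 3 diseases; 100 region-shared genes with sign agreement (1 + c)/2, c = 0.6 | partial concordance between regional and disease axes |
| doublets | 2%, average-and-resample of two parents | keeps the library-size distribution realistic |
| mito fraction | Beta, mean 0.03 | healthy nuclei with a QC-relevant tail |

Regional fold changes are planted in genes between the 20th and 80th
percentile of baseline abundance: the vulnerability question is only posed
within the percentile-banded expressed background, so planting signal in
genes outside that testable universe would discard truth by construction.

Marker and regional effects act on relative abundances before per-cell
renormalization, so realized fold changes are slightly compressed relative
to the planted log-shift (the Monte-Carlo check allows ±0.3 log₂ at ≥ 300
cells). The GWAS table is built so that the selection rules recover the
planted per-disease gene sets *exactly* for any seed — an identity used as
an oracle test.

The generator does **not** emulate: ambient RNA, batch chemistry, subject-
level expression covariance (subject ids are recorded but, like the DE
model, carry no covariate), spatial structure, spliced/unspliced layers, or
gene–gene correlation beyond what cell types induce. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
stated NB model, not robustness to those real-data artefacts.

## Numerical choices

* Linear predictors clipped at ±30 and Newton steps at ±5 (NB GLM) /
  halved-on-decrease (logistic); boundary genes report finite, capped
  effects.
* The NB profile likelihood for scalar dispersions uses a cumulative-log
  table over integer counts instead of per-entry `gammaln`, and drops the
  gammaln(y+1) term (constant in both μ and φ) inside profile
  maximizations.
* Dispersion grids are log-uniform; maxima are refined by parabolic
  interpolation in log φ and clipped to the grid range.
* BH families are per result table; empty inputs return empty outputs.
* All randomness flows from explicit integer seeds (`numpy` Generator);
  two runs of the CLI with the same seed are byte-identical, which the
  suite checks by hashing every output file.

## Problem sizes used by the checks

Unit tests run a scaled study (800 genes, 900 cells, proportionally scaled
planted sets). The end-to-end recovery experiment uses the default design
(2000 genes, ≈ 3000 cells) over 20 seeds with regional DE on the eight
neuronal subtypes, where the subtype-resolved vulnerability contrast is
defined; calibration checks use 2000 genes at 100–200 cells per side. The
seeded determinism run uses 500 genes × 750 cells, determinism being
independent of problem size.

## Known limitations

* The DE model is two-group only (no covariates, no pseudobulk); subject
  effects are simulated and recorded but not modelled, mirroring the
  analysis the package implements.
* SNP-level enrichment frameworks (MAGMA/LDSC-style) and eQTL-based
  SNP-to-gene mapping are out of scope; gene mapping is taken from the
  input table as given.
* Symbol-level gene identity means cross-dataset alias mismatches reduce
  power silently (logged, not repaired).
* The quasi-likelihood test is calibrated at the simulated depths; very
  sparse genes (detection near zero) lean on the moderated denominator and
  their individual p-values should be read with care.
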