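# Methods

`hepatlas` re-implements, as a tested library, the computations used to
analyse immune-cell dynamics across chronic liver disease (CLD) stages —
healthy liver, MASH, cirrhosis, hepatocellular carcinoma (HCC) — and to
derive prognostic scores from bulk cohorts.  Every stage is exercised on
synthetic data with known ground truth; this note records the models, the
parameters that matter, and the design choices made where the procedure
was genuinely open.

## Quality control (`qc_markers.qc_filter`)

Cells are kept when the mitochondrial read fraction is **strictly below**
0.10 and the detected-gene count lies in the **inclusive** window
[200, 4000]; genes are then kept when detected in **strictly more than**
3 of the surviving cells.  The boundary conventions are deliberate and
tested (a cell at exactly 10% mitochondrial content is removed; a gene in
exactly 3 cells is removed; cells at exactly 200 or 4000 genes are kept).
The gene filter runs after the cell filter, which makes the operation
idempotent: the second application sees the same cells, hence the same
detection counts.

## Signature genes (`qc_markers`)

Differential expression is one-vs-rest per cluster: a Wilcoxon rank-sum
test (vectorized Mann-Whitney U with tie-corrected asymptotic p-values)
on counts-per-10k-normalized expression, with Benjamini–Hochberg
adjustment across genes within each cluster.  `avg_log2FC` is
`log2((m1+1)/(m2+1))` on normalized means; `pct1`/`pct2` are the raw
detection fractions inside/outside the cluster.  A constant gene yields
p = 1 and log2FC = 0 by convention.

Class-specific selection rules (strict inequalities):

* macrophage signatures: `p_adj < 0.01`, `pct1 > 0.5`, `pct2 < 0.5`,
  `avg_log2FC > 1`;
* T-cell signatures: `p_adj < 0.01`, `avg_log2FC > 0.5` (no detection
  rule; an optional `min_pct` prefilter is exposed for workflows that
  want the 25% detection floor used in generic marker discovery).

Curated non-specific genes (`ALB`, the liver background gene, and the
ubiquitous `ATP5F1E`) are removed before ranking.  Survivors are ranked
by **entropy-difference specificity**: for a gene with cluster-mean
profile m over K clusters, p = (m + ε)/Σ(m + ε) with ε = 1e-9 of the
total mass, and

    D = log2 K − H(p)   (bits),

so D = 0 for a uniformly expressed gene and log2 K for a perfectly
cluster-exclusive one.  D is scale-invariant and strictly decreases as
expression mass spreads across clusters.  This formula is this package's
operational definition of entropy-based specificity; the upstream
literature names the procedure without printing the formula, so the
definition here is declared rather than transcribed.

## Cell-state scores (`cellstate`)

Per cell, genes are ranked by decreasing expression; ties are broken by a
single seeded random permutation fixed per run, which preserves
exchangeability without biasing toward input order.  A gene set is
scored by the area under its recovery curve over the top
`ceil(top_fraction · n_genes)` ranks (default `top_fraction = 0.05`, the
reference rank-based scorer's default), normalized by the maximum
achievable area given the set size and window, so scores live in [0, 1]
and 1 is attainable.  The score is invariant to any strictly monotone
transform of a cell's expression and non-decreasing when a member gene
moves up in rank; both properties are tested, and the implementation is
checked to 1e-12 against an independent step-by-step recovery-curve
integration.

## Cohort scores (`cohort`)

The per-sample enrichment score ES is a single-sample GSEA running sum:
with genes ordered by decreasing expression within a sample, position i
contributes `w_i / Σ_set w` to the in-set ECDF when gene i is a set
member (weight `w_i = rank_value^α`, rank value n..1, α = 0.25) and
`1/(n − s)` to the out-of-set ECDF otherwise; ES is the sum of the ECDF
differences over all positions.  ES vectors are min–max rescaled across
the cohort to [0, 1] and floored at 0.01, so every downstream ratio is
defined; scores are therefore comparable within one cohort only.

The composite scores correct a subtype signature for immune abundance:

    Mscore = ES / IS          Tscore = ES · CA / IS

IS (immune score) is the mean rescaled enrichment over a user-supplied
panel of immune cell-type signature sets — any monotone per-sample
abundance proxy serves this role, and the panel is configurable rather
than tied to one deconvolution tool.  CA is the rescaled enrichment of
the cytotoxic-T signature, included in Tscore as a deviation correction.
The ratio identities (`Mscore·IS = ES`, homogeneity of degree −1 in IS)
hold exactly for every sample and are asserted in tests.

## Survival (`survival`)

Stratification splits samples at a cutpoint (cohort median by default,
ties to the low group), compares groups with Kaplan–Meier curves and the
log-rank test, and estimates the high-vs-low hazard ratio from a Cox
proportional-hazards fit with patient age as a covariate — the standard
operationalization of "age-corrected" survival contrasts.  If age is
constant (possible only in constructed data) the covariate is dropped
with a warning.  `cox_continuous` provides the per-SD companion fit on a
standardized continuous score.  The univariate screen fits one Cox model
per gene on standardized expression, BH-adjusts the Wald p-values and
flags direction (risk/protective); constant genes are excluded with a
warning.  Penalized multigene model construction is out of scope.

## Composition (`composition`)

Per-stage cell-type proportions carry bias-corrected and accelerated
(BCa) bootstrap intervals: cells are resampled with replacement
(n_boot = 1000, two-sided 95% by default, explicit seed required in the
CLI), the bias term z0 is the normal quantile of the fraction of
bootstrap statistics strictly below the point estimate (clipped to
avoid infinities), and the acceleration a is the jackknife skewness
`Σd³ / (6 (Σd²)^{3/2})` with d the leave-one-out deviations.  With
z0 = 0 and a = 0 the interval reduces exactly to the percentile interval
(same quantile rule), which is tested by construction, and the
implementation is cross-checked against an independent BCa
implementation.  Stage contrasts resample each stage independently and
jackknife across both stages.  The resampling unit is the cell within a
stage, matching pooled per-stage proportions; a clustered option
(resample whole donors) is exposed for pseudo-replication control.
Degenerate bootstrap distributions collapse the interval to the point
estimate with a warning.

## FISH quantification (`fish`)

Channel-separated rasters are thresholded (Otsu per channel by default;
explicit thresholds accepted), labeled with 8-connected components,
size-filtered (default minimum 5 px), and summarized by
intensity-weighted centroids.  An RGB/HSV micrograph export can be
split into channels upstream; channel-true input is strictly more
general and keeps the segmentation oracle exact.  DAPI components are
nucleus candidates; a marker is assigned when a spot centroid lies
within the typing radius of the nucleus centroid — diameter 20 μm for
macrophage markers, 10 μm for T-cell markers, i.e. radii 10 μm / 5 μm,
boundary **inclusive**.  The nearest assigned marker fixes the class;
within the class the nearest subtype marker names the cell (lineage
marker alone gives the bare class), and a nucleus carrying both a
lineage and a subtype marker of one class is flagged double-positive.
Tumor calls come exclusively from the tumor channel.  Distances are
Euclidean in μm; per cell the nearest-tumor distance is the minimum over
tumor centroids, and per-type medians summarize spatial organization.
Double-positive pairs are each subtype-bearing call paired with the
nearest same-class lineage-bearing call within the class radius — 0 μm
when both markers sit on one nucleus.  Pixel size must be supplied; no
magnification inference is attempted.

## Synthetic data (`simulate`)

The generators define the study conditions under which the pipeline is
validated.

**Single-cell counts.**  Negative binomial with mean/dispersion
parameterization (`variance = μ + μ²/θ`, default θ = 0.5), gene
baselines from a log-normal weight vector scaled to a mean library size
of 2000, per-cell log-normal library factors (σ = 0.3, settable to 0,
under which the marginal of a gene is exactly NB — verified by
chi-square goodness of fit).  Marker genes of type k have their mean
multiplied by `2^marker_log2fc` (default 3) in their own type and sit on
a low baseline (uniform 0.4–0.7 counts) elsewhere, the off-state
behaviour real subtype markers show and the regime in which detection
fraction thresholds are meaningful.  Mitochondrial fractions are drawn
uniform in (0.01, 0.08) as metadata.  Droplet artifacts (doublets,
ambient RNA), batch effects and cell-to-cell correlation are *not*
modelled, so passing tests demonstrate statistical correctness of the
pipeline, not robustness to those artifacts.

**Survival cohort.**  Log-scale expression with gene baselines N(5, 2)
and unit noise; signature genes are shifted by `signature_effect_sd`
(default 1.0) times the standardized planted burden z.  Survival times
are exponential with hazard `baseline_hazard · HR^z` (defaults 0.05,
HR = 2); censoring is an independent exponential whose rate is solved by
root-finding so the expected censoring fraction matches the target
(default 0.3); age is uniform in [40, 80] and independent of hazard.
The default sizes (n = 300 tumor samples, 2000 genes, 40 signature
genes) give Spearman ≈ 0.86 between the Mscore and z, and a median-split
age-adjusted group hazard ratio ≈ 2.2 — attenuated from the noiseless
median-split value ≈ 3.0 because the Mscore is a rank-based proxy of
the burden.

**FISH scenes.**  Nuclei, marker spots and tumor cells are filled discs
at exact planted coordinates; Gaussian pixel noise of sd `noise_level`
(max intensity 1) is optional, and at noise 0 the segmentation oracle is
exact.  `example_fish_config` builds an HCC-like scene — SPP1+
macrophage nuclei 6–10 px from a tumor centroid with Spp1/Clec4f spots
inside the 10 μm radius, Klf2+ T nuclei placed uniformly with Klf2/Cd3
spots inside 5 μm, 25 px minimum nucleus separation so typing is
unambiguous — and emits an analytically exact ground-truth table of
types and nearest-tumor distances.  No point-spread function, 3-D
structure or autofluorescence is modelled.

## Problem sizes used in validation

Simulation-based checks run at desk scale, chosen once as study
conditions: 500 simulations for bootstrap coverage and log-rank
type-I error, 50 seeds for hazard-ratio/power/correlation recovery at
n = 300 samples, 20 seeds for differential-expression effect recovery,
10 seeds (9,000 p-values) for null-uniformity, 3 seeds at 4 types × 200
cells × 1000 genes for marker sensitivity/precision, and single
noise-free 400×400 px scenes with 16 nuclei and 10 tumor cells for
geometry recovery.

## Known limitations

* ES rescaling is cohort-relative; Mscore/Tscore are not comparable
  across cohorts and no cross-cohort calibration is attempted.
* IS is an abundance proxy from a user-supplied signature panel, not a
  deconvolution estimate; different panels shift the scale (not the
  ordering) of the corrected scores.
* Wilcoxon p-values on sparse counts rely on the tie-corrected
  asymptotic approximation; at very small group sizes or near-constant
  genes the null distribution is visibly discrete.
* The FISH module operates in 2-D on channel-true rasters; thresholds
  and the component-size cutoff are data-dependent choices exposed as
  parameters (Otsu / 5 px defaults).
* Exponential survival with independent censoring admits closed-form
  checks but ignores time-varying hazards; the Cox step itself makes no
  such assumption.
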