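# Methods

This note documents the statistical models, fixed constants, numerical
choices and known limitations of glycopipe. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Glycan model

Glycan identity is a monosaccharide-count vector; bottom-up
fragmentation data cannot resolve linkage or branching, so structural
isomers with equal composition are one entity throughout. Compositions
use the search-engine dialect `Symbol(count)` with a fixed canonical
symbol order (HexNAc, Hex, Fuc, NeuAc, NeuGc, Pent, HexA, Sulfo,
Phospho), so equal compositions always render identically; a bare
symbol parses as count 1 (glycation is `Hex`). Monoisotopic residue
masses are the free monosaccharides minus one water, summed from
standard atomic masses; mass is linear in counts by construction.

Modification classes: glycation is exactly one hexose on lysine — any
other composition on K is rejected; N-glycosylation requires the
Asn-X-Ser/Thr sequon with X ≠ Pro, evaluated at 1-based coordinates on
the mature protein sequence (matching the field's site naming, e.g.
K143, N285).

Decoy glycans are primarily a curated non-human list supplied as a
newline-delimited file (141 targets + 141 decoys in the study design
this mirrors). When no curated list exists, `generate_decoy_glycans`
draws random compositions rejected against count-identity with any
target and constrained to the targets' [min, max] mass range (widened
by one hexose when degenerate), so decoys are plausible competitors in
a mass-tolerant search. `builtin_glycan_database` is a **synthetic**
stand-in panel — 141 enumerated high-mannose/complex/hybrid N-glycan
compositions plus 141 mass-matched decoys — used by the simulator and
tests; it is not a curated human serum list.

## PSM-level FDR

The combined P-score regresses the pooled binary decoy state (sequence
decoy OR glycan decoy) on Log-P and Delta-Mod with main-effects
logistic regression (scikit-learn, effectively unpenalised at C=1e6,
bounded iterations so quasi-separated score distributions terminate
with a warning rather than diverging). The P-score is the predicted
*target* probability, orientation-enforced so targets average at least
as high as decoys.

The threshold is the smallest observed P-score t such that among PSMs
with pscore ≥ t, #decoys/#targets < the FDR target (1% default). Ties
at the threshold are included; candidate cut points are restricted to
positions where the sorted score actually changes, so the reported
threshold is consistent with the "everything ≥ t passes" semantics.
The decoy-FDR denominator is the surviving *target* count (the
standard target-decoy estimate; with FDR ≪ 1 the distinction from
"all survivors" is negligible). Thresholding operates on the
concatenated multi-run PSM table, not per run. After thresholding, a
hard strict `Score > 200` cut is applied; both filters are row-wise
predicates and therefore commute (tested). Per-class (sequence vs
glycan decoy) FDRs are reported alongside the pooled estimate.

## Quantification matrix

Raw intensities are summed over duplicate (feature, sample) rows, then
log2-transformed; zeros and absent rows are missing. The observed mask
is immutable: imputation fills values but never flips the mask, so
every downstream count of "valid values" refers to measured cells.

Normalization median-centers each sample's observed values to the
median of per-sample medians (idempotent by construction). It stands
in for the quantification tool's own normalization when the matrix is
built from summed PSM intensities; externally normalized matrices pass
through unchanged up to the grand median.

Imputation draws each missing cell independently from
Normal(mean_obs − shift·sd_obs, (width·sd_obs)²) computed **per
sample** (column-wise, the common proteomics convention; the
whole-matrix alternative is not implemented), with shift 1.8 and width
0.3 as defaults. This encodes the left-censoring premise: absent
values are below the detection limit, so their surrogate distribution
sits in the low tail. Samples need ≥ 2 observed values for a usable
SD.

The validity filter keeps features with ≥ 70% observed values in at
least one stratum. Strata are a parameter: groups for the baseline
analysis, group × timepoint cells for the longitudinal analysis —
which is why the two analyses can retain different feature counts from
the same matrix. The comparison uses a 1e-12 tolerance so a feature at
exactly 70.0% (e.g. 7 of 10) is kept. The pipeline imputes first and
filters second, but because filtering counts the original mask, the
retained set is identical under either ordering.

## Differential analysis

**Baseline.** Per feature, OLS of log2 intensity at the first visit on
a decliner indicator plus covariates (mean HbA1c by default; baseline
age optional via config, off by default at T1 and always included in
the longitudinal model). Decliner is coded 1, so positive
coefficients mean up in decliners. The group coefficient is the
adjusted log2 fold change; its two-sided t test gives p. Fits are
batched across features as multi-RHS least squares on the shared
design (the feature-wise results equal statsmodels OLS to 1e-10;
tested). Constant covariates are dropped with a warning; a
rank-deficient design (covariate collinear with group) flags every
feature rather than raising. Significance requires p < 0.05 AND
|log2FC| ≥ 1 (a two-fold change), both thresholds a-priori
configurable.

**Rate of change.** The longitudinal model is a random-intercept
linear mixed model; the group × time interaction is the difference in
the T1→T2 change between groups. Two engines:

- *paired* (default for balanced, fully observed two-visit designs,
  which is what the pipeline produces after imputation): the mixed
  model is fit exactly via the orthogonal between/within
  decomposition. Between-subject covariates cancel in the
  within-subject differences, so the interaction estimate reduces to
  OLS of per-subject differences on group — identical to the
  difference-in-differences of group × time cell means — and its p
  comes from the within-stratum t with n_subjects − 2 df (the
  classical paired analysis; exact under the model).
- *mixedlm*: statsmodels MixedLM (REML) per feature for general or
  unbalanced designs. Wald p-values use a containment-style df
  (n_obs − n_subjects − #within-varying fixed effects) rather than the
  normal approximation; Satterthwaite df are not available in
  statsmodels, and on balanced designs the containment rule gives the
  same df Satterthwaite converges to. Non-convergence falls back to
  OLS of per-subject T2−T1 differences on group, recorded per feature
  in the `method` column.

The two engines agree on estimates to 1e-6 and on p-values to a few
percent (tested). Rate significance is p < 0.05 with no fold-change
gate. No multiple-testing correction gates any call — at this cohort
size none would survive — but BH q-values are reported as an extra
column in both analyses.

**Descriptive operators.** Signed fold change maps log2 effects to the
reporting convention where −16.0 means 16-fold down (2^x for x ≥ 0,
−2^−x otherwise), with an exact inverse. Glycation proportion,
multiplicity histograms (glycopeptiforms per protein; distinct glycans
per protein site) and the Venn/overlap logic are exact counts.
`summary_stats_ttest` is the pooled-variance two-sample Student t from
mean/SD/n summaries (df = n1+n2−2), for reproducing published
demographic-table comparisons; zero-variance corner cases return t=0,
p=1 (equal means) or p=0 with a warning (unequal means).

## Enrichment

One-sided hypergeometric upper-tail test per pathway, members
intersected with the background universe first; BH across tested
pathways; enrichment at q < 1e-3. The default background is the
in-experiment universe — every protein carrying a quantified
glycopeptiform in the rate analysis — a deliberate, configurable
choice since web-service defaults (whole annotated proteome) are not
reproducible offline. Hit lists are the rate-significant features
split by modification class and effect sign, collapsed to unique
accessions. This module is a methodological stand-in for web-based
pathway analysis, not a replication of any service's statistics.

## Synthetic-data generator

The generator is first-class, tested code that defines the study
conditions for every downstream check.

*Cohort*: 8 decliners + 14 non-decliners, two visits each (44
samples); baseline age ~ N(74.5, 2.5²) years, mean HbA1c ~ N(6.7,
0.55²) % — the scale of the emulated cohort's demographics table.

*Intensities*: per feature f and sample of subject i at visit t,
y = μ_f + b_{f,i} + β_f·decliner + γ·T2 + δ_f·decliner·T2 + ε,
with b ~ N(0, 0.5²), ε ~ N(0, 0.3²), μ_f ~ U(18, 26) on the log2
scale. Defaults plant 150 baseline effects of ±2 log2 units and 150
interaction effects of ±1.5 log2 units among 3,000 features, plus a
global visit shift γ = 0.3 (the emulated data show a clear
between-visit separation). 45% of features are glycated (`Hex` on K);
the rest carry random synthetic N-glycans.

*Missingness*: intensity-dependent left censoring — cell (f, s) is
removed with probability sigmoid((c − y)/scale), with c calibrated by
bisection so the overall missing fraction hits the 36% target. The
smooth MNAR mechanism (rather than a hard global quantile cut) keeps
low-abundance features partially observed, matching how real runs lose
cells near the detection limit, and is exactly the premise the
down-shifted imputation assumes. A hard cut would also delete
low-mean features outright. Censoring is monotone in c.

*PSMs*: correct targets draw Log-P ~ N(5, 1.2²), Delta-Mod ~ N(15,
5²), Score ~ N(400, 120²) (clipped at 0); decoys and a 5% incorrect
target fraction draw N(1.5, 1²), N(3, 2.5²), N(120, 60²). Because
incorrect targets share the decoy distribution, the decoy count is an
unbiased proxy for false target matches, which is what the FDR-control
property tests exploit. Decoys split evenly between sequence- and
glycan-decoy classes.

All randomness derives from one master seed via
`default_rng([seed, STREAM])` with fixed per-stage stream ids, so any
stage reproduces in isolation and byte-identical outputs follow from
identical seeds.

**What passing tests do and do not show.** The generator draws
Gaussian log-intensities with homoscedastic noise, independent
features, no batch or run-order structure, no retention-time or
match-between-runs artifacts, and an exactly logistic censoring
mechanism. Passing recovery and calibration tests therefore validates
the estimators under the model the analysis itself assumes — they do
not certify performance on real serum data, where feature correlation,
heavy tails and non-logistic censoring will erode power and FDR
control to a degree the simulation cannot measure.

## Problem sizes and numerical choices

The test suite runs the FDR-control property at 200 replicates of
5,500 PSMs, mixed-model recovery at 200 cohort replicates, null
calibration at 2,000 feature-level tests, the imputation check at
10,000 features, and pipeline determinism at the generator default of
3,000 features × 44 samples — sizes chosen so the whole suite
completes in under a minute on one core while keeping Monte-Carlo
error well inside the asserted tolerances. Thresholds follow the
workflow's fixed operating point (decoy-FDR < 1%, Score > 200, 70%
valid, shift 1.8/width 0.3, p < 0.05, |log2FC| ≥ 1, q < 1e-3) and are
all exposed in `PipelineConfig`.

## Known limitations

- Glycan structure/isomer resolution is out of scope by design;
  compositions are the identity unit.
- Spectral search, match-between-runs and retention-time modeling are
  upstream of this package; their outputs are consumed, not modeled.
  The built-in PSM-intensity summation is a deliberately simple
  quantification stand-in for pipelines without a dedicated LFQ tool.
- The mixed model assumes a common residual variance across groups and
  visits; with 8 vs 14 subjects, heteroscedasticity is neither
  detectable nor modeled.
- The categorical (sex-ratio) group comparison of demographics tables
  is not implemented: small-sample categorical p-values depend
  strongly on the exact test variant, and no variant is canonical
  here.
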