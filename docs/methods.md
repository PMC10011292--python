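# Methods

## Germination statistics

A germination assay plates 30 kernels per plot in duplicate and counts
germinated kernels at 24/48/72 h. GE is the germinated fraction of plated
kernels (non-viable kernels are not distinguished; all plated kernels enter
the denominator). GI is the inverse-mean-germination-time index

    GI = 10 (n24 + n48 + n72) GE / (1 n24 + 2 n48 + 3 n72),

bounded in [0, 10], equal to 10 only when every plated kernel germinates on
day one. A plate on which nothing germinates is a 0/0 case; we define GI = 0
there — the dormant extreme, consistent with lower GI indicating better PHS
resistance. Technical replicates are summarised per plate first and then
averaged per plot × timepoint (not pooled counts); GI at TP1 (6 days post
physiological maturity) is exposed as `phs_score`.

## The REML engine

All model stages reduce to the Gaussian mixed model
y = Xβ + Zu + e with u ~ N(0, G), e ~ N(0, R), where G per grouping factor is
IID (one variance), DIAG (one variance per level of a stratifier — e.g. a
line variance per selection cycle, or independent line effects per trait) or
US2 (an unstructured 2×2 covariance over a two-level trait factor), and R is
IID or DIAG by a stratifier (year, or trait × year). Estimation maximises the
restricted log-likelihood

    l_R = -½ [(n−p) log 2π + log|V| + log|X'V⁻¹X| + y'Py]

via the Woodbury identity, so only W = G⁻¹ + Z'R⁻¹Z is factorised. For every
model in this family W decomposes into independent blocks of 1–4 columns (one
per line); blocks are batch-factorised by Cholesky. Numerical choices:

* **Parameterization.** Variances on the log scale; the US2 block through the
  Cholesky of the 2×2 matrix (positive semi-definite by construction);
  correlations reported post hoc. Log-variances are bounded in [−16, 13] on
  the unit-scaled response; estimates at the lower bound are reported as 0
  with an `at_bound` flag.
* **Optimisation.** L-BFGS-B with *analytic* gradients of the restricted
  likelihood (verified against finite differences in the test suite),
  multi-started from three deterministic start vectors (a moment-based split
  of the OLS residual variance and ±log 4 perturbations) to guard against
  local optima. The response is centred and scaled internally; results are
  returned on the original scale, with the log-likelihood adjusted by
  −(n−p) log c.
* **Convergence.** Relative-likelihood/gradient termination; when the line
  search stalls at machine precision the optimum is accepted if the projected
  gradient is below max(10⁻², 10⁻⁵ |l_R|). Genuine non-convergence is a
  flagged state on the fit, never silent.
* **Identifiability.** Refused (with the offending terms named) when the
  total number of random-effect levels reaches n; aliased fixed-effect
  columns are detected by pivoted QR, dropped and reported.
* **Inference.** REML LRTs require identical fixed structures and identical
  response data (enforced); the statistic is clipped at 0. The correlation
  test uses 1 df (correlation 0 is interior); the cycle-variance homogeneity
  test uses n_cycles − 1 df, noting the χ² is approximate near variance
  boundaries. Wald t-tests use residual degrees of freedom n − rank(X) — a
  documented approximation to Kenward–Roger, whose exact form for
  heterogeneous structures is out of scope; acceptance checks use effect
  sizes for which the df choice is immaterial.

## Variance partitioning and heritability

Per trait: model 'Y = plot + e' on technical replicates gives the assay
repeatability σ²_pl/(σ²_pl+σ²_e). Within a year, 'Y = TP + g + g:TP + e'
splits line variance from line-by-timepoint deviations. σ²_g:TP confounds
genuine after-ripening change with plot-level sampling error, σ²_g:TP ≈
σ²_Δg:TP + σ²_pltE. The replicated check cultivar (grain from one lot)
estimates σ²_pltE: every check insertion is a separate sampling event per
malting timepoint, so the variance of check sample means is pooled *within*
timepoint (removing the aggregate after-ripening shift) and the assay error,
scaled by the technical-replicate count, is subtracted. Sample means rather
than raw values are used because σ²_pltE is defined at the sample level.
Negative σ²_Δg:TP estimates are reported and flagged, never truncated — they
are an honest feature of the difference estimator. `ratio1 = σ²_pltE/σ²_g:TP`
(documented as inferred) and `ratio2 = σ²_Δg:TP/σ²_g` summarise relative
importance.

Across years, 'Y = year + TP + year:TP + g + g:TP + e' yields
H² = σ²_g/(σ²_g + σ²_g:TP + σ²_e/y). The per-year variant divides by σ²_e
un-scaled (y = 1); this per-year form is a labelled assumption. The
assay-error input to the check estimator defaults to the repeatability-model
residual (config-selectable).

## Line BLUEs

Line effects are reported as adjusted means — line coefficient + intercept +
the equally-weighted average over observed covariate cells — so the labelling
schemes (per-TP, "TP4/TP6", "20/21", "19/20/21", "Combined") are directly
comparable; the contrast convention was genuinely open and this choice is
ours. The across-year scheme estimates per-year residual variances by REML
and applies feasible GLS, falling back to homogeneous weights with a warning
if the variance fit is unusable. Because the weights are *estimated*, the
balanced-data identity "BLUE = simple mean" holds only to O(1/√n) for this
route (exact for the others). First-year observations without controlled
after-ripening are assigned the TP6 label before across-year fits. The
timepoints-as-replicates model pools any line × TP interaction into the
residual.

## Genetic correlations and HvMKK3 stratification

The bivariate model stacks two traits' plot-level means (technical replicates
averaged, so observations pair by plot): trait-by-year cell means fixed, a
2×2 unstructured line covariance, and trait-by-year diagonal residuals.
Residual cross-trait covariance is fixed at zero: germination and malting are
measured on different grain samples from the plot, and with mostly one plot
per line per trial such a covariance is near-unidentifiable. r_g is reported
even at the ±1 boundary (flagged `boundary`); a group with no genetic
variance in a trait yields a flagged undefined r_g. Scans run across lines
and within each *HvMKK3* allele group; the allele is classified from the
E165Q causal marker (mutant → N*) and a linked 50k marker separating N from D
among wild types — the 50k allele orientation is not derivable from public
text, so the mapping is config-driven with the documented default; any
unresolved call yields UNKNOWN and excludes the line from within-allele
analyses. Significance stars use p < 0.01. Phenotypic correlations use
scaled-and-centred BLUEs with pairwise-complete lines (chosen over casewise
deletion to preserve n); biplots come from the eigen-decomposition of that
matrix with small negative eigenvalues (a pairwise-completion artefact)
clipped at zero with a warning.

## Correlated response to selection

Per trait: fixed year, cycle, timepoint and their two-way interactions
(an interaction is dropped with a logged note when a cycle×year or cycle×TP
cell is empty — the augmented design is unbalanced by construction), a line
random effect with one genetic variance per cycle, and one residual variance
per year. Cycle contrasts are against the C0 base; parents are excluded by
default (configurable). The homogeneity LRT compares against a single genetic
variance. Reporting follows mean ± two genetic standard deviations per cycle
with star tiers p < 0.05/0.01/0.001/0.0001; observed cycle means are shown
alongside the model-based contrasts.

## Quality scoring

Scoring is entirely config-driven: per trait and end use (adjunct /
all-malt), ordered half-open bands [lo, hi) → points with an implicit 0-point
catch-all, plus an acceptance interval per trait for range classification
(ALL_MALT / ADJUNCT / BOTH / NEITHER). Overlapping bands are a config
validation error. The packaged `data/scoring_default.yaml` is an
**illustrative synthetic configuration** — plausible magnitudes for 2-row
spring barley, not any lab's published point tables, which are not publicly
printed.

## Marker QC

Heterozygosity ≤ 0.10 and MAF ≥ 0.05 are retained (the filters are phrased as
strict inequalities on the removal side, so the boundaries survive). MAF
counts HET calls as half a dose of each allele — the treatment of HET calls
was open and this is our choice. Markers with no non-missing call are
excluded with a warning. The operation is idempotent.

## The synthetic generator

The generator emulates the study design: eight founders (a common parent
crossed to seven family parents), a C0 base of half-sib families, and
selected cycles — C1P by a phenotypic index, C1G/C2G by an idealised genomic
index (true breeding values blurred by an accuracy noise of 0.6 GI units).
C1 parents are the best two per family; C2 uses mass truncation selection of
the top 25%. The index weights GI at TP1 heavily (selecting low = resistant)
and grain protein lightly. Genetics are a single major locus plus an
infinitesimal polygenic background: progeny receive mid-parent polygenic
values plus a segregation draw at half the polygenic covariance and inherit
one parental allele at the major locus (inbred lines, no linkage map —
genome-wide markers exist only for the QC operation, simulated unlinked).
A `family_structure=False` panel mode draws C0 values i.i.d. from the
configured covariance; calibration and recovery scenarios use it because
moments conditional on only eight founder draws cannot match the configured
values to a few percent.

After-ripening follows saturating curves per allele: mean germination day
d(t) = 1 + 2 exp(−t/τ_d) and capacity GE(t) = ge_max (1 − exp(−t/τ_g)), so
latent GI(t) = 10 GE/d rises monotonically with days post PM and plateaus —
the curve form is our choice; defaults (τ_d = 60/15/4 days for D/N/N*) put
the allele separation at TP1 and near-asymptotic values before ~48 days.
Plates are drawn per kernel: capacity is clipped into [GI/10, 3GI/10] so the
implied mean germination day stays in the observable 1–3-day window and the
expectation of the plate GI statistic tracks the latent line GI.

Malting values are mean + year + timepoint shift + allele effect + polygenic
value + a per-line×TP after-ripening deviation (SD `dgtp_sd`) + a
per-plot×TP sampling error (SD `pltE_sd`) + per-replicate assay error, with
duplicate (SP/ST/ME/MP) or triplicate (FAN/BG/AA/DP) technical replicates;
a check cultivar with no genetic term is inserted every 15 samples. Default
trait scales (e.g. FAN mean 190 ppm, polygenic SD 20, N*/N allele effects
+32/+10 ppm) are realistic magnitudes for North American 2-row malting
barley; the polygenic correlation matrix is built from configured pairwise
entries and repaired to the nearest valid correlation matrix by eigenvalue
clipping. Every latent value, realized per-group genetic correlation,
variance-component truth, cycle mean and allele frequency is recorded in a
`SyntheticTruth` object for recovery tests.

What the generator does **not** emulate: linkage and LD structure, spatial
field trends, genotype×environment interaction beyond additive year effects,
location effects (the emulated study malts grain from one location per
year), kernel viability loss, and non-Gaussian assay error. Passing recovery
tests therefore demonstrates correctness of the estimators under the stated
model, not robustness to those real-data features.

## Problem sizes in the test suite

The acceptance checks run at desk scale as the package's own choice of study
conditions: 20 balanced designs of 50 groups × 4 replicates for the
closed-form comparison; 20 replicates of 500 lines × 2 years for r_g
recovery (Gaussian malt-trait pair; the plate-count germination route has a
separate recovery test at a looser ±0.1 tolerance because the 30-kernel
statistic adds non-Gaussian noise); 200 replicates of 200 lines for the LRT
null calibration; 50 replicates with ~50 check samples for the plot-error
decomposition; 50 generator replicates of 60 lines/cycle for the
selection-response direction; and the study's actual cycle sizes with a
FAN-like signal-to-noise for the variance-homogeneity LRT power. The
allele-frequency criterion reads "monotonically" as non-increasing across
C0 → C1G → C2G with a strict overall reduction, since a cycle already at
frequency 0 cannot decrease strictly.

## Known limitations

* Degrees of freedom are a residual approximation, not Kenward–Roger; p
  values for small effects in strongly unbalanced layouts are approximate.
* The χ² reference for the variance-homogeneity LRT is approximate when a
  cycle variance sits near zero.
* Clipping of latent GI at 0 and 10 attenuates within-group genetic
  correlations at extreme timepoints (dormant lines at TP1, non-dormant lines
  late) — as in real germination data.
* Feasible-GLS BLUEs depend on estimated year weights; with few plots the
  weights themselves are noisy.
* The 2×2 unstructured covariance does not generalise to >2 traits; no
  spatial/AR1 residuals; no pedigree or genomic relationship matrices (line
  effects are IID, as in the emulated models).
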