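# Methods

## Neck-width geometry

An annotation is 85 ordered landmarks in image pixel coordinates plus the
per-axis pixel spacing (mm/px). The inferior femoral-neck contour is traced
by landmarks 6–12 (1-based) and the superior contour by 32–38. FNW is the
minimum distance between the two open polylines after scaling x by the
column spacing and y by the row spacing:

* the distance is the exact bidirectional point-to-segment minimum — every
  vertex of one contour against every segment of the other, both ways. For
  non-crossing contours this equals the true segment-pair minimum, because
  the closest approach of two non-intersecting segments is always realized
  at a vertex of one of them;
* crossing contours (invalid anatomy) are detected by an explicit
  segment-intersection test and return 0 with a warning;
* anisotropic spacing is supported; scaling precedes the distance. The
  measure is invariant under rigid motion with isotropic spacing (checked
  to 1e-9) and is side-agnostic — left/right flipping is the caller's
  concern.

## Synthetic data

The generator produces every input with known truth; its defaults encode
the study conditions the analyses assume.

**Genotypes.** Haplotypes are latent standard-normal vectors with AR(1)
correlation ρ^|i−j| inside LD blocks and independence across blocks; an
allele is carried when the latent value falls below the allele-frequency
quantile, and dosage is the sum of two independent haplotypes. This gives
controllable LD with no ancestry or relatedness structure — deliberately,
since only the LD algebra matters downstream; the mixed-model machinery a
real biobank scan needs is therefore out of scope, and the quantitative
scan is plain per-variant least squares (a declared simplification, not an
emulation). The closed-form dosage r² implied by the latent model (bivariate
normal orthant probability) is exposed for oracle checks.

**Architecture.** Defaults: 71 FNW signals and 49 FN-BMD signals, 15
shared (14 with opposite signs, 1 LRP5-like same-sign), FNW genetic
variance 7.6% of a unit-variance trait (BMD: 15%, a free choice in the
plausible range for a DXA trait). Causal variants are placed at a random
column within distinct LD blocks: systematic edge placement would correlate
causality with local LD score and bias LD-score regressions. Effect sizes
are drawn from a shifted normal and rescaled so the standardized-genotype
effect vector has exactly the target variance.

**Traits and covariates.** Standardized FNW = genetic value (rescaled to
the target variance) + a shared body-size latent factor (loading 0.25,
feeding height and weight so body-size adjustment attenuates GRS effects
qualitatively) + a small age trend (loading 0.05) + Gaussian noise topping
the variance up to 1. Millimetre FNW applies per-sex mean/SD 34.6/2.4
(males) and 29.0/2.0 (females); sex enters through these means, not a
regression coefficient. Ages are drawn per sex (64.5/7.6, 63.1/7.4 yr),
48% male.

**Fractures.** Per-site exponential proportional hazards with log-hazard
`log_or_fnw·FNW_sd + log_or_bmd·BMD_sd` around per-site baseline yearly
rates (defaults: femoral neck 6.5e-4, trochanteric 6.5e-4, forearm 2e-3 —
chosen to give roughly the 1%/15.5-yr hip incidence of an unselected adult
cohort). Default hazard effects per SD: FNW log(1.5) at hip/femoral-neck
and 0 at trochanteric/forearm (site specificity is generated, not
emergent); FN-BMD log(0.45) at hip sites and log(0.6) at the forearm
(protective everywhere). The any-hip event is the earlier of the two hip
subtypes, so subtype events imply an any-hip event by construction.
Follow-up is censored administratively at 15.5 yr; a pre-baseline window
(default 5 yr) generates prevalent hip-fracture flags from the same
hazards. A configurable fraction (default 10%; 50% in the desk-scale
pipeline so both halves are usable) is flagged as the discovery subsample.

**Annotations.** The two neck contours are parabolic arcs bulging toward
each other with vertically aligned apexes separated by exactly the target
width; curvature 0.05/mm puts the apex neighbours ~0.45 mm farther out, so
the closest pair is unique. Landmark jitter is i.i.d. Gaussian per
coordinate in mm. Consequences, verified against the measurement: at zero
jitter the round trip is exact; at jitter σ the recovered width is
approximately N(target, √2·σ) — unbiased, but its upper tail is that of a
normal, so "never more than 3σ above target" holds only per ~98% of seeds,
not surely. The remaining 71 landmarks form a schematic head/shaft outline
that the measurement never touches.

**Summary-statistic simulator.** For heritability/correlation recovery at
large variant counts, z-scores are drawn directly from the sampling model
`z = √n·R·b + ε, ε ~ N(0, R)` with per-variant standardized effects
`b ~ N(0, h²/M)` (bivariate with correlation r_g for two traits, no sample
overlap), block-diagonal R. This is the model LD-score regression assumes;
it avoids materialising an n×M genotype matrix where n·M ~ 10⁸. The
genotype-level route is exercised at smaller M in the unit tests.

**What the generator does not emulate** — ancestry and relatedness,
imputation error (INFO is 1.0 everywhere; the INFO filter is tested with
edited fixtures), haplotype phasing, competing risks of death, and
realistic femur anatomy. Passing tests therefore validate the statistical
machinery, not robustness to those real-data features.

## Association scan and conditional selection

The phenotype is built per sex: least-squares residual on age, chip and 20
PCs, standardized to mean 0/SD 1, then concatenated — so sex is balanced by
construction and adding it as a covariate changes nothing. Scans filter
MAF ≥ 1% (cohort-estimated) and INFO > 0.3; quantitative tests are
two-sided t with n−2 df, binary scans are per-variant logistic with age and
sex, flagging complete separation as unusable.

Conditional-and-joint selection works on the standardized-genotype scale
(β·√(2·EAF·(1−EAF)) on a unit-variance phenotype), where a single-cohort
design with homogeneous n makes the correlation-matrix algebra equivalent
to the allele-count parameterization. Stepwise loop: start from the
smallest-p genome-wide-significant variant (ties: smallest p, then
chr:pos); for every remaining variant compute the joint coefficient it
would take when added to the selected set S,
`b_t|S = (b_t − r_tSᵀ R_S⁻¹ b_S)/(1 − r_tSᵀ R_S⁻¹ r_tS)`, with variance
`σ²/(n(1 − r_tSᵀR_S⁻¹r_tS))` (σ² kept at 1 — conservative); add the
smallest conditional-p variant below 5e-8; variants with r² > 0.9 to any
selected variant are ineligible; a singular LD matrix drops the latest
candidate with a warning. Final joint effects are `R_S⁻¹ b_S` with the
residual variance estimated as `max(1 − b_jointᵀ b_S, 0.05)`, back-
transformed to the allelic scale. With in-sample LD this reproduces exact
individual-level stepwise selection and joint least squares (tested).

Variance explained is `Σ 2·EAF·(1−EAF)·β²` — the independent-signal
formula; it can differ from a joint-model R² when selected signals are
correlated, which is why the tests also compare against a realized joint
fit. MAF classes: low-frequency 1% < MAF ≤ 5% (boundary inclusive, with a
1e-9 float guard), common > 5%. Nearest-gene annotation takes BED
(0-based half-open) intervals against 1-based positions; ties prefer the
upstream feature, then the smaller start, deterministically.

## LD-score regression

Scores sum bias-adjusted squared correlations `r̃² = r² − (1−r²)/(n_ref−2)`
over a window (default 1000 kb) including the exact self term; variants
with MAF ≤ 5% are excluded (standing in for the usual common-SNP
restriction). Heritability is the slope of a weighted regression of χ² on
`n·ℓ/M`; the cross-trait regression of z₁·z₂ estimates the genetic
covariance with a free intercept absorbing sample overlap. Weights are
1/ℓ in a single pass — the full iterative weighting scheme buys little at
desk-scale variant counts, and the recovery tests validate calibration.
Standard errors are delete-one-block jackknives over contiguous blocks
(default 200, reduced with a warning when variants are scarce); the r_g
p-value is a normal test on the jackknife ratio, with significance at the
Bonferroni-style α the caller supplies (default 0.05/3). Non-positive
heritability makes r_g undefined and returns an error record rather than a
number. Known limitation: with sparse architectures (tens of causal
variants among a few thousand) single-cohort estimates are unstable and can
go negative — an honest desk-scale outcome the pipeline simply reports;
heritability for binary traits is on the observed scale.

## Mendelian randomization

Instruments: genome-wide significant (5e-8), MAF > 1%, greedy ascending-p
pruning at panel r² < 0.01. When two exposures contribute instrument lists,
cross-exposure pairs in LD are resolved by keeping the member more strongly
associated with the second exposure (primary rule) or the first
(sensitivity mode), processing pairs in descending r² so clusters resolve
deterministically.

Harmonization aligns outcome (and second-exposure) rows to the exposure's
effect allele: label match, swap (flip β, complement EAF), or strand
complement; palindromic single-base variants are aligned by allele
frequency when both MAFs < 0.42 and removed as non-clear-strand otherwise;
irreconcilable pairs and missing variants are dropped and counted. Steiger
filtering removes variants whose outcome correlation significantly exceeds
their exposure correlation (one-sided Fisher-z at α = 0.05), with the
binary-outcome r² on the observed scale from the logistic β and case
fraction — liability-scale conversion is deliberately deferred. Instrument
strength is the mean F, `mean((γ/se_γ)²)`.

Estimators (per-SD exposure effects on the outcome log-odds scale):

* **IVW** — weighted mean of Wald ratios `Γ_j/γ_j` with weights
  `γ_j²/se(Γ_j)²`; Cochran's Q on J−1 df; if Q's p < 0.05 the SE is
  inflated multiplicatively by √(Q/(J−1)), never below fixed. Wald-ratio
  SE uses the first-order delta method (se(Γ)/|γ|), standard two-sample
  practice. Zero-γ instruments are excluded with a warning.
* **Egger** — weighted regression with intercept after orienting γ ≥ 0;
  the intercept and its normal-test p index directional pleiotropy;
  residual heterogeneity (J−2 df) triggers the same SE inflation.
* **Weighted median** — cumulative-normalized-weight interpolation at 0.5;
  SE from a 5000-draw seeded parametric bootstrap of (γ_j, Γ_j).
* **MR-LASSO** — `Γ_j = θγ_j + α_j` with L1 on the per-instrument
  intercepts, solved by soft-threshold coordinate descent on a descending
  100-point geometric λ grid from just above the all-zero λ; the chosen λ
  is the largest whose retained (α_j = 0) set passes Q at p ≥ 0.05; the
  estimate is IVW on that set and the α_j ≠ 0 instruments are reported as
  outliers. Fewer than 3 retained instruments is an error advising against
  the method.
* **MVMR** — zero-intercept weighted regression of Γ on (γ, γ₂), weights
  1/se(Γ)², Q on J−2 df with the same inflation. An identically-zero
  exposure column has an undefined conditional effect: the other exposure
  is fit alone and NaN is returned for the degenerate one, rather than
  failing on a technically rank-deficient design.

All estimators are invariant to joint sign flips of (γ_j, Γ_j[, γ₂_j]).

## Risk scores and survival

A GRS is Σ_j w_j·dosage_ij after aligning each weight's effect allele to
the cohort's dosage coding (flipping to 2−dosage where needed),
standardized to mean 0/SD 1 over the analysis sample after exclusions (the
standardization sample is a documented choice). Cox models use lifelines
with Efron tie handling; the time origin is the baseline visit, prevalent
cases are always excluded from survival fits, and the discovery subsample
is excluded by default. Fewer than 10 events warns rather than errors so
hand-sized oracle fixtures remain fittable; zero events is an error.
Product interaction terms are formed from centred variables — with both
mains in the model the Wald test is unchanged and the partial-likelihood
fit is far better conditioned than with raw age×score products. Age
stratification splits at the median age at event when computable (71.7 yr
as the fixed fallback). The four-group analysis binarizes the FNW GRS at
its top 50/25/10% and the FN-BMD GRS at its bottom 50/25/10%, fits
indicator terms for groups 2–4 against the doubly-unexposed reference with
sex and age, and errors on any event-free group.

## Pipeline and formats

Summary statistics use the tab-separated `SNP A1 A2 freq b se p N [INFO]`
dialect; positions in tables are 1-based, gene intervals BED 0-based
half-open; indel alleles are carried as strings and palindrome logic
applies only to single bases. The driver chains simulate → geometry →
phenotype → scan → selection → genetic correlation → MR/MVMR → GRS/Cox →
groups at a desk scale chosen to finish in seconds-to-minutes on one CPU
(defaults: panel 1000×2000 in AR(0.4) blocks of 10, cohort 20 000 with a
50% discovery split), logs every filter's input/output counts, pairs every
estimate with its simulated truth in `report.json`, persists partial output
and the failing stage name on error, and is byte-for-byte reproducible for
a fixed config. At this scale the scan finds a minority of the planted
signals (the realistic consequence of 7.6% variance over ~100 causal
variants at n = 10 000) and sparse-architecture LD-score estimates are
noisy; the report shows whatever was computed.

The acceptance script (`scripts/acceptance.py`) re-derives the headline
quantities at fixed problem sizes — 71-signal table summaries; geometry
round trips (n = 200 jittered annotations); a 20 000-cohort for per-sex
means; M = 5000 summary-statistic recovery for h²/r_g; a 60 000 cohort
(50% discovery) for end-to-end MVMR and GRS survival; 50 000-individual
planted-hazard Cox recoveries — sizes chosen as the smallest at which the
recoveries are comfortably inside their sampling error.
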