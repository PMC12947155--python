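# Methods

This note documents the models, the synthetic-data design, and the numerical
conventions the package commits to, in the spirit of a statistical software
methods appendix.

## Units

Serum haematocrit and ECV are **fractions** everywhere in patient tables and
ECV maps. All HU→Hct regression models operate in **Hct-percent**: the
published coefficient sets plainly map HU ≈ 50 to synHct ≈ 40, i.e. percent,
while cohort summaries quote haematocrit as a fraction (0.40). Conversion
(÷100) happens only where a model prediction enters a fractional computation
(ECV, MAE in fraction units). Mixing the two conventions silently is the most
likely user error, so the boundary is kept explicit in every API.

## The calibration family

A synHct model is a line `Hct% = slope·HU_blood + intercept`. The package
ships the published family verbatim — literature model `0.51·HU + 17.4`,
whole-cohort baseline `0.864·HU − 2.09`, and the stratified lines
`1.16·HU − 17.2` (males, BMI < 30.7), `0.669·HU + 8.38` (males, BMI ≥ 30.7),
`0.669·HU + 8.19` (females, BMI ≥ 22.4). Published coefficients are stored
exactly as printed and never re-derived; `fit_linear` (closed-form OLS via
`scipy.stats.linregress`) produces new models with R², n and coefficient
standard errors attached.

The combined model is an ordered routing table of `(sex, BMI-interval)`
predicates. BMI intervals are half-open `[low, high)`, so a record sitting
exactly on a threshold routes to the upper stratum; the published thresholds
are written with strict inequalities on both sides, which leaves the boundary
formally undefined — half-open intervals keep the routes a partition. Records
no route covers (females with BMI < 22.4) are **flagged missing** by default;
substituting the baseline or literature model is available but strictly
opt-in, because silently extrapolating into a subgroup where no calibration
could be established is exactly the failure mode the stratified model exists
to avoid.

## ECV computation

`compute_ecv_map` follows the image pipeline: erode the blood-pool mask
(default 2 iterations of a 6-connected structuring element — the source
pipeline only says a "small central region", so the count is configurable),
take ΔHU = late − baseline, set ΔHU_blood to its mean over the eroded pool,
and evaluate `(1 − Hct)·ΔHU(v)/ΔHU_blood` on every myocardial voxel.
Out-of-range voxels (ECV < 0 or > 1, possible under noise) are kept and
counted, not clipped; the mask mean includes them unless `exclude_flagged` is
set. Registration and segmentation are upstream concerns: volumes are assumed
to share one grid.

For every voxel, `synECV/conECV = (1 − synHct)/(1 − Hct)` holds exactly; the
test suite asserts this identity at 1e-12, which pins the implementation of
the substitution.

## Synthetic cohort generator

The clinical tables are not publicly deposited, so the generator *inverts*
the calibration family to produce cohorts with the statistical structure the
analysis assumes. Per (sex, BMI) subgroup with true line `(a, b)` and target
mean/SD of Hct-percent `(m, s)` and target R²:

* `HU ~ Normal(μ_HU, σ_HU)` with `μ_HU = (m − b)/a`, `σ_HU = s·√R²/|a|`;
* `Hct% = a·HU + b + ε`, `ε ~ Normal(0, σ_ε)` with `σ_ε = s·√(1 − R²)`,

so that `1 − σ_ε²/var(Hct%)` equals the target R² by construction (asserted
to 1e-9). Defaults: males `m = 40.2, s = 5` (the per-sex SD of 0.1 printed
for males is treated as a typographical outlier — physiologically implausible
and inconsistent with the cohort-level 0.40 ± 0.05), females
`m = 38.7, s = 4`; R² = 0.55 for both male strata and 0.33 for females above
BMI 22.4, the reported fit qualities. Blood-pool HU distributions are not
printed anywhere, so deriving them from the inverted lines is a modelling
convention, not a data fact.

Females below BMI 22.4 keep the same line with an inflated residual SD of
8 Hct-percent (implied R² ≈ 0.08): wide enough that no significant
calibration exists at realistic subgroup sizes — reproducing the null finding
for that subgroup — while keeping haematocrit values physiological. Residuals
that would push Hct outside (1%, 99%) are redrawn.

Sex counts are fixed (75/33), not Bernoulli, so the cohort composition is
exact. BMI and creatinine are log-normal matched to the per-sex
median/IQR summaries; age is normal from median/IQR; eGFR normal from
mean/SD (floored at 5 to stay physical); ground-truth ECV is normal with
median 0.32 and IQR 0.05. Age, eGFR and creatinine are drawn independently
of haematocrit — independence encodes the reported null result for those
covariates. Each record also carries a drawn `ΔHU_blood ~ Normal(60, 8)` HU
(a typical late-enhancement blood-pool change; floored at 20) and the exact
`ΔHU_myo = ECV·ΔHU_blood/(1 − Hct)`, so downstream ECV evaluations are
reproducible from the table alone.

All randomness flows from a single integer seed through one numpy
`Generator`; the same (spec, seed) pair always yields the identical table.

The phantom generator builds concentric-ellipsoid LV geometry (inner
ellipsoid = blood pool, shell = myocardium, isotropic 2 mm voxels by
default) and inverts the ECV relation per voxel; with zero noise the forward
pipeline recovers the field to floating-point precision, and Gaussian HU
noise added independently to both volumes leaves the mask-mean ECV unbiased.

**What passing tests do and do not show.** The generator emulates the
*published summaries and fitted models*, not raw clinical data: it has
Gaussian noise, no HU dependence on scanner protocol, no registration error,
no metal artefacts, and demographics independent of haematocrit by
construction. Tests passing on these cohorts demonstrate that the pipeline's
statistics and searches behave correctly under the study's stated model; they
cannot certify performance on real scans.

## Stratification search

`fit_interaction` fits `Hct% ~ 1 + HU + X + HU·X` by closed-form OLS with a
two-sided t-test on the product term (sex coded male = 0 / female = 1). With
Gaussian residuals the test is exact; the suite verifies the 5% size in a
1000-replicate null simulation.

`bin_search` enumerates 2–5 bins whose edges come from the covariate's
empirical percentile lattice (p10…p90 in 5-percentile steps; the lattice is
coarsened — step doubled — whenever a bin count would exceed 2000 candidates,
keeping the space finite and deterministic, and guaranteeing occupied bins).
A candidate is retained only if (i) the HU–Hct Pearson correlation is
significant *within every bin* and (ii) every bin **boundary** carries a
significant change of slope. The boundary test uses segmented coding — per
boundary j an intercept step `1[bin ≥ j]` and a slope step `HU·1[bin ≥ j]` —
so each coefficient tests the slope change *across that boundary* rather
than against a reference bin; with reference coding, any extra cut of an
already-distinct stratum would inherit significance from the true break and
the gate would prune nothing.

Retained candidates are ranked by the equal-weight min–max combination of
four in-sample metrics (Hct MAE and Pearson R, ECV MAE and Pearson R; MAE
inverted so lower is better). Two numerical conventions make this selection
stable:

* metrics are **quantized** before ranking (MAE to 1e-4 in fraction units,
  R to 1e-2) — differences below these quanta are within the metrics'
  in-sample estimation noise at the cohort sizes involved and should not
  decide a model;
* candidates whose every quantized metric lies within one quantum of the top
  scorer are treated as statistically indistinguishable, and the most
  parsimonious of them wins (fewest bins, then smallest first edge). An
  extra chance-significant boundary typically buys exactly one quantum of
  in-sample MAE, so without this rule the search would systematically prefer
  spurious extra bins — the binning analogue of the one-standard-error rule
  used in cross-validated model selection.

`window_search` slides windows (widths 25–90% of the covariate range in 5
steps, lower edges on the same percentile lattice, upper edges clamped to
the data maximum) and gates on the within-window correlation P. Windows of
different sizes cannot be compared by raw in-sample metrics — smaller windows
win on noise — so selection applies a one-SE rule on the Fisher-z scale:
among gate-passers whose z(correlation) lies within one standard error
(`1/√(n−3)` of the best) of the best, the window covering the most records
wins, ties to the smaller lower edge. This prefers the maximal sub-range on
which the calibration is as strong as anywhere, which is the quantity of
interest when restricting a model's validity domain.

Gates default to two-sided α = 0.05 with **no multiple-testing correction**,
matching the source procedure's apparent practice. `bonferroni=True` divides
α by the total number of gate tests in the whole search, which controls the
familywise chance of retaining anything under a null covariate; the null
property tests run in that mode. One caveat discovered during development
and worth stating: when the searched population is itself a mixture of two
true lines (e.g. all males, pooled across the BMI break), the boundary
t-test for an *independent* covariate such as age is misspecified and
over-rejects — null-covariate searches are therefore only calibrated within
a homogeneous stratum.

## Evaluation

MAE and Pearson R are computed on per-record haematocrit (fraction) and on
per-record mean-LV ECV derived from the stored (ΔHU_myo, ΔHU_blood) pairs.
Pearson R intervals use the Fisher z transformation with SE `1/√(n−3)` and
the two-sided normal quantile; this convention reproduces, at two-decimal
rounding, every published interval whose subgroup size is known, which is the
reason it was adopted (the source never names its CI procedure — this is an
inference, not a stated fact). Under a stratified model, unroutable records
are excluded from the metrics and counted, mirroring the restricted female
analysis. The seven-column comparison table uses published coefficients
where they exist and refits the two sex-only models (their coefficients are
not printed) on the cohort being evaluated.

## Problem sizes

Default test and acceptance runs use: 108-record cohorts for table-level
checks, 10 000 records for demographic calibration, 5000 per subgroup for
coefficient recovery, 2000 males / 1000 females for the searches, 1000
replicates of n = 100 for the interaction-test size, and 48³ phantoms for
the voxel pipeline. These sizes make Monte-Carlo error small relative to
every tolerance asserted while keeping a full run in well under a minute for
the generator stages and a few seconds per search.

## Known limitations

* The searches reproduce the grid-and-gate procedure as described; they are
  not changepoint estimators and inherit the procedure's multiplicity
  behaviour when uncorrected.
* The per-candidate metric quanta (1e-4 / 1e-2) are calibrated to cohort
  sizes in the hundreds-to-thousands; for much larger cohorts they would be
  conservative (real differences treated as ties).
* The CI helper is approximate for small n (Fisher z is first-order); it is
  used for display and comparison, not for gating.
* Phantom geometry is idealized; nothing about CT physics is simulated.
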