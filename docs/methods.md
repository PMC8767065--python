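# Methods

This note documents the models behind `excitoq`: what each estimator
computes, what the synthetic-data generator emulates, the defaults and why,
and the decisions taken where the underlying experimental convention is
genuinely open.

## Signals and events

All kinetic analyses operate on per-cell traces sampled on a common grid
(time in seconds internally; loaders accept minutes). Two trace kinds are
distinguished: two-excitation ratios (F340/F380 of ratiometric Ca²⁺/Na⁺
indicators) and single-channel F/F0 traces normalized to the pre-stimulus
baseline (Rh123, Fluo-5N, DiBAC). Every window-based computation is anchored
on a named event schedule (`glu_on`, `glu_off`, `fccp_on`, `iono_on`).
Missing samples are rejected rather than imputed: the estimators anchor
levels at specific times and an imputation rule would silently move those
anchors. Traces are smoothed only for *locating* features (plateau, maximal
slope); all quantitative fits use the raw samples.

## DCD classification

A cell is DCD-positive when, after the first-phase plateau, the smoothed
signal rises **strictly** above

    plateau + max(k · σ_robust, f · A₁)

and stays above until washout (≥ 90% of samples, including the last). Here
σ_robust is a MAD-based noise sd from raw-minus-smoothed residuals near the
plateau, A₁ the first-phase amplitude (plateau − baseline), k = 5 and
f = 0.10 by default. The plateau is located as the minimum of the smoothed
signal in the glutamate window past a 40-s settle margin — this handles
short-lag cells whose secondary rise begins before a fixed plateau window
would end. The two-part threshold separates DCD from slow drift: the k·σ
term scales with measurement noise, the f·A₁ term puts a floor under it on
very clean recordings. A rise exactly at threshold does not count (strict
inequality; the documented tie-break).

## Lag-DCD by tangent intersection

Tangent 1 is the least-squares line over the plateau window (ending 10 s
before the detected rise to keep rise samples out of the plateau fit);
tangent 2 the least-squares line over a 60-s window centered on the maximal
smoothed slope of the secondary rise (search capped at the secondary peak so
the falling flank is excluded). The onset is the analytic intersection of
the two lines; lag-DCD is that time minus `glu_on`, clamped to the glutamate
window with a warning flag. Near-parallel tangents (relative slope
difference below 1e−9) raise a degenerate-geometry error rather than return
an unstable intersection. On noiseless piecewise-linear traces whose
segments *are* the tangents, the estimate equals the closed-form 2×2 solve
to machine precision; the acceptance suite verifies this on 1,000 randomized
traces.

On logistic (sigmoidal) secondary rises the least-squares tangent over a
finite window is slightly shallower than the true maximal slope, which
biases single-cell lags upward by ~2·τ·(s_max/s_fit − 1) ≈ 5 s for the
default rise time constant τ = 20 s and 60-s window — under 3% of the
cortical median and well inside the 10% recovery tolerance the tests use.

## Recovery index

X = 100 (R_off − R_end)/(R_off − R_base), where R_base is the pre-glutamate
baseline mean, R_off the level at `glu_off`, and R_end the level at a fixed
horizon (default: 15 s before the FCCP pulse); R_off and R_end are local
means over ±10 s for noise robustness. **This formula is a reconstruction**:
the convention it quantifies ("X% recovery after washout") is usually shown
graphically, not printed; anchoring the numerator at washout and the
denominator at baseline makes 100% = full return and 0% = no recovery, and
the index is invariant to affine rescaling of the trace. Cells with
R_off ≤ R_base have nothing to recover from and are flagged undefined —
excluded from cohort medians with the exclusion count always reported.
Sister-culture normalization divides by the control cohort's median, so the
control maps to 1 exactly.

## Rh123 (ΔΨm) metrics

The washout slope is the least-squares slope of F/F0 over
[`glu_off`, `fccp_on` − 15 s); negative slope = repolarization. AUCs are
trapezoidal integrals of max(F/F0 − 1, 0); the baseline defaults to the
F/F0 normalization level 1 because no other convention is stated anywhere —
it is a parameter, not a constant. The FCCP window runs from `fccp_on` to
`iono_on` (or trace end). The ratio AUC_FCCP/AUC_post-glutamate is undefined
when the post-glutamate area is zero. Whether a high ratio reflects true
repolarization or probe redistribution is an interpretive question the
module deliberately leaves open: it reports both metrics.

## Flux metrics

After subtracting the per-cycle mean of the blank wells (cells-free wells
carrying only instrument drift): NOCR = minimum OCR after
antimycin A/rotenone; basal = mean of all pre-injection cycles − NOCR (mean
rather than a single cycle, for robustness); maximal = maximum OCR in the
FCCP segment − NOCR; SRC = maximal − basal, so maximal = basal + SRC holds
identically. The acute response to an agent is the extremum of its segment
(the direction with the larger absolute deviation) minus the last
pre-injection value. Two normalizations are provided because "normalize to
basal" is ambiguous: dividing by basal respiration (NOCR-subtracted; basal
→ 1, maximal − SRC = 1) or by the raw pre-injection OCR (NOCR included).
The default is `basal_respiration`, which reproduces the basal ≈ 1
convention of normalized respirometry figures; neither is silently
preferred in outputs. The 3/2/3-min mix/wait/measure cycle structure is
metadata; metrics use the per-cycle measurement values.

## Viability and morphometry

Survival index = (live/dead)/(control live/dead) from Syto-13/EthD-1
counts; undefined (never imputed) when a dead count is zero. MTT activity is
the kinetic variant: the least-squares slope of background-corrected A550
over the first 10 min after MTT addition, normalized to the control slope.
The background wavelength is a data field (620 and 650 nm are both in use
in practice) and is carried into the result rather than assumed. Soma area
is the contour pixel count; fold-changes are scale-free so no micron
calibration is needed. Under a spherical-soma assumption, projected area ∝
r² and volume ∝ r³, so volume fold = (area fold)^{3/2}: +42.7% area → 1.70×
volume, +22% → 1.35×. Cohort area changes are reported as mean ± SEM with
per-experiment aggregation by default (cells averaged within experiment
first); per-cell pooling is available since the unit of replication for the
rank tests is not universally fixed.

## Statistics ladder

Each group is tested for normality (D'Agostino–Pearson, α = 0.05; groups
with n < 8 cannot support the test and force the nonparametric branch,
which the audit trail records). Any non-normal group routes to Mann-Whitney
(2 groups) or Kruskal-Wallis with Dunn's pairwise z-tests
(Bonferroni-adjusted, pooled mid-ranks with tie correction — implemented
here directly); all-normal groups route to Welch's t-test (2 groups; the
convention source is silent on this cell of the table, Welch is the robust
default) or one-way ANOVA with Šidák-adjusted pairwise t-tests. Repeated
time × group designs use a mixed-design ANOVA (pingouin) followed by
Dunnett's comparisons against the control on per-subject means. Branch
selection is a pure function of (design, group count, normality outcome)
and is unit-tested over the full decision table; the two-group branch's
type-I error is verified at ≈ 5% by null simulation. Nonparametric
summaries use linear-interpolation quantiles (the Tukey box-plot
convention) — stated explicitly because quantile definitions differ across
software.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the *statistical structure* the estimators assume:

- **Ca²⁺ traces** — baseline 1.0; universal first-phase rise (amplitude 1.0
  ratio units, τ = 8 s); a Bernoulli(p_dcd = 0.8) subpopulation adds a
  logistic secondary rise (amplitude 2.0, time constant τ = 20 s) whose
  onset lag is log-normal. The logistic midpoint is placed at
  `glu_on` + lag + 2τ, because the tangent-intersection onset of a logistic
  sits exactly 2τ before its midpoint — ground truth and the geometric
  estimator agree by construction on noiseless traces. After washout the
  whole elevation relaxes exponentially at rate
  `recovery_rate × lps_recovery_factor` (defaults 0.004 s⁻¹ × 1.0); an FCCP
  transient and ionomycin saturation follow. Additive Gaussian noise,
  sd 0.02 (2% of the first-phase amplitude).
- **Calibration presets** — "cortical": lag median 180 s, n = 288;
  "cerebellar": 530 s, n = 298. The log-sd is derived from the reported
  interquartile ranges, σ = ln(Q3/Q1)/(2 z₀.₇₅) (0.846 and 0.714). Lags are
  truncated by resampling to fit the glutamate window minus a 120-s margin
  so every DCD cell's rise is observable and the DCD fraction stays exactly
  binomial; for the cortical window this censors ~4% of the distribution
  and shifts the observable median by ~+3%. The cerebellar preset extends
  the glutamate exposure to 40 min: under a 15-min window ~29% of a
  530-s-median lag distribution would be censored and the observable median
  would fall near 400 s, so the longer recording is what makes the slow
  phenotype measurable at all.
- **Rh123 traces** — depolarization is a logistic rise (amplitude 1.5)
  sharing each cell's DCD onset; non-DCD cells show a small transient that
  decays before FCCP. Washout relaxation uses the same LPS-scaled rate. The
  FCCP transient amplitude (default 2.0, the prominent protonophore
  dequenching spike of representative recordings) scales with the
  polarization remaining just before the pulse, so poorly recovered cells
  give small FCCP responses — this is what makes the AUC ratio decrease
  monotonically as the recovery factor falls, despite their larger residual
  area inside the FCCP window.
- **Na⁺ / DiBAC traces** — rise at glutamate addition in every cell;
  post-washout Na⁺ recovery at 0.4× the Ca²⁺ rate (Na⁺/K⁺-ATPase lags the
  Ca²⁺ pumps), so the Na⁺ half-recovery time always exceeds the paired Ca²⁺
  one.
- **Flux plates** — 24 wells (4 blanks), pre-injection OCR uniform on
  100–200 pmol O₂/min, NOCR 20% of it; piecewise-constant segment levels
  (glutamate 1.7×, FCCP 2.1× basal; antimycin/rotenone → NOCR) plus a
  sinusoidal drift shared with the blanks and Gaussian noise (sd 3). In the
  noiseless limit blank correction removes the drift exactly and the
  metrics recover ground truth to machine precision.
- **Endpoints** — binomial live/dead counts at condition survival
  probabilities (0.75/0.716/0.677, chosen so the survival indices fall near
  1.0/0.84/0.70); MTT kinetics linear over the initial window then
  saturating; log-normal cell areas with multiplicative condition effects of
  unit-mean noise so the expected area change equals the condition factor.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real recordings: photobleaching and focus drift,
probe leakage and compartmentalization, correlated (non-Gaussian) noise,
cell-to-cell heterogeneity in first-phase amplitude and recovery rate,
within-cell correlation between lag and recovery (left independent: no
published estimate of that correlation exists to calibrate against), and
any biophysical mechanism (NMDAR flux, mitochondrial Ca²⁺ uniport, ATP
dynamics). The generator validates the estimators' correctness and
calibration on data of the assumed structure, not the structure itself.

## Numerical choices and degenerate inputs

Trapezoidal integration with interpolated window endpoints is exact for
piecewise-linear signals on the grid and O(h²) for smooth ones. Half-time
crossings use the first downward crossing with linear interpolation; later
re-crossings are ignored (monotone-recovery assumption of the washout
phase). Tangent fits need ≥ 2 samples, slope fits ≥ 3; empty windows,
zero denominators (named by sample index), zero control medians,
non-monotone schedules, and missing injections are all hard errors.
Undefined per-cell metrics (no elevation, zero dead count, zero
post-glutamate AUC) are flagged and counted, never imputed.

## Problem sizes

Tests and the acceptance script run the presets at their calibrated sizes
(288/298 cells, ~480/720 samples per trace), 1,000 traces for the tangent
oracle, 2,000 null simulations for the type-I check, and 24-well plates —
sizes at which every stochastic tolerance in the suite has comfortable
margin under the fixed seeds.
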