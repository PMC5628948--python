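# Methods

This note documents the statistical machinery, the configuration assets and
their provenance, the synthetic-cohort design, numerical choices, and known
limitations. It states no empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## LMS growth references

A measurement y at gestational age t is modelled as Box-Cox-normal with
age-varying power L(t), median M(t) and coefficient of variation S(t);
z-scores and centiles follow the standard Cole–Green transforms, with the
L→0 case handled by the analytic log limit (branch switch at |L| < 1e−8,
continuous to <1e−6).

**Fitting** (`fit_lms_curves` / `LMSGrowthModel.fit`) maximizes the
penalized likelihood by Fisher-scoring backfitting: each cycle refreshes one
curve (M, then S, then L) from its working response and
expected-information weights — for M, weight (1 + 2L²S²)/(M²S²); for S,
2/S²; for L, the standard 7S²/4 approximation with a numerically
differentiated score — smoothed by a weighted natural cubic smoothing
spline whose smoother-matrix trace is matched to the requested equivalent
degrees of freedom by bisection on the penalty (trace tolerance 1e−3;
edf 1 = weighted constant, edf 2 = weighted line). Replicate ages are
aggregated onto unique knots by weighted means. Updates are damped
(per-iteration change of M and S capped at a factor 2, of L at ±0.5) and
iterated until the deviance changes by <1e−6, cap 200 iterations
(`FitError` beyond). The fit is deterministic: no randomness, fixed
iteration order, bitwise-stable on refit. Default edf (1, 8, 4) for
(L, M, S); edf_L = 1 yields the constant skewness curve used throughout.
Ages are measured in days; no age transformation is applied.

**Back-solving** (`backsolve_lms`) recovers a single age's (L, M, S) from a
row of published centile values: for fixed L the model is linear on the y^L
scale, so a coarse profile over L ∈ [−3, 3] selects a start, refined by
bounded least squares on the original scale (L ∈ [−3, 3], S ∈ (0, 1));
deterministic, and exact to <1e−6 on noiseless rows.

**Age interpolation.** Age-indexed models interpolate L, M, S independently
with natural cubic splines over the model grid; extrapolation beyond the
grid raises rather than guesses.

### The shipped weekly TVol table and its column labels

The packaged weekly reference table (14–37 weeks, seven columns) is
shipped exactly as published, with columns labelled 5/10/25/50/75/90/95.
Back-solving shows the printed values are **not** consistent with any
single Box-Cox distribution per row at those quantile positions (best
attainable maximum residual ≈0.76 cm³ at 36 weeks), but are consistent to
print precision with the channel positions **3/10/25/50/75/90/97** — the
default centile set of LMS charting software (the 14-week row then fits to
0.0003 cm³, and the fitted L is near-constant ≈ −0.4 across rows, matching
a one-degree-of-freedom skewness curve). The package therefore validates
and inverts the table at the consistent positions, exported as
`TABLE_PROBS_CONSISTENT`, while `tvol_reference_lookup` stays keyed by the
printed labels. Consequence: a value on the table's lowest channel scores
≈3rd centile, not 5th. For rows printed at 0.1 cm³ resolution (25 weeks
onward) print rounding alone contributes up to 0.05 cm³ of irreducible
back-solve residual; the measured least-squares maximum over all rows is
≈0.057 cm³.

## Individualized growth assessment

Per-parameter individual trajectories use the Rossavik form
P(t) = c·u^(k + s·u), u = t − t0, linear in (ln c, s) on the log scale:
exact closed-form for two scans, least squares for more. Eligibility
enforces ≥2 scans before 196 days with consecutive separations of 28–56
days. k and t0 are fixed configuration assets (below). Percent deviation is
100·(observed − predicted)/predicted; cohort systematic/random prediction
errors are the mean and sample SD (n−1) of those deviations.

**mPGAS (negative version).** Each parameter-visit record contributes
min(0, deviation − lower reference bound); the score is the mean over all
records including zeros, so it is ≤0, 0 when everything is in range, and
monotone in any deepening breach. Parameters combined: head circumference,
abdominal circumference, femur diaphysis length, thigh circumference, and
EFW(BPD–AC–TVol). Abnormal strictly below −0.17% (the published 95%
reference range 0 to −0.17%). All third-trimester visits in the analysis
window contribute; averaging over a single visit is a caller choice (pass
one visit's records).

**GPRI_WT** is 100·birthweight/predicted birthweight, predicted from the
fitted EFW trajectory at min(delivery GA, 266 d) — the ≤38-week rule —
abnormal outside 84–118%.

## Estimated fetal weight

The Hadlock BPD–AC–FL formula is built in exactly as published (inputs cm,
output g). EFW(BPD–AC–TVol) coefficient sets are configuration assets
because the underlying publications' coefficients are not redistributed
here: the usable default is a **synthetic calibration** — a single
power-law term EFW = C·BPD^0.25·AC^0.806·TVol^0.55 (BPD/AC cm, TVol cm³),
scaled so a median-curve fetus realizes ~3.48 kg at term birth — and a
placeholder set that refuses evaluation unless explicitly enabled guards
against mistaking synthetic coefficients for validated clinical ones. The
power-law form makes the implied EFW trajectory exactly Rossavik
(exponent-weighted sums of the component k and s), so the fixed EFW
exponent used by IGA is internally consistent.

## Customized birthweight centiles

A generic Gardosi-style model: term optimal weight = baseline 3480 g +
8.5 g/cm of maternal height above 164 cm + 7.0 g/kg of booking weight
above 66 kg + 90 g if parous + sex (±60 g) and ethnicity adjustments;
expected weight at GA scales by a proportionality curve (cubic polynomial
of gestational weeks to 38 weeks, then an exponential extension at 0.302%/
day reflecting late-term growth deceleration, normalized to 1 at 40 weeks,
represented as a config spline); the centile is Φ((ln bw − ln expected)/
σ_log)·100 with σ_log = 0.12. All coefficients are synthetic-calibration
config values, self-consistent with the cohort generator; proprietary
customized-growth coefficient tables are deliberately out of scope.
Classes: FGR <3rd, SGA 3rd–<10th, LGA >90th, AGA otherwise (strict
cutoffs).

## Screening evaluation

Confusion-table metrics follow the standard definitions, with undefined
quantities (LR+ at 100% specificity, PPV with no positive calls) carried
as `None` and printed as dashes. `reconstruct_confusion` searches
exhaustively for the unique integer counts whose percentages round (half
away from zero) to printed integers, raising on none or several.

**Display rounding.** Published screening tables that print integer
percentages are reproduced by rounding half away from zero in two stages —
to 1 decimal, then to integer (e.g. 103/109 = 94.495% → 94.5 → 95); LR+ is
printed at 1 decimal, LR− at 2. Values are snapped to 12 significant
digits first so decimal-exact halves reached through binary floats round
as a calculator would.

ROC AUC uses the rank (Mann-Whitney) statistic with ties counted half.
DeLong's paired comparison is implemented from placement values with the
empirical covariance across shared subjects; it matches R pROC's
`roc.test(..., method="delong")` to 4 decimals on 20 frozen datasets (the
module suite asserts this). Against a 5,000-draw swap-permutation test the
asymptotic p-values agree to ~0.01 in the median, with worst-case
deviations of 0.03–0.06 at n ≈ 60–115 — the intrinsic error of the normal
approximation, not an implementation artifact.

Birthweight regression is OLS (statsmodels) of birthweight on a predictor
plus gestational ages at scan and delivery, with AIC in the statsmodels
convention (−2ℓ + 2k; model comparisons by ΔAIC are convention-free) and a
base-10 log transform applied when the predictor's sample skewness exceeds
1. The screening table dichotomizes by default at the 10th percentile of
the cohort's GA-adjusted predictor distribution (residual of ln value on
GA); centile-valued predictors are cut at the 10th centile directly. AUC
is computed on logistic-regression scores (outcome ~ ln value + GA), with
a deterministic fallback to the GA-adjusted deficit under separation.

## Synthetic cohort

The generator emulates the assumed study design, not any real dataset:

- **Structure:** 115 subjects; one scan per window at a uniform day within
  98–111, 140–153, 182–195, 238–258 (clustering around ~100/150/190/250
  days); latent classes FGR 9%, SGA-only 12%, LGA 2.6%, AGA the rest,
  drawn i.i.d. (cohort fractions vary binomially by design).
- **Latent curves:** per-parameter Rossavik curves sharing the fixed
  calibration (k, t0), with individual ln c jitter (SD 0.015–0.025) and
  slope jitter (SD 1–2×10⁻⁵). A per-fetus size factor g (lengths ×g,
  volumes ×g³) is solved in closed form so the 3D EFW at the effective
  birth age matches a target weight: expected customized weight at
  delivery times exp(σ_log·Φ⁻¹(p)) for a class-conditional target centile
  (AGA uniform 15–85, SGA 3.5–9.5, LGA 90.5–98; FGR draws its
  pre-faltering growth *potential* from 20–60).
- **Faltering:** FGR fetuses have the slope of TVol (decrement 9×10⁻⁴),
  AC (×0.17) and thigh circumference (×0.375) reduced after 196 days with
  value continuity — soft-tissue growth flattens, head and femur are
  spared — calibrated so median FGR birthweight lands near 2.44 kg versus
  ~3.5 kg for AGA, and FGR deliveries center on 268 d vs 280 d.
- **Birthweight:** realized from the (faltered) EFW trajectory at a damped
  effective age (266 + 0.3·(GA − 266) beyond 38 weeks; real growth
  decelerates at term while the Rossavik projection keeps climbing) times
  a log-normal residual (CV 2.5%). The EFW scale anchors at the damped
  age of a term delivery (270.2 d) so birthweights, the customization
  model and the component reference curves stay mutually consistent.
- **Measurement noise:** multiplicative log-normal per scan, CV 3% for
  TVol (test-retest correlation ≈0.99) and 1.5–2.5% for 2D biometry;
  independent across visits (no within-subject noise correlation —
  a documented simplification).

What passing tests on this cohort do show: the estimators recover known
truth, the pipeline's classifications agree with the latent classes ≥90%
(deliberate boundary noise mirrors real SGA/FGR ambiguity), injected
faltering is detected by mPGAS/GPRI with high sensitivity, and the
soft-tissue EFW out-predicts single 2D measures. What they do not show:
real-world screening magnitudes — birthweight derives from the same
trajectory family the predictors measure, so synthetic AUC/R² run higher
than any clinical cohort's, and only directional statements transfer.

### Calibration provenance (all synthetic)

Rossavik population constants: shared t0 = 43 d; (ln c, k, s) solved
exactly through standard mid-pregnancy anchor values at 105/175/252 days
for BPD/HC/AC/FL/thigh circumference, and by inverse-variance-weighted
least squares against the shipped weekly TVol medians at the scan-window
weeks (residuals within ±10% at the windows). mPGAS deviation reference
ranges are the rounded 2.5th/97.5th percentiles of third-trimester percent
deviations among normal-outcome fetuses across 10 seeded cohorts (HC ±6.5,
AC −8/+9, FL −7.5/+9.5, thigh circ −9.5/+12, EFW −9.5/+10.5 percent).

## Known limitations

- The penalized-likelihood fitter targets the standard three-curve model;
  fractional edf between 1 and 2 is unsupported, and very small S with
  extreme L can slow convergence.
- Customized-centile coefficients are generic and synthetic; clinical use
  requires population-specific tables the package deliberately does not
  ship.
- The reference-table labelling inconsistency above means absolute centile
  statements near the outer channels depend on which reading is adopted;
  the package adopts the internally consistent one and says so.
- DeLong p-values inherit normal-approximation error of up to a few
  hundredths against exact permutation at double-digit cohort sizes.
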