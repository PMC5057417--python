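# Methods

## Triage model

The implemented triage model stratifies adult ED admissions into five acuity
levels in two steps. Step one is deterministic: five dichotomous vital-sign
items (SBP < 100 mmHg, HR > 110 bpm, RR > 22 /min, SpO2 < 94%, treatment with
supplemental oxygen) each contribute an integer weight when abnormal, and the
summed score is mapped to green/yellow/orange/red through three increasing
integer thresholds. Step two is a nurse clinical-assessment override
constrained to at most two categories up or one down. Blue (minor
injuries/complaints) is an intake route, not a score output: it is never
produced by the score and never reclassified.

Conventions chosen where the construction admits dialects:

- **Strict cutoffs.** A vital exactly at its cutoff is normal (SBP = 100 does
  not score). This follows the strict inequalities in the chart definition.
- **Override clamping.** A requested category outside the allowed window is
  clamped to the nearest permitted category and flagged, rather than
  rejected — triage must always yield a category. Overriding to blue is an
  error; a red base may be taken one step down under the general rule.
- **Missing vitals are errors**, never imputed; the error names the field.

## Score derivation pipeline

`TriageScoreDeriver` reconstructs the chart from a cohort:

1. **Dichotomization** at the nearest-rank percentile of the abnormal tail
   (default fraction 0.10). Nearest-rank is deterministic and independent of
   interpolation dialects; with heavy ties the realized abnormal fraction can
   only fall below the target, never exceed it. Oxygen treatment enters as a
   boolean flag with no distributional tail.
2. **Univariate screening** by logistic regression; retain Wald p < α
   (default α = 0.05, two-sided — exposed as a parameter).
3. **Backward elimination** of the joint logistic model: repeatedly drop the
   largest-p predictor while it is ≥ α, refitting after each drop. Logistic
   fits use Newton maximum likelihood (statsmodels, tolerance 1e-10);
   a zero cell in any predictor–outcome 2×2 table is reported as perfect
   separation naming the predictor.
4. **Weight rounding**: odds ratios are rounded half-up (2.5 → 3) to integer
   weights. An OR rounding to 0 is dropped with a warning rather than floored
   to 1 — a zero-weight item carries no information, and flooring would
   overweight null effects.
5. **Threshold calibration**: exhaustive enumeration of all strictly
   increasing integer triples in the observed score range (the score maxes at
   14, so at most a few hundred triples). The objective is the number of
   categories whose observed mortality lies inside its target band
   (green < 2.5%, yellow 2.5–7.5%, orange 7.5–15%, red > 15%); ties are
   broken by minimal total absolute deviation from the band anchors
   (1.25, 5.0, 11.25, 15.0%), then lexicographically for full determinism.
   An empty category counts as out-of-band and adds a fixed 100-point
   deviation penalty, so degenerate triples never beat triples populating all
   four categories. The search depends only on the score → (count, deaths)
   table, hence is invariant to row permutation.

The packaged default chart uses the published cutoffs and weights
(oxygen 4, SBP 3, RR 3, HR 2, SpO2 2); its thresholds (1, 4, 5) were produced
once by this calibration on the default synthetic cohort (n = 100,000,
seed 20160, recorded in the chart metadata) because the deployed chart's
threshold figure is not recoverable from the published text — only the
mortality bands it was tuned to are. With these thresholds all four
categories sit inside their bands on that cohort (green ≈ 2.0%,
red ≈ 16.1%).

## Synthetic cohort generator

The generator emulates the statistical structure of a large two-center ED
admission registry so every other module is testable without patient data:

- **Vitals**: independent normals (SpO2: normal truncated at 100) with round
  clinically plausible scales (SBP 27 mmHg, HR 18 bpm, RR 3.5 /min,
  SpO2 2.5%) and locations solved so each chart cutoff sits exactly at the
  10% abnormal tail — making the fixed cutoffs and the 10%-tail derivation
  mutually consistent. Oxygen treatment is Bernoulli(0.10).
- **30-day death**: main-effects logistic model on the five abnormality
  flags with odds ratios 4.27 (oxygen), 3.28 (SBP), 2.14 (HR), 2.71 (RR),
  1.67 (SpO2); the intercept is calibrated by bisection (tolerance 1e-6 on
  the probability) against the *exact* expectation over all 2^5 flag
  combinations so the marginal mortality is 4.2%.
- **Secondary outcomes**: ICU admission Bernoulli(0.034), 30-day readmission
  Bernoulli(0.10), length of stay log-normal (meanlog 1.0 ≈ 2.7 days,
  sdlog 0.8) — all independent of death by default, since only marginal
  rates are specified for them.
- **Comparator triage signals**: 5-level ordinals built by adding Gaussian
  noise to the latent mortality log-odds and cutting at quintiles. Noise
  scales (nurse assessment 1.0, DEPT-like comparator 2.5) were fixed once so
  that large-cohort discrimination reproduces the qualitative ordering
  score > nurse assessment > DEPT-proxy; the absolute AUCs of these
  comparators are emulation artifacts, not estimates of any real system.
- **Structure**: two centers exactly balanced within each half of the
  inclusion sequence; the period flips at the cross-over index (default
  n/2). Everything is reproducible bit-for-bit from the seed.

What the generator does **not** emulate: vital-sign correlations (an identity
copula is the default; the mortality model is main-effects, so independence
suffices to test it), age and comorbidity effects, arrival-time processes,
center case-mix differences (available as an optional log-odds offset in the
trial simulator), and any dependence of LOS/ICU/readmission on triage or
death. Tests passing on this generator therefore validate the *machinery* —
estimation, calibration, decision rules — not clinical performance on real
patients.

## Trial design and analysis

Primary endpoint: 30-day mortality, compared as d = p_dept − p_cta (positive
favors the new model). Per-arm sample size uses the normal approximation with
equal variance under the design null of equal mortality:
n = (z₁₋α + z_pow)² · 2p₀(1−p₀)/Δ². With p₀ = 0.042, Δ = 0.005, power 0.80
and one-sided α = 0.05 this gives 19,901/arm, 39,802 total — within 0.1% of
the published requirement of 39,820 (a rounding-level difference in quantile
precision). Note a documented tension: the published text describes a 95%
two-sided interval, but that convention (one-sided 2.5%) would require
≈ 50,500 patients; only the one-sided-5% (90% two-sided CI) convention
reproduces the published number. The quantile is therefore a parameter, with
one-sided 0.05 as the default for the design computation, while the trial
*analysis* CI defaults to the conventional two-sided 95% independently.

Non-inferiority is declared when the lower Wald bound (unpooled SE) for d
exceeds −Δ; superiority is gatekept — evaluated only after non-inferiority —
and requires the same lower bound above 0. The closed-form superiority power
at p_cta = 0.037, p_dept = 0.042, n = 20,000/arm and two-sided α = 0.05 is
≈ 0.73; the published protocol states 0.72, a mismatch that no single
quantile convention removes, so the formula is implemented as stated and the
gap left documented rather than forced. Secondary endpoints: log-transformed
LOS (and time-to-treatment when present) compared by Welch t-test with the
back-transformed geometric-mean ratio reported; ICU and readmission as Wald
proportion differences.

The cross-over simulator assigns arm = f(center, period) with the period
flipping at total_n/2 inclusions, so each arm holds exactly half the
encounters and every center serves both arms. A CTA-arm mortality effect is
an odds multiplier applied to each encounter's latent log-odds before deaths
are drawn. `operating_characteristics` estimates declaration probabilities by
Monte-Carlo; its default path draws per-arm deaths directly at the arm's
marginal mortality (exactly the information the patient-level Wald analysis
uses, since no covariates enter the decision rule), with a `vitals=True` path
running the full generator per replicate for structural checks at smaller
sizes. Readmission handling follows the encounter-splitting rule: a
readmission more than 30 days after discharge opens a new encounter; within
30 days it sets the index encounter's readmission flag (and extends the
discharge date used for subsequent gap comparisons) without creating a row.

## ROC machinery

AUC is the Mann-Whitney pair-counting statistic (ties one half); its standard
error and the paired test for two correlated AUCs use DeLong's
structural-components method (midrank formulation, so large cohorts are
O(n log n)). The published AUC table prints a single SE for all models and
does not name its method; DeLong is the standard, assumption-light choice and
handles the paired comparison the published figure implies. ROC curves carry
one point per distinct threshold including (0,0) and (1,1), and their
trapezoidal area equals the pair-counting AUC to 1e-12 (ties contribute
diagonal segments exactly). The published real-data AUCs (0.735/0.705/0.605)
are not reproducible without the registry; only their ordering is emulated.

## Problem sizes and runtime

The package's standard experiment sizes — chosen as the smallest that leave
Monte-Carlo error well inside each quantity's interpretation window — are:
200,000 encounters for odds-ratio recovery (MC error ≈ ±0.15 on the oxygen
OR), 100,000 for threshold calibration, 10^6 for verifying the calibrated
marginal mortality (binomial error ≈ ±0.04 pp), 2,000–5,000 replicate trials
for power and type-I-error estimates (MC SE ≈ 0.6–0.9 pp), and 500 bootstrap
cohorts for validating the DeLong SE.

## Known limitations

- The analysis is patient-level throughout; cluster-robust variance for the
  two-center design is not implemented (the simulator's center-offset
  parameter lets one probe the cross-over's confounding protection, but the
  decision rule ignores clustering).
- Wald intervals only; exact/score intervals for small trials are out of
  scope, and the tiny-trial behaviour (wide CI, non-inferiority never
  declared) reflects that choice.
- The generator's vital-sign distributions are synthetic stand-ins; none of
  the absolute discrimination numbers computed on them estimate real-world
  triage performance.
- Pediatric, obstetric and symptom-list (presentation-based) triage logic is
  out of scope; the DEPT-like comparator is a noisy ordinal signal, not an
  implementation of that system.
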