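# Methods

This note documents the models, algorithmic conventions and design
choices behind `hypocgm`, in the spirit of a statistical methods
appendix. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic glucose model

A subject's interstitial glucose trace is

```
g(t) = clamp( soft_floor( b + A·cos(2π(h(t) − φ)/24) + X(t) ) , 1.1, 33.3 )
```

with hypoglycaemic excursions carved in afterwards (§2). Components:

* **Baseline `b` (mmol/l)** — the subject's glycaemic set point.
* **Circadian sinusoid** — amplitude `A` (default 2.0 mmol/l), acrophase
  `φ` (default 16:00, i.e. peak late afternoon, trough ~04:00). Placing
  the trough at night reflects the usual overnight decline and puts the
  background's lowest values inside the 00:00–08:00 window.
* **Ornstein–Uhlenbeck noise `X(t)`** — stationary SD `σ` and reversion
  rate `θ` (default 0.5 h⁻¹, a ~2 h memory typical of meal-to-meal
  dynamics). Discretised with the exact AR(1) transition
  `X[k+1] = ρ X[k] + σ√(1−ρ²)·ε`, `ρ = exp(−θΔt)`, initialised from the
  stationary law, so the stationary SD is exactly `σ` at any sampling
  interval (default 5 min).
* **Counter-regulatory soft floor** — a softplus floor at 4.6 mmol/l
  (softness 0.5). Physiologically, background glycaemia does not drift
  below ~4.5 mmol/l on its own: hepatic glucose release and
  counter-regulatory hormones intervene, and clinically significant
  lows in insulin-treated diabetes are discrete events (insulin/meal
  mismatch), not diffusive noise. Statistically, the floor makes the
  marginal distribution right-skewed — as real CGM in poorly controlled
  type 2 diabetes is — and guarantees that *all* time below 4.0 mmol/l
  comes from the explicit excursion process, so episode rates and
  durations are controlled by interpretable parameters rather than by
  the Gaussian tail. Without the floor, a symmetric process calibrated
  to the low group's SD (~4.15 mmol/l at mean ~10.2) would spend ~6–7%
  of time below 4.0 mmol/l on its own and the detected episode rate
  would no longer track the configured event rate.

Consequence worth knowing: the closed form
`SD² = σ² + A²/2` (excursions off) holds only while the floor is not
engaged (baseline − A − 3σ comfortably above 4.6); the property test
uses such a configuration. With the shipped defaults the floor *is*
engaged a few percent of the time, which is why the pair (b, σ) is
calibrated rather than solved analytically (§3).

## 2. The excursion process

Hypoglycaemic excursions are a homogeneous Poisson process with rate λ
events/subject/week (defaults: 5.5 low group, 2.1 high group — the
groups' observed episode rates). Each event:

* draws a **nadir** from a two-component mixture: with probability
  `deep_prob` (1.8/5.5 low, 0.4/2.1 high — the observed ≤ 3 mmol/l
  shares) uniform on 1.9–3.0 mmol/l, else uniform on 3.1–3.9 mmol/l.
  The deep range gives P(nadir ≤ 2.2 | deep) ≈ 0.27, reproducing the
  sparse severe-hypoglycaemia rates (≈ 0.5 and 0.1 events/week);
* draws a **duration** = target time at/below 4.0 mmol/l, lognormal
  with mean 115 min (low) / 106 min (high) — observed duration/week ÷
  rate/week — CV 0.5, left-truncated at 25 min so every event exceeds
  the detector's 20-min minimum;
* is shaped as a **trapezoid**: half-cosine descent and recovery ramps
  (35 min each) joining the surrounding trace to a plateau at the
  nadir, with the plateau length chosen so the realised time at/below
  4.0 mmol/l matches the drawn duration. A plain half-cosine over the
  drawn duration would put only ~20% of it below 4.0 and make drawn
  durations unrecoverable; the trapezoid matches the sustained flat
  lows seen in overnight basal-excess hypoglycaemia and makes the
  ground truth exactly recoverable by the detector on noise-free
  traces;
* is **night-restricted** (entire span within 00:00–08:00) with
  probability `night_prob_deep` when the nadir is ≤ 3.0 mmol/l
  (defaults 0.3 low, 1.0 high — in the high group deep lows occur only
  at night). Placement is rejection-sampled (≤ 200 tries) so events are
  disjoint and separated by > 20 min of unmodified trace (30 min
  margin), which also prevents the detector's gap-merge rule from
  fusing two injected events; an unplaceable event is dropped with a
  logged warning. A configuration whose expected event time exceeds
  50% of the trace is rejected outright.

## 3. Calibration of (baseline, OU SD)

Because the floor and the excursions both move the mean and the SD, the
shipped defaults for `(b, σ)` per group are produced by
`simulate.calibrate_trace_params`: a fixed-point loop (4 rounds, pilot
of 400 subjects × 14 days, seed 20170) in which the baseline absorbs
the mean error additively and the OU variance absorbs the variance
error. Targets are the study groups' published summaries: mean glucose
10.2 / 9.9 mmol/l and mean per-subject SD 4.15 / 3.01 mmol/l
(low / high). The calibrated constants (low: b = 10.594, σ = 3.896;
high: b = 10.021, σ = 2.628) ship in `config.CGM_CALIBRATED` and are
what `default_cgm_config()` returns; the calibration routine remains
public API for re-deriving them under other targets.

## 4. Detection and measurement conventions

* **QC windows** are consecutive 24-h blocks anchored at the session
  start (sessions begin mid-day; nothing in the inclusion rules anchors
  to midnight). A trailing partial window is discarded, never
  evaluated. MAD% uses the SMBG as denominator (MARD-style reference
  convention). The r and MAD% inequalities are strict, exactly as
  stated (> 0.77, < 28). An undefined correlation (fewer than two
  pairs, or zero variance) fails the criterion. SMBG–sensor pairing
  uses the nearest grid sample within ±5 min, ties to the earlier
  sample; both conventions are choices, since the inclusion rules do
  not specify them.
* **Episodes**: each sample represents the interval [t, t + Δt), so
  duration = (# samples at/below threshold) × Δt. Runs separated by an
  above-threshold gap of ≤ 20 min are merged (an episode completes only
  after *more than* 20 min above threshold); merged-gap time is
  excluded from duration, since the reported quantity is time at/below
  threshold. Episodes are assigned wholly to day or night by start
  time — splitting would double-count episodes in per-period rates.
  Boundary conventions: 08:00 → day, 00:00 → night.
* **Metrics** are computed on the pooled retained samples per subject
  (not per-window then averaged). MAGE collapses plateaus to single
  turning points, qualifies excursions whose amplitude exceeds 1 SD
  (n − 1) of the full series, and averages amplitudes in the direction
  of the first qualifying excursion; when nothing qualifies MAGE is
  undefined (None), not zero. LBGI converts with 18.016 mg/dl per
  mmol/l and uses every sample.
* **Statistics**: Pearson χ² without continuity correction (a
  correction switch exists); Wald CIs for regression coefficients;
  exact Garwood intervals `[χ²(α/2, 2k)/2, χ²(1−α/2, 2k+2)/2] / T` for
  raw Poisson rates; the rate-ratio z test is on log rates with
  `SE = √(1/k₁ + 1/k₂)` (the natural scale for a ratio; which scale the
  original analysis used is not stated). Zero event counts yield a
  flagged unbounded CI, never a silent infinity. Adjusted models are
  IRLS/ML fits via statsmodels; separation or non-convergence raises
  rather than returning.

## 5. The questionnaire generator

True monthly symptomatic (Q5) and asymptomatic (Q6) counts are Poisson
with the group means (3.5 / 1.8 and 1.4 / 0.69 episodes/month); each
count maps to the category whose recoded value (0, 2, 4, 10, 18, 25) is
nearest, ties to the lower category. Note the round trip
category→rate is biased low relative to the Poisson mean (e.g. a drawn
count of 1 maps to "none"): recoded group rates are therefore
compressed toward zero relative to the configured means. This is
inherent to analysing coarse self-report categories and is shared by
the analysis stage, so between-group contrasts remain directionally
faithful. Awareness items are independent Bernoulli draws (defaults
0.29 / 0.22 per item, giving reduced-awareness prevalences of roughly
one-in-ten vs one-in-twenty); Q3/Q4 annual counts are Poisson with
small group-specific rates.

## 6. Problem sizes used by tests and the acceptance script

The study-scale round trip simulates the design-sized cohort (17 + 17
subjects, 4.25 recording days at 5-min sampling) over 20 replicate
seeds — about 680 subject-recordings — which holds the Monte-Carlo SE
of every group summary well inside the published 95% CIs it is checked
against. Oracle-equivalence checks use 1000 random traces ≤ 200 samples
(episodes) and 300 traces ≤ 100 samples (MAGE); null-calibration checks
use 1000 replicates. The pilot calibration (§3) is larger (400 × 14 d)
but runs offline; its outputs ship as constants.

## 7. What the generator does and does not emulate

It reproduces: two strata with matched means and distinct SDs,
Poisson-distributed excursions with realistic durations/depths,
night-confined deep lows in the insulin-preserved group, SMBG
calibration noise (CV 4.5%), 1:1 sex/HbA1c matching in the CGM cohort,
and covariate distributions adequate for exercising the adjusted
models. It does not model meals or insulin doses, sensor drift,
compression artefacts, missing-data patterns, or any feedback between
glycaemia and behaviour; the OU + sinusoid + excursion form is a
modelling choice, not an identified physiological model. Passing the
round-trip tests therefore demonstrates that the *pipeline* measures
faithfully what the generator encodes — not that the generator is a
complete model of CGM physiology. LBGI and MAGE levels, in particular,
depend on distributional details the published summaries do not pin
down, so only their ordering between groups is asserted.

## 8. Known limitations

* MAGE on a series whose first/last samples sit mid-excursion counts
  the truncated end swings like any other; different MAGE
  implementations disagree on such edge handling.
* Metrics are pooled across non-contiguous retained segments; a
  turning point spanning an excised window boundary is treated as if
  the segments were abutting.
* The adjusted-model defaults assume complete covariates; rows with
  missing values are dropped, not imputed.
* Day/night rates use episode start time only; an episode straddling
  08:00 contributes wholly to night.
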