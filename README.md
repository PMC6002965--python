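# hypocgm

Continuous-glucose-monitoring (CGM) analytics for studying hypoglycaemia
risk in insulin-treated type 2 diabetes stratified by random non-fasting
C-peptide (rCP), a routine biomarker of residual endogenous insulin
secretion. Patients with severe insulin deficiency (rCP < 200 pmol/l)
show markedly higher glucose variability and more frequent, longer
hypoglycaemia than patients with preserved secretion, despite similar
mean glucose — this package implements the full measurement pipeline
behind that comparison, together with a calibrated synthetic-cohort
generator so every stage is testable without patient data.

## What it computes

For each subject with an interstitial glucose trace g(t) sampled every
5 min over ~4 days, plus fingerstick (SMBG) calibration readings:

* **Quality control** per consecutive 24-h window: ≥ 3 paired SMBG
  calibrations, no missing samples, Pearson r(SMBG, sensor) > 0.77 and
  MAD% < 28, where MAD% = mean(|SMBG − sensor| / SMBG) × 100. Failing
  windows are excised; subjects with < 24 h retained are excluded.
* **Glycaemic variability**: mean, SD (n − 1), MAGE (mean amplitude of
  glycaemic excursions exceeding 1 SD, Service's turning-point rule) and
  LBGI (Kovatchev low blood glucose index,
  f(g) = 1.509·((ln g_mg/dl)^1.084 − 5.381), LBGI = mean of 10·f² over
  samples with f < 0).
* **Hypoglycaemia episodes** at 4.0 / 3.0 / 2.2 mmol/l: an episode is
  ≥ 20 min at or below threshold and completes only after > 20 min above
  it; durations count time at/below threshold only. Episodes are
  assigned to day (08:00–00:00) or night (00:00–08:00) by start time and
  converted to exposure-normalised rates (episodes/person/week) and
  durations (min/person/week).
* **Clarke hypoglycaemia-awareness questionnaire**: seven 0/1 items,
  score ≥ 4 = reduced awareness; Q5/Q6 frequency categories recoded to
  episodes/month as none→0, 1–3/month→2, 1/week→4, 2–3/week→10,
  4–5/week→18, almost daily→25.
* **Group statistics**: paired t tests, Pearson χ², exact (Garwood)
  Poisson rate CIs from χ² quantiles, rate-ratio z tests on log rates,
  and covariate-adjusted logistic / Poisson / ANCOVA models.

The synthetic generator emulates the two strata of both study designs
(17 + 17 CGM subjects; 35 + 221 questionnaire subjects) with matched
mean glucose but differing variability and Poisson excursion processes;
see `docs/methods.md` for the model and its calibration.

## Worked example

```bash
hypocgm --seed 1 --out-dir out run-all --mode both
```

writes the simulated cohorts (`subjects.csv`, `cgm.csv`, `smbg.csv`,
`clarke.csv`), the stage outputs (`qc_report.csv`, `metrics.csv`,
`episodes.csv`, `hypo_summary.csv`, `clarke_scored.csv`,
`comparisons.csv`) and a JSON + text report. The text report begins:

```
CGM study: hypoglycaemia by C-peptide group
============================================================

Proportion with >= 1 episode:
     low  <= 4.0 mmol/l : 88%
     low  <= 3.0 mmol/l : 59%
    ...
Rate (episodes/person/week):
     low  <= 4.0 mmol/l : 6.38
    high  <= 4.0 mmol/l : 1.85
    ...
Duration (min/person/week):
     low  <= 4.0 mmol/l : 739
    high  <= 4.0 mmol/l : 186
    ...
Variability (group means):
     low  mean 9.9007 mmol/l, SD 4.0185 mmol/l, LBGI 1.4225
    high  mean 9.7705 mmol/l, SD 2.9066 mmol/l, LBGI 0.3815
```

Read this as: in the severely insulin-deficient ("low") group almost
every subject experiences sustained hypoglycaemia ≤ 4 mmol/l, at roughly
three times the rate and four times the weekly duration of the "high"
group, while the per-subject SD of glucose is ~1.1 mmol/l higher at the
same mean glucose — the signature pattern the pipeline is built to
measure. The contrasts section gives each difference with its 95% CI and
p-value (paired t, χ², or rate-ratio z test as appropriate).

The same analyses run on your own data: place CSVs in the documented
schemas (see `hypocgm/io.py`) in `--out-dir` and use the stage verbs
`qc`, `metrics`, `episodes`, `clarke`, `compare`.

As a library:

```python
from hypocgm import default_cgm_config, generate_cohort, apply_qc, compute_metrics

cohort = generate_cohort(default_cgm_config(seed=1))
rep = apply_qc(cohort.traces["low000"], cohort.smbg["low000"])
print(compute_metrics("low000", rep.segments))
```

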