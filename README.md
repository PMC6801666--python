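# heatcross

Heatwave health-impact analysis in Python: Excess Heat Factor (EHF) heatwave
identification with severity tiers, daily exposure preparation (PM2.5
gap-filling, public-holiday flags), time-stratified case-crossover dataset
construction, and conditional logistic regression for whole-population and
subgroup odds ratios.

The package is aimed at environmental-epidemiology analysts who want to
estimate the short-term effect of severe/extreme heatwave days on counts of
acute health events (here: hospital emergency-department presentations),
with the whole workflow testable end to end on synthetic data carrying known
effect sizes — no confidential line list or reanalysis archive required.

## The method

**Heatwave exposure.** For each region, daily mean temperature is
`T = (Tmax + Tmin)/2`. With `T3(i)` the mean over days `i−2..i` and `T30(i)`
the mean over the preceding 30 days (`i−32..i−3`), the Excess Heat Factor is

```
EHI_sig(i)  = T3(i) − T95            (climatological significance, °C)
EHI_accl(i) = T3(i) − T30(i)         (short-term acclimatization, °C)
EHF(i)      = EHI_sig(i) × max(1, EHI_accl(i))     (°C²)
```

where `T95` is the 95th percentile of daily mean temperature over a
reference period. A day with `EHF > 0` is a heatwave day: *low intensity*
below the 85th percentile of positive climatological EHF (`ehf85`), *severe*
at or above it, *extreme* at or above `3 × ehf85`. The analysis exposure is
severe-or-extreme.

**Design.** Each presentation is matched to itself on referent days — every
other day in the same calendar month and year falling on the same weekday
(3 or 4 per case). Day-of-week and seasonal confounding cancel within
stratum; stable personal characteristics cancel because case and referents
are the same person.

**Estimation.** The conditional logistic likelihood
`ℓ(β) = Σ_s [x_case·β − log Σ_{j∈s} exp(x_j·β)]` is maximized exactly by
Newton iteration (stratum sizes ≤ 5, so the denominator is enumerated, not
approximated). The reported odds ratio is `exp(β_exposed)` with a Wald 95%
CI, adjusted for daily PM2.5 and public holidays.

## Worked example

```python
import heatcross as hc

cfg = hc.SyntheticConfig(
    seed=3, study_start="2014-01-01", study_end="2015-12-31",
    outcome=hc.OutcomeConfig(daily_rate=50.0, heatwave_rr=1.5),
)
study = hc.simulate_study(cfg)
pm = hc.fill_pm25_gaps(study["pm25"])
exposure = hc.assemble_exposure_table(
    study["calendar"], pm, study["holidays"], cfg.study_start, cfg.study_end)
dataset = hc.build_analysis_dataset(study["presentations"], exposure)
fit = hc.fit_conditional_logit(dataset.data, ("exposed", "pm25", "holiday"))
print(dataset.n_strata, dataset.n_informative, round(fit.or_, 2), fit.ci95)
```

prints

```
36781 931 1.52 (1.324471524168967, 1.7434588289280883)
```

— 36,781 matched strata of which 931 are informative (exposure differs
between the case day and at least one referent), and an estimated odds ratio
of 1.52 (95% CI 1.32–1.74) against a generating rate ratio of 1.5: the
pipeline recovers the known effect. The `examples/` directory holds one
short narrative script per capability (heatwave identification, exposure
preparation, the matched fit, the full study), and a `heatcross` CLI exposes
the same stages as subcommands (`generate`, `compute-ehf`, `build-dataset`,
`fit`, `run-all`).

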