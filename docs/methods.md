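# Methods

This note documents the models and procedures implemented in `heatcross`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Excess Heat Factor

Daily mean temperature is `(Tmax + Tmin)/2` over the midnight-to-midnight
local day. The EHF combines a *significance* index (the 3-day mean minus a
climatological 95th percentile `t95`) with an *acclimatization* index (the
3-day mean minus the preceding 30-day mean), as
`EHF = EHI_sig × max(1, EHI_accl)`, in °C². The `max(1, ·)` floor means a
climatologically hot spell always scores at least its significance excess;
acclimatization only amplifies, never excuses, unusual heat.

**Window orientation.** The 3-day window *ends* on the indexed day
(days `i−2..i`), with the acclimatization window the 30 days before it
(`i−32..i−3`). A backward window is the natural choice for retrospective
health attribution — a day's exposure should reflect heat already
experienced — whereas heatwave *forecasting* uses a forward window
(`i..i+2`). Both are implemented (`orientation="backward"|"forward"`);
backward is the default. The first 32 days of a series have insufficient
history, carry undefined components, and are classified "none" and excluded
from threshold fitting.

**Thresholds.** `t95` is the empirical 95th percentile of daily mean
temperature over the reference period (default: the full study window, all
calendar days pooled; configurable). `ehf85` is the 85th percentile of the
*strictly positive* EHF values over the same window, computed in a second
pass using `t95`. Severity is: low for `0 < EHF < ehf85`, severe for
`ehf85 ≤ EHF < 3·ehf85`, extreme for `EHF ≥ 3·ehf85` — boundaries belong to
the higher class, and the extreme threshold is exactly three times the
severe one. The analysis exposure pools severe and extreme days (extreme
days are rare; low-intensity days are common and mild). All percentiles use
linear interpolation between order statistics, and every test oracle uses
the same definition. There is no event-persistence rule beyond what the
3-day mean already encodes: any day with positive EHF is a heatwave day of
some severity.

A reference window shorter than two years is rejected, as is a window with
no positive EHF values ("no heat events in reference period") — a constant
series has no meaningful heat threshold.

## PM2.5 gap-filling

Two regimes, split at the 48-hour mark:

* gaps of 1–2 daily records: filled with the mean of the up-to-7 observed
  days before plus the up-to-7 observed days after the gap, pooled. An
  alternative reading — average of the two one-sided means — is available
  (`short_gap_rule="two_means"`); the two coincide when both sides
  contribute equally many days. Pooled is the default for simplicity.
* gaps of 3 or more days: linear interpolation between the nearest observed
  values on each side.

Filled values are floored at 0 (cannot occur with non-negative anchors, but
guarded) and flagged, so the fill is idempotent and auditable. A gap
touching the series boundary has no anchor on one side and is an error
rather than an extrapolation.

## Case-crossover dataset

Referent days for a case day are every other same-weekday day in the same
calendar month and year: 3 or 4 per case, symmetric (if *b* is a referent of
*a* then *a* is one of *b*), never including the case day. Exposure is
attached by the presentation's region — each region has its own heatwave
calendar and pollution monitor. No exposure lag is applied: the presentation
day's exposure only.

ICD-10 diagnostic grouping matches on the 3-character category (J45.9
belongs to J45–J46); groups may overlap and a presentation can belong to
several. Codes outside every configured range (and missing codes)
contribute only to whole-population analyses. SEIFA deciles condense to low
(1–3), middle (4–7), high (8–10) relative advantage; unknown deciles and
genders are kept for whole-population analysis and dropped only from the
affected subgroup. Age bands follow the study convention: ≤5 and ≤15
overlap by design and are analysed separately; "over 65" is strictly >65.

## Conditional logistic regression

The conditional likelihood conditions on one case per stratum, eliminating
stratum intercepts. With stratum sizes ≤5 the per-stratum denominator is the
exact sum over members — no approximation. Estimation is damped Newton from
β = 0: convergence when `max |score| < 1e−8`, at most 50 iterations,
step-halving if the log-likelihood would decrease (the likelihood is
concave, so halving suffices). Standard errors come from the inverse
observed information; CIs are Wald at z = 1.959964. A coefficient escaping
±10 indicates a monotone likelihood (separation); the fit is flagged
non-converged with the runaway direction rather than returning a spurious
estimate. A design in which no stratum varies in exposure has a flat
exposure likelihood and raises "no information".

Adjusters enter linearly and untransformed: PM2.5 as the daily µg/m³ value,
holiday as 0/1. Subgroup analyses with fewer than 2 informative strata or
fewer than 30 cases are reported as "insufficient data" instead of fitted
(thresholds configurable); no multiple-testing correction is applied, each
subgroup being reported on its own.

Verification is dual-route throughout: a dense grid-search maximizer for
unadjusted designs, the closed-form 1:1 matched-pair estimator
(OR = n10/n01), a within-stratum permutation null for empirical type-I
error, and an independent library implementation of the same likelihood as
a cross-check in the test suite.

## Synthetic-data generator

The generator produces the full set of study inputs with recorded ground
truth:

* **Temperature:** per region, an annual sinusoid (southern-hemisphere
  January peak; default mean 12.5 °C, amplitude 6 °C — a cool temperate
  maritime climate) plus AR(1) noise (ρ = 0.7, innovation sd 2.2 °C,
  capturing day-to-day persistence with the high variability of a
  frontal-weather regime), `Tmax/Tmin = Tmean ± 4.5 °C`, and injected
  multi-day summer heat episodes (default one 4-day, +11 °C episode per
  summer per region) recorded in the truth log.
* **PM2.5:** lognormal daily values (median ≈ 5.5 µg/m³, log-sd 0.55) with
  a winter elevation emulating wood-smoke season, and missing runs of
  configured lengths (default 1–6 days) whose true values are logged so the
  gap-fill can be scored.
* **Holidays:** a Tasmanian-pattern calendar (fixed-date, Easter-derived
  and Monday-rule holidays, including a local February holiday).
* **Presentations:** daily counts per region are Poisson with rate
  `baseline × dow × holiday × RR^exposed`; default baseline 256.1/day split
  60/40 across two regions, mild weekday multipliers peaking Monday, a 1.10
  holiday multiplier. Individuals carry age band (10.1% ≤5, 8.9% 6–15,
  61.9% 16–65, 19.1% >65), gender (51.6/48.3/0.1% male/female/unknown —
  the small unknown share mirrors real line lists whose gender rows do not
  sum to the total), SEIFA band (52/30/16/2% low/middle/high/unknown) and
  an ICD-10 code from a fixed mix dominated by non-grouped codes with
  realistic shares for the grouped conditions. Heatwave rate ratios may
  differ by age band; they act both on the daily rate and on the exposed-day
  age composition, so the overall ratio is the composition-weighted mixture
  of band ratios (written to the truth log).

What the generator does **not** emulate: spatially coherent weather between
regions, humidity or ozone, long-term presentation trends, overdispersed
counts, repeat presentations by the same person, or diagnostic-specific
heat sensitivity (the heat-and-light-disorder surge seen in real data). A
passing recovery experiment therefore shows the estimator is correct under
a clean Poisson world with the study's matching structure — not that every
feature of real ED data is harmless.

## Problem sizes in the validation runs

The stochastic checks run on reduced-scale studies — 2 years at ~50
presentations/day (≈36,000 strata) — which keep a full
generate-match-fit replicate under half a second while still yielding
~900 informative strata per study: CI coverage is evaluated over 100
replicates per generating rate ratio, and the permutation null uses 500
within-stratum permutations on the informative strata of a null study
(permuting a concordant stratum is a no-op, so restricting to informative
strata changes no fit, only the cost). The descriptive-arithmetic checks
use the published group totals of the 2008–2016 study population over its
3,288-day window.

## Known limitations

* The severe threshold (85th percentile of positive EHF) and the reference
  period are conventions; sites with different climates may warrant
  different percentiles, which is why both are configurable.
* Wald intervals are first-order; in very sparse subgroups (few informative
  strata) they can under-cover, which is one reason sparse subgroups are
  reported as "insufficient data" rather than fitted.
* The exposure is binary (severe/extreme vs not); no dose-response in EHF
  magnitude, and no distributed-lag structure.
* Per-region pooling fits a single model with region-specific exposure;
  effect-measure modification by region is not modelled.
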