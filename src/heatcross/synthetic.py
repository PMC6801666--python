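"""Synthetic study generator with known ground truth.

Real inputs for this kind of study -- reanalysis temperatures, monitor PM2.5
and a confidential hospital line list -- cannot be redistributed, so every
stage of the pipeline is exercised on synthetic data whose generating
parameters are recorded in a *truth log*.  The generator emulates:

* a two-region, multi-year daily temperature series: a southern-hemisphere
  seasonal sinusoid (January peak) plus AR(1) day-to-day noise, with rare
  injected multi-day summer heat episodes that the EHF machinery should
  classify as severe/extreme;
* daily PM2.5 per region: lognormal with a mild winter elevation (wood-smoke
  season) and occasional missing runs for the gap-filler to repair;
* a public-holiday calendar in the style of Tasmania (fixed-date, Easter
  derived and Monday-rule holidays);
* an ED presentation line list: daily counts are Poisson with day-of-week
  and holiday multipliers and a heatwave rate ratio on exposed days;
  individuals carry age, gender, SEIFA decile and an ICD-10 code drawn from
  configured compositions that mirror the descriptive make-up of a
  population of ~256 presentations/day (about 10% aged <=5, 19% <=15, 19%
  over 65, 52% male, 52% low-SEIFA).

Heatwave rate ratios can differ by age band; they act by tilting both the
daily Poisson rate and the age composition on exposed days, so the overall
rate ratio is the composition-weighted mixture of the band ratios (recorded
in the truth log).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import pathlib

import numpy as np
import pandas as pd

from . import ehf as ehf_mod

__all__ = [
    "TemperatureConfig",
    "Pm25Config",
    "OutcomeConfig",
    "SyntheticConfig",
    "tasmanian_style_holidays",
    "simulate_temperature",
    "simulate_pm25",
    "simulate_presentations",
    "simulate_study",
    "generate_study",
]

AGE_BANDS = ("le5", "a6_15", "a16_65", "gt65")
_AGE_RANGES = {"le5": (0, 5), "a6_15": (6, 15), "a16_65": (16, 65), "gt65": (66, 95)}


@dataclasses.dataclass
class TemperatureConfig:
    """Seasonal AR(1) temperature model with injected heat episodes.

    ``annual_mean``/``seasonal_amplitude`` (degC) define the sinusoidal
    climatology (peak mid-January); ``ar1`` and ``noise_sd`` the day-to-day
    autocorrelated anomaly; ``diurnal_range`` the tmax-tmin spread.
    ``episodes_per_summer`` heat episodes of ``episode_length_days`` days and
    ``episode_excess`` degC are injected at random summer (Dec-Feb) dates.
    """

    annual_mean: float = 12.5
    seasonal_amplitude: float = 6.0
    ar1: float = 0.7
    noise_sd: float = 2.2
    diurnal_range: float = 9.0
    episodes_per_summer: int = 1
    episode_length_days: int = 4
    episode_excess: float = 11.0
    region_offsets: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"hobart": 0.0, "launceston": 1.0}
    )


@dataclasses.dataclass
class Pm25Config:
    """Lognormal daily PM2.5 (ug/m3) with seasonal wood-smoke elevation and
    missing runs of the given lengths placed at random interior dates."""

    log_mean: float = 1.7  # exp(1.7) ~ 5.5 ug/m3 median
    log_sd: float = 0.55
    winter_log_amplitude: float = 0.4
    missing_run_lengths: tuple[int, ...] = (1, 2, 2, 4, 6)


@dataclasses.dataclass
class OutcomeConfig:
    """Poisson presentation process and population composition.

    ``daily_rate`` is the all-region mean daily presentation count, split
    across regions by ``region_shares``.  ``heatwave_rr`` multiplies the
    rate on severe/extreme heatwave days; per-age-band overrides go in
    ``heatwave_rr_by_age`` (unset bands inherit the overall value).
    Composition proportions per axis must sum to 1.
    """

    daily_rate: float = 256.1
    region_shares: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"hobart": 0.6, "launceston": 0.4}
    )
    dow_multipliers: tuple[float, ...] = (1.07, 1.0, 0.97, 0.96, 0.98, 0.99, 1.03)
    holiday_multiplier: float = 1.10
    heatwave_rr: float = 1.05
    heatwave_rr_by_age: dict[str, float] = dataclasses.field(default_factory=dict)
    age_proportions: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"le5": 0.101, "a6_15": 0.089, "a16_65": 0.619, "gt65": 0.191}
    )
    gender_proportions: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"male": 0.516, "female": 0.483, "unknown": 0.001}
    )
    seifa_band_proportions: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"low": 0.52, "middle": 0.30, "high": 0.16, "unknown": 0.02}
    )
    icd10_proportions: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "J18": 0.040,  # respiratory, not asthma/COPD
            "J45": 0.010,
            "J44": 0.012,
            "I20": 0.017,
            "I48": 0.003,
            "I50": 0.006,
            "I10": 0.002,
            "E11": 0.002,
            "F32": 0.030,
            "F03": 0.001,
            "F41": 0.008,
            "N17": 0.002,
            "N20": 0.001,
            "N39": 0.020,
            "T67": 0.0005,
            "S00": 0.150,
            "R10": 0.120,
            "Z00": 0.5755,
        }
    )


@dataclasses.dataclass
class SyntheticConfig:
    """Complete configuration of one synthetic study."""

    seed: int = 0
    study_start: str = "2008-01-01"
    study_end: str = "2016-12-31"
    regions: tuple[str, ...] = ("hobart", "launceston")
    temperature: TemperatureConfig = dataclasses.field(default_factory=TemperatureConfig)
    pm25: Pm25Config = dataclasses.field(default_factory=Pm25Config)
    outcome: OutcomeConfig = dataclasses.field(default_factory=OutcomeConfig)

    def validate(self) -> None:
        for name, props in (
            ("age_proportions", self.outcome.age_proportions),
            ("gender_proportions", self.outcome.gender_proportions),
            ("seifa_band_proportions", self.outcome.seifa_band_proportions),
            ("icd10_proportions", self.outcome.icd10_proportions),
        ):
            total = sum(props.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"{name} sum to {total}, expected 1")
            if any(p < 0 for p in props.values()):
                raise ValueError(f"{name} contain negative proportions")
        if self.outcome.daily_rate < 0:
            raise ValueError("daily_rate must be non-negative")
        if not all(m > 0 for m in self.outcome.dow_multipliers):
            raise ValueError("dow multipliers must be positive")
        rrs = [self.outcome.heatwave_rr, *self.outcome.heatwave_rr_by_age.values()]
        if not all(r > 0 for r in rrs):
            raise ValueError("rate ratios must be positive")
        n_days = len(pd.date_range(self.study_start, self.study_end, freq="D"))
        if self.temperature.episode_length_days > n_days:
            raise ValueError("episode longer than study window")


def _easter_sunday(year: int) -> dt.date:
    """Gregorian Easter (anonymous computus)."""
    a = year % 19
    b, c = divmod(year, 100)
    d, e = divmod(b, 4)
    g = (8 * b + 13) // 25
    h = (19 * a + b - d - g + 15) % 30
    i, k = divmod(c, 4)
    l = (32 + 2 * e + 2 * i - h - k) % 7
    m = (a + 11 * h + 22 * l) // 451
    month, day = divmod(h + l - 7 * m + 114, 31)
    return dt.date(year, month, day + 1)


def _nth_weekday(year: int, month: int, weekday: int, n: int) -> dt.date:
    first = dt.date(year, month, 1)
    offset = (weekday - first.weekday()) % 7
    return first + dt.timedelta(days=offset + 7 * (n - 1))


def tasmanian_style_holidays(years: range | list[int]) -> list[dt.date]:
    """State-wide public holidays in the Tasmanian pattern.

    New Year's Day, Australia Day (26 Jan), Eight Hours Day (2nd Monday of
    March), Good Friday through Easter Monday, Anzac Day (25 Apr), Queen's
    Birthday (2nd Monday of June), Christmas and Boxing Day, plus the
    locally specific Royal Hobart Regatta (2nd Monday of February).
    """
    days: list[dt.date] = []
    for y in years:
        easter = _easter_sunday(y)
        days += [
            dt.date(y, 1, 1),
            dt.date(y, 1, 26),
            _nth_weekday(y, 2, 0, 2),   # Regatta Day
            _nth_weekday(y, 3, 0, 2),   # Eight Hours Day
            easter - dt.timedelta(days=2),
            easter + dt.timedelta(days=1),
            dt.date(y, 4, 25),
            _nth_weekday(y, 6, 0, 2),
            dt.date(y, 12, 25),
            dt.date(y, 12, 26),
        ]
    return sorted(set(days))


def _summer_mask(dates: pd.DatetimeIndex) -> np.ndarray:
    return np.isin(dates.month, [12, 1, 2])


def simulate_temperature(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[dict]]:
    """Daily tmax/tmin per region plus a truth log of injected episodes."""
    config.validate()
    tc = config.temperature
    dates = pd.date_range(config.study_start, config.study_end, freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    seasonal = tc.annual_mean + tc.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - 15) / 365.25
    )
    frames = []
    episodes: list[dict] = []
    summer_idx = np.flatnonzero(_summer_mask(dates))
    n_summers = max(1, len(pd.period_range(config.study_start, config.study_end, freq="Y")))
    for region in config.regions:
        noise = np.empty(n)
        innov = rng.normal(0.0, tc.noise_sd, size=n)
        noise[0] = innov[0] / np.sqrt(max(1e-12, 1 - tc.ar1**2)) if tc.noise_sd > 0 else 0.0
        for i in range(1, n):
            noise[i] = tc.ar1 * noise[i - 1] + innov[i]
        excess = np.zeros(n)
        n_episodes = tc.episodes_per_summer * n_summers
        if n_episodes > 0 and len(summer_idx) > 0:
            starts = rng.choice(
                summer_idx[summer_idx <= n - tc.episode_length_days],
                size=min(n_episodes, len(summer_idx)),
                replace=False,
            )
            for s in np.sort(starts):
                sl = slice(s, s + tc.episode_length_days)
                excess[sl] = np.maximum(excess[sl], tc.episode_excess)
                episodes.append(
                    {
                        "region_id": region,
                        "start": str(dates[s].date()),
                        "length_days": int(tc.episode_length_days),
                        "excess_c": float(tc.episode_excess),
                    }
                )
        tmean = seasonal + tc.region_offsets.get(region, 0.0) + noise + excess
        frames.append(
            pd.DataFrame(
                {
                    "region_id": region,
                    "date": dates,
                    "tmax": tmean + tc.diurnal_range / 2.0,
                    "tmin": tmean - tc.diurnal_range / 2.0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), episodes


def simulate_pm25(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[dict]]:
    """Daily PM2.5 per region with masked runs; returns (frame, truth log).

    The truth log records every masked value so gap-fill error can be scored.
    """
    config.validate()
    pc = config.pm25
    dates = pd.date_range(config.study_start, config.study_end, freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    winter = pc.winter_log_amplitude * np.cos(2 * np.pi * (doy - 196) / 365.25)
    frames = []
    masked: list[dict] = []
    for region in config.regions:
        log_values = pc.log_mean + winter + rng.normal(0.0, pc.log_sd, size=n)
        values = np.exp(log_values)
        pm = values.copy()
        taken: set[int] = set()
        for run_len in pc.missing_run_lengths:
            if run_len >= n - 2:
                continue
            for _ in range(50):  # rejection-sample an interior, non-adjacent slot
                start = int(rng.integers(1, n - run_len - 1))
                span = set(range(start - 1, start + run_len + 1))
                if not span & taken:
                    break
            else:
                continue
            taken |= span
            for i in range(start, start + run_len):
                masked.append(
                    {
                        "region_id": region,
                        "date": str(dates[i].date()),
                        "true_pm25": float(values[i]),
                    }
                )
                pm[i] = np.nan
        frames.append(
            pd.DataFrame({"station_id": region, "region_id": region, "date": dates, "pm25": pm})
        )
    return pd.concat(frames, ignore_index=True), masked


def _mixture_rr(outcome: OutcomeConfig) -> float:
    """Overall exposed/unexposed rate ratio implied by the age-band ratios."""
    return sum(
        p * outcome.heatwave_rr_by_age.get(band, outcome.heatwave_rr)
        for band, p in outcome.age_proportions.items()
    )


def simulate_presentations(
    config: SyntheticConfig,
    calendar: pd.DataFrame,
    holidays: list[dt.date],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson ED line list with known day-level and subgroup effects.

    Daily counts per region are Poisson with rate ``baseline * dow *
    holiday * mixture_rr^exposed``; on exposed days the age composition is
    tilted by the band-specific rate ratios so each band individually
    experiences its configured ratio.
    """
    config.validate()
    oc = config.outcome
    hol = set(pd.Timestamp(h) for h in holidays)
    cal = calendar.copy()
    cal["date"] = pd.to_datetime(cal["date"])
    bands = list(oc.age_proportions)
    base_p = np.array([oc.age_proportions[b] for b in bands])
    band_rr = np.array(
        [oc.heatwave_rr_by_age.get(b, oc.heatwave_rr) for b in bands]
    )
    mix_rr = float(base_p @ band_rr)
    tilted_p = base_p * band_rr / mix_rr
    genders = list(oc.gender_proportions)
    gender_p = np.array([oc.gender_proportions[g] for g in genders])
    seifa_bands = list(oc.seifa_band_proportions)
    seifa_p = np.array([oc.seifa_band_proportions[b] for b in seifa_bands])
    # decile sampled uniformly inside the band; "unknown" -> blank decile
    band_deciles = {"low": (1, 2, 3), "middle": (4, 5, 6, 7), "high": (8, 9, 10)}
    codes = list(oc.icd10_proportions)
    code_p = np.array([oc.icd10_proportions[c] for c in codes])

    band_lo = np.array([_AGE_RANGES[b][0] for b in bands])
    band_hi = np.array([_AGE_RANGES[b][1] for b in bands])

    frames = []
    next_id = 1
    for region in config.regions:
        sub = cal[cal["region_id"] == region].sort_values("date").reset_index(drop=True)
        share = oc.region_shares.get(region)
        if share is None:
            raise ValueError(f"no region share for {region!r}")
        dates = sub["date"]
        exposed = sub["exposed"].to_numpy(dtype=bool)
        dow = np.array([oc.dow_multipliers[d.weekday()] for d in dates])
        is_hol = np.array([d in hol for d in dates])
        lam = oc.daily_rate * share * dow
        lam = np.where(is_hol, lam * oc.holiday_multiplier, lam)
        lam = np.where(exposed, lam * mix_rr, lam)
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        day_idx = np.repeat(np.arange(len(sub)), counts)
        row_exposed = exposed[day_idx]
        band_idx = np.empty(total, dtype=int)
        n_exp = int(row_exposed.sum())
        band_idx[~row_exposed] = rng.choice(len(bands), size=total - n_exp, p=base_p)
        if n_exp:
            band_idx[row_exposed] = rng.choice(len(bands), size=n_exp, p=tilted_p)
        age = rng.integers(band_lo[band_idx], band_hi[band_idx] + 1)
        gender_idx = rng.choice(len(genders), size=total, p=gender_p)
        seifa_idx = rng.choice(len(seifa_bands), size=total, p=seifa_p)
        code_idx = rng.choice(len(codes), size=total, p=code_p)
        decile = np.full(total, "", dtype=object)
        for s, band in enumerate(seifa_bands):
            mask = seifa_idx == s
            if band in band_deciles and mask.any():
                picks = rng.choice(band_deciles[band], size=int(mask.sum()))
                decile[mask] = picks.astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "presentation_id": [
                        f"p{next_id + i:07d}" for i in range(total)
                    ],
                    "date": dates.to_numpy()[day_idx],
                    "region_id": region,
                    "age": age,
                    "gender": np.array(genders, dtype=object)[gender_idx],
                    "seifa_decile": decile,
                    "icd10": np.array(codes, dtype=object)[code_idx],
                }
            )
        )
        next_id += total
    if not frames:
        return pd.DataFrame(
            columns=[
                "presentation_id", "date", "region_id", "age", "gender", "seifa_decile", "icd10",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def simulate_study(config: SyntheticConfig) -> dict:
    """Generate every study input in memory, plus the truth log.

    Returns a dict with keys ``temperature``, ``pm25``, ``holidays``,
    ``presentations``, ``calendar`` (the heatwave calendar actually used to
    drive outcome rates) and ``truth``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    temps, episodes = simulate_temperature(config, rng)
    pm25, masked = simulate_pm25(config, rng)
    clim = ehf_mod.fit_climatology(temps)
    series = ehf_mod.classify_severity(ehf_mod.compute_ehf_series(temps, clim), clim)
    calendar = ehf_mod.heatwave_calendar(series)
    years = range(
        pd.Timestamp(config.study_start).year, pd.Timestamp(config.study_end).year + 1
    )
    holidays = tasmanian_style_holidays(years)
    presentations = simulate_presentations(config, calendar, holidays, rng)
    truth = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "episodes": episodes,
        "masked_pm25": masked,
        "heatwave_rr": config.outcome.heatwave_rr,
        "heatwave_rr_by_age": dict(config.outcome.heatwave_rr_by_age),
        "overall_mixture_rr": _mixture_rr(config.outcome),
        "n_exposed_days": int(calendar["exposed"].sum()),
    }
    return {
        "temperature": temps,
        "pm25": pm25,
        "holidays": holidays,
        "presentations": presentations,
        "calendar": calendar,
        "truth": truth,
    }


def generate_study(
    config: SyntheticConfig, outdir: str | pathlib.Path, *, overwrite: bool = False
) -> dict[str, pathlib.Path]:
    """Write the four study input files plus the truth log.

    Creates temperature.csv, pm25.csv, holidays.txt, presentations.csv and
    truth.json under ``outdir``; refuses to clobber existing files unless
    ``overwrite`` is set.  Returns the paths keyed by input name.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "temperature": outdir / "temperature.csv",
        "pm25": outdir / "pm25.csv",
        "holidays": outdir / "holidays.txt",
        "presentations": outdir / "presentations.csv",
        "truth": outdir / "truth.json",
    }
    if not overwrite:
        existing = [str(p) for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(f"refusing to overwrite: {existing}")
    study = simulate_study(config)
    temps = study["temperature"].copy()
    temps["date"] = temps["date"].dt.date
    temps.rename(columns={"tmax": "tmax_c", "tmin": "tmin_c"}).to_csv(
        paths["temperature"], index=False
    )
    pm = study["pm25"][["station_id", "date", "pm25"]].copy()
    pm["date"] = pm["date"].dt.date
    pm.to_csv(paths["pm25"], index=False)
    paths["holidays"].write_text("\n".join(str(d) for d in study["holidays"]) + "\n")
    pres = study["presentations"].copy()
    pres["date"] = pres["date"].dt.date
    pres.to_csv(paths["presentations"], index=False)
    paths["truth"].write_text(json.dumps(study["truth"], indent=2, default=str))
    return paths
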