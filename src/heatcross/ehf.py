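"""Excess Heat Factor (EHF) heatwave identification.

The EHF is a relative heat index (units degC^2) combining two excess-heat
indices computed from the daily mean temperature ``tmean = (tmax + tmin) / 2``:

* the *significance* index ``EHI_sig(i) = T3(i) - T95``, the short-term
  (3-day mean) departure from a climatological 95th percentile of ``tmean``;
* the *acclimatization* index ``EHI_accl(i) = T3(i) - T30(i)``, the same
  3-day mean relative to the mean of the 30 days immediately preceding it.

``EHF(i) = EHI_sig(i) * max(1, EHI_accl(i))``

so a heatwave day requires heat that is both climatologically unusual and in
excess of what the population has recently acclimatized to.  Severity classes
are set against the 85th percentile of the strictly positive climatological
EHF values (``ehf85``): low intensity below ``ehf85``, severe at or above it,
and extreme at or above ``3 * ehf85``.

By default the 3-day window ENDS on the indexed day (days ``i-2 .. i``) so a
day's exposure reflects heat already experienced -- the natural orientation
for retrospective health attribution.  The forward-looking orientation used
in heatwave forecasting (days ``i .. i+2``) is available via
``orientation="forward"``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

__all__ = [
    "SEVERITY_LEVELS",
    "EhfClimatology",
    "validate_temperature_series",
    "daily_mean_series",
    "fit_climatology",
    "compute_ehf_series",
    "classify_severity",
    "heatwave_calendar",
    "severity_day_counts",
]

#: Ordered severity classes; "none" covers EHF <= 0 and the warm-up window.
SEVERITY_LEVELS = ("none", "low", "severe", "extreme")

#: Days at the start of a series with insufficient history for the backward
#: 30-day acclimatization window (30 + 3-day window offset of 2).
WARMUP_DAYS = 32


@dataclasses.dataclass(frozen=True)
class EhfClimatology:
    """Climatological thresholds for one region.

    Attributes
    ----------
    region_id : str
        Region the thresholds belong to.
    t95 : float
        95th percentile (configurable) of daily mean temperature over the
        reference period, degC.
    ehf85 : float
        85th percentile (configurable) of the strictly positive EHF values
        over the reference period, degC^2.  This is the severe-heatwave
        threshold; the extreme threshold is exactly ``3 * ehf85``.
    reference_start, reference_end : datetime.date
        Inclusive reference window the percentiles were fitted on.
    """

    region_id: str
    t95: float
    ehf85: float
    reference_start: dt.date
    reference_end: dt.date

    def __post_init__(self) -> None:
        if not self.ehf85 > 0:
            raise ValueError(f"ehf85 must be positive, got {self.ehf85}")

    @property
    def extreme_threshold(self) -> float:
        return 3.0 * self.ehf85


def validate_temperature_series(temps: pd.DataFrame) -> pd.DataFrame:
    """Validate a daily temperature frame (region_id, date, tmax, tmin).

    Enforces one record per calendar day with no gaps, per region, and
    ``tmax >= tmin`` everywhere.  Returns the frame sorted by (region, date)
    with ``date`` as ``datetime64``.
    """
    required = {"region_id", "date", "tmax", "tmin"}
    missing = required - set(temps.columns)
    if missing:
        raise ValueError(f"temperature series missing columns: {sorted(missing)}")
    out = temps.copy()
    out["date"] = pd.to_datetime(out["date"])
    out = out.sort_values(["region_id", "date"]).reset_index(drop=True)
    for col in ("tmax", "tmin"):
        bad = out.loc[out[col].isna(), "date"]
        if len(bad):
            raise ValueError(f"missing {col} on {bad.dt.date.iloc[0]}")
    if (out["tmax"] < out["tmin"]).any():
        bad = out.loc[out["tmax"] < out["tmin"], "date"].dt.date.iloc[0]
        raise ValueError(f"tmax < tmin on {bad}")
    for region, grp in out.groupby("region_id", sort=False):
        d = grp["date"]
        if d.duplicated().any():
            raise ValueError(f"duplicate dates for region {region!r}")
        gaps = d.diff().dropna()
        if (gaps != pd.Timedelta(days=1)).any():
            where = d[gaps.index[gaps != pd.Timedelta(days=1)][0]].date()
            raise ValueError(f"date gap before {where} in region {region!r}")
    return out


def daily_mean_series(temps: pd.DataFrame) -> pd.DataFrame:
    """Daily mean temperature ``(tmax + tmin) / 2`` per region-day.

    Returns a frame (region_id, date, tmean) aligned to the input dates.
    """
    out = validate_temperature_series(temps)
    out["tmean"] = (out["tmax"] + out["tmin"]) / 2.0
    return out[["region_id", "date", "tmean"]]


def _rolling_components(
    tmean: np.ndarray, orientation: str
) -> tuple[np.ndarray, np.ndarray]:
    """3-day and 30-day window means (t3, t30) with NaN where undefined."""
    s = pd.Series(tmean)
    if orientation == "backward":
        t3 = s.rolling(3).mean()
        # 30 days immediately preceding the 3-day window: i-32 .. i-3
        t30 = s.rolling(30).mean().shift(3)
    elif orientation == "forward":
        t3 = s.rolling(3).mean().shift(-2)
        # 30 days preceding the indexed day: i-30 .. i-1
        t30 = s.rolling(30).mean().shift(1)
    else:
        raise ValueError(f"orientation must be 'backward' or 'forward', got {orientation!r}")
    return t3.to_numpy(), t30.to_numpy()


def _ehf_from_components(
    ehi_sig: np.ndarray, ehi_accl: np.ndarray
) -> np.ndarray:
    return ehi_sig * np.maximum(1.0, ehi_accl)


def fit_climatology(
    temps: pd.DataFrame,
    reference_start: dt.date | str | None = None,
    reference_end: dt.date | str | None = None,
    *,
    tmean_percentile: float = 95.0,
    ehf_percentile: float = 85.0,
    orientation: str = "backward",
    min_reference_days: int = 730,
) -> dict[str, EhfClimatology]:
    """Fit per-region climatological thresholds (two-pass procedure).

    Pass 1 takes ``t95`` as the empirical ``tmean_percentile`` percentile of
    daily mean temperature over the reference window.  Pass 2 computes the
    EHF series over the same window with that ``t95`` and takes ``ehf85`` as
    the ``ehf_percentile`` percentile of the strictly positive EHF values.
    Percentiles use linear interpolation between order statistics throughout.

    The reference window defaults to the full extent of the series and must
    span at least ``min_reference_days`` (two years) of complete daily data.

    Returns a dict mapping region_id to :class:`EhfClimatology`.

    Raises
    ------
    ValueError
        If the reference window is too short, lies outside the series, or
        contains no positive EHF values ("no heat events in reference period").
    """
    tm = daily_mean_series(temps)
    out: dict[str, EhfClimatology] = {}
    for region, grp in tm.groupby("region_id", sort=False):
        dates = grp["date"]
        start = pd.Timestamp(reference_start) if reference_start is not None else dates.iloc[0]
        end = pd.Timestamp(reference_end) if reference_end is not None else dates.iloc[-1]
        if start < dates.iloc[0] or end > dates.iloc[-1]:
            raise ValueError(
                f"reference window [{start.date()}, {end.date()}] not contained "
                f"in series for region {region!r}"
            )
        mask = (dates >= start) & (dates <= end)
        ref = grp.loc[mask]
        if len(ref) < min_reference_days:
            raise ValueError(
                f"reference window has {len(ref)} days; "
                f"at least {min_reference_days} required"
            )
        tmean = ref["tmean"].to_numpy()
        t95 = float(np.percentile(tmean, tmean_percentile))
        t3, t30 = _rolling_components(tmean, orientation)
        ehf = _ehf_from_components(t3 - t95, t3 - t30)
        positive = ehf[np.isfinite(ehf) & (ehf > 0)]
        if positive.size == 0:
            raise ValueError(f"no heat events in reference period for region {region!r}")
        ehf85 = float(np.percentile(positive, ehf_percentile))
        out[region] = EhfClimatology(
            region_id=region,
            t95=t95,
            ehf85=ehf85,
            reference_start=start.date(),
            reference_end=end.date(),
        )
    return out


def compute_ehf_series(
    temps: pd.DataFrame,
    clim: EhfClimatology | dict[str, EhfClimatology],
    *,
    orientation: str = "backward",
) -> pd.DataFrame:
    """Per-day EHF components for one or more regions.

    Returns a frame (region_id, date, tmean, ehi_sig, ehi_accl, ehf,
    severity) with NaN components over the warm-up window (the first 32 days
    under the default backward orientation, where the 30-day acclimatization
    history is incomplete).  ``severity`` is filled by
    :func:`classify_severity`; here it is set to "none" only for undefined
    days and left NA otherwise.
    """
    tm = daily_mean_series(temps)
    clim_map = clim if isinstance(clim, dict) else {clim.region_id: clim}
    frames = []
    for region, grp in tm.groupby("region_id", sort=False):
        if region not in clim_map:
            raise ValueError(f"no climatology for region {region!r}")
        c = clim_map[region]
        if len(grp) < WARMUP_DAYS + 1:
            raise ValueError(
                f"series for region {region!r} has {len(grp)} days; "
                f"at least {WARMUP_DAYS + 1} required"
            )
        g = grp.reset_index(drop=True)
        t3, t30 = _rolling_components(g["tmean"].to_numpy(), orientation)
        g["ehi_sig"] = t3 - c.t95
        g["ehi_accl"] = t3 - t30
        g["ehf"] = _ehf_from_components(g["ehi_sig"].to_numpy(), g["ehi_accl"].to_numpy())
        frames.append(g)
    out = pd.concat(frames, ignore_index=True)
    out["severity"] = pd.array([pd.NA] * len(out), dtype="string")
    out.loc[~np.isfinite(out["ehf"].to_numpy(dtype=float)), "severity"] = "none"
    return out


def classify_severity(
    ehf_series: pd.DataFrame,
    clim: EhfClimatology | dict[str, EhfClimatology],
) -> pd.DataFrame:
    """Assign a severity class to every region-day.

    ``none`` for EHF <= 0 or undefined; ``low`` for 0 < EHF < ehf85;
    ``severe`` for ehf85 <= EHF < 3*ehf85; ``extreme`` for EHF >= 3*ehf85.
    Boundary values belong to the higher class.
    """
    clim_map = clim if isinstance(clim, dict) else {clim.region_id: clim}
    out = ehf_series.copy()
    sev = np.full(len(out), "none", dtype=object)
    for region, grp in out.groupby("region_id", sort=False):
        if region not in clim_map:
            raise ValueError(f"no climatology for region {region!r}")
        thr = clim_map[region].ehf85
        ehf = grp["ehf"].to_numpy(dtype=float)
        idx = grp.index.to_numpy()
        defined = np.isfinite(ehf)
        sev[idx[defined & (ehf > 0) & (ehf < thr)]] = "low"
        sev[idx[defined & (ehf >= thr) & (ehf < 3 * thr)]] = "severe"
        sev[idx[defined & (ehf >= 3 * thr)]] = "extreme"
    out["severity"] = pd.Categorical(sev, categories=list(SEVERITY_LEVELS), ordered=True)
    return out


def heatwave_calendar(ehf_series: pd.DataFrame) -> pd.DataFrame:
    """Exposure calendar: one row per region-day with the analysis exposure.

    A day is *exposed* when its severity is severe or extreme (low-intensity
    events are too common and too mild to matter for health attribution, and
    extreme days are rare enough that they are pooled with severe days).
    """
    if ehf_series["severity"].isna().any():
        raise ValueError("severity not classified; run classify_severity first")
    out = ehf_series[["region_id", "date", "severity"]].copy()
    out["exposed"] = out["severity"].isin(["severe", "extreme"]).to_numpy()
    return out


def severity_day_counts(calendar: pd.DataFrame) -> pd.DataFrame:
    """Per-region counts of low / severe / extreme days (summary layout)."""
    rows = []
    for region, grp in calendar.groupby("region_id", sort=False):
        sev = grp["severity"].astype(str)
        rows.append(
            {
                "region_id": region,
                "low_days": int((sev == "low").sum()),
                "severe_days": int((sev == "severe").sum()),
                "extreme_days": int((sev == "extreme").sum()),
            }
        )
    return pd.DataFrame(rows)
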