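"""End-to-end study orchestration.

Runs the full analysis: fit EHF climatology and classify heatwave days,
gap-fill PM2.5 and assemble the exposure table, build one matched
case-crossover dataset per analysis population (whole population, age bands,
gender, SEIFA advantage bands, diagnostic groups), fit the conditional
logistic regression for each, and emit a descriptive summary table plus an
odds-ratio results table.

Populations with too little information to support a conditional fit (fewer
than ``min_informative`` informative strata or ``min_cases`` cases) are
reported as "insufficient data" rather than fitted -- rare conditions in a
small population genuinely cannot be estimated this way.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Callable

import numpy as np
import pandas as pd

from . import casecrossover as cc
from . import clogit
from . import ehf as ehf_mod
from . import exposure as exp_mod

__all__ = [
    "StudyConfig",
    "summarize_presentations",
    "summary_from_totals",
    "default_subgroups",
    "run_analysis",
    "results_table",
]


@dataclasses.dataclass
class StudyConfig:
    """Settings for one full analysis run (in-memory inputs)."""

    study_start: str = "2008-01-01"
    study_end: str = "2016-12-31"
    reference_start: str | None = None
    reference_end: str | None = None
    ehf_orientation: str = "backward"
    tmean_percentile: float = 95.0
    ehf_percentile: float = 85.0
    short_gap_rule: str = "pooled"
    adjusters: tuple[str, ...] = ("pm25", "holiday")
    min_informative: int = 2
    min_cases: int = 30
    station_to_region: dict[str, str] | None = None
    include_zero_days: bool = True
    seed: int = 0


def _daily_counts(
    dates: pd.Series, window: pd.DatetimeIndex, include_zero_days: bool
) -> np.ndarray:
    counts = dates.value_counts().reindex(window, fill_value=0).to_numpy()
    if not include_zero_days:
        counts = counts[counts > 0]
        if counts.size == 0:
            counts = np.array([0])
    return counts


def summarize_presentations(
    presentations: pd.DataFrame,
    study_start: str | dt.date,
    study_end: str | dt.date,
    group_filters: list[tuple[str, Callable[[pd.DataFrame], pd.Series]]] | None = None,
    *,
    include_zero_days: bool = True,
) -> pd.DataFrame:
    """Descriptive table: totals, percent of total, and daily-count summaries.

    For each population group: total presentations, percent of the
    whole-population total, and the mean / sd / min / max of daily counts
    over every day of the study window.  Days with zero presentations in a
    group count as zeros by default; ``include_zero_days=False`` restricts
    the daily summaries to days on which the group presented at all (the
    convention that matches printed descriptive tables for rare conditions).
    """
    window = pd.date_range(study_start, study_end, freq="D")
    if len(window) == 0:
        raise ValueError("empty study window")
    pres = presentations.copy()
    pres["date"] = pd.to_datetime(pres["date"])
    if group_filters is None:
        group_filters = default_subgroups()
    grand_total = len(pres)
    rows = []
    for label, filt in [("Whole population", None), *group_filters]:
        sub = pres if filt is None else pres[filt(pres).to_numpy(dtype=bool)]
        counts = _daily_counts(sub["date"], window, include_zero_days)
        total = len(sub)
        rows.append(
            {
                "group": label,
                "total": total,
                "percent": 100.0 * total / grand_total if grand_total else np.nan,
                "mean_daily": float(counts.mean()),
                "sd_daily": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
                "min_daily": int(counts.min()),
                "max_daily": int(counts.max()),
            }
        )
    return pd.DataFrame(rows)


def summary_from_totals(
    totals: dict[str, int], whole_population_total: int, n_days: int
) -> pd.DataFrame:
    """Mean-daily and percent columns implied by group totals alone.

    ``mean_daily = total / n_days`` (every study day counted) and
    ``percent = 100 * total / whole_population_total``, both rounded to one
    decimal as printed in descriptive tables.
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    rows = [
        {
            "group": name,
            "total": total,
            "mean_daily": round(total / n_days, 1),
            "percent": round(100.0 * total / whole_population_total, 1),
        }
        for name, total in totals.items()
    ]
    return pd.DataFrame(rows)


def default_subgroups(
    groups: dict[str, tuple[str, ...]] | None = None,
) -> list[tuple[str, Callable[[pd.DataFrame], pd.Series]]]:
    """The standard analysis populations: age bands, gender, SEIFA, diagnoses.

    Age bands follow the study convention: 0-5 and 0-15 overlap by design
    and are analysed separately; "over 65" is strictly greater than 65.
    """
    groups = cc.DIAGNOSTIC_GROUPS if groups is None else groups

    def seifa_band(df: pd.DataFrame) -> pd.Series:
        return pd.to_numeric(df["seifa_decile"], errors="coerce").map(cc.condense_seifa)

    subgroups: list[tuple[str, Callable]] = [
        ("Age <=5", lambda df: df["age"] <= 5),
        ("Age <=15", lambda df: df["age"] <= 15),
        ("Age 16-65", lambda df: (df["age"] > 15) & (df["age"] <= 65)),
        ("Age >65", lambda df: df["age"] > 65),
        ("Male", lambda df: df["gender"] == "male"),
        ("Female", lambda df: df["gender"] == "female"),
        ("SEIFA low", lambda df: seifa_band(df) == "low"),
        ("SEIFA middle", lambda df: seifa_band(df) == "middle"),
        ("SEIFA high", lambda df: seifa_band(df) == "high"),
    ]
    for name in groups:
        flags_for = name  # bind per-iteration

        def filt(df: pd.DataFrame, _name=flags_for) -> pd.Series:
            return cc.diagnostic_group_flags(df["icd10"], {_name: groups[_name]})[_name]

        subgroups.append((name, filt))
    return subgroups


def run_analysis(
    temps: pd.DataFrame,
    pm25: pd.DataFrame,
    holidays: list,
    presentations: pd.DataFrame,
    config: StudyConfig | None = None,
) -> dict:
    """Execute the full pipeline and return the results bundle.

    Returns a dict with ``climatology``, ``calendar`` (per-region severity
    and exposure), ``severity_counts``, ``exposure`` (covariate table),
    ``summary`` (descriptive table), ``fits`` (label -> FitResult or an
    "insufficient data" marker) and ``results`` (the formatted OR table).
    """
    cfg = config or StudyConfig()
    try:
        clim = ehf_mod.fit_climatology(
            temps,
            cfg.reference_start,
            cfg.reference_end,
            tmean_percentile=cfg.tmean_percentile,
            ehf_percentile=cfg.ehf_percentile,
            orientation=cfg.ehf_orientation,
        )
        series = ehf_mod.classify_severity(
            ehf_mod.compute_ehf_series(temps, clim, orientation=cfg.ehf_orientation), clim
        )
        calendar = ehf_mod.heatwave_calendar(series)
    except ValueError as err:
        raise ValueError(f"[ehf] {err}") from err
    try:
        pm = pm25
        if cfg.station_to_region is not None:
            pm = exp_mod.map_stations_to_regions(pm, cfg.station_to_region)
        if "region_id" not in pm.columns:
            pm = pm.assign(region_id=pm["station_id"])
        pm = exp_mod.fill_pm25_gaps(pm, short_gap_rule=cfg.short_gap_rule)
        exposure = exp_mod.assemble_exposure_table(
            calendar, pm, holidays, cfg.study_start, cfg.study_end
        )
    except ValueError as err:
        raise ValueError(f"[exposure_prep] {err}") from err

    subgroups = default_subgroups()
    summary = summarize_presentations(
        presentations,
        cfg.study_start,
        cfg.study_end,
        subgroups,
        include_zero_days=cfg.include_zero_days,
    )
    fits: dict[str, object] = {}
    for label, filt in [("Whole population", None), *subgroups]:
        try:
            dataset = cc.build_analysis_dataset(presentations, exposure, filt, label)
        except ValueError as err:
            raise ValueError(f"[casecrossover] {err}") from err
        if dataset.n_strata < cfg.min_cases or dataset.n_informative < cfg.min_informative:
            fits[label] = {
                "status": "insufficient data",
                "n_cases": dataset.n_strata,
                "n_informative": dataset.n_informative,
            }
            continue
        covariates = ("exposed", *cfg.adjusters)
        try:
            fits[label] = clogit.fit_conditional_logit(dataset.data, covariates)
        except ValueError as err:
            fits[label] = {
                "status": f"fit failed: {err}",
                "n_cases": dataset.n_strata,
                "n_informative": dataset.n_informative,
            }
    return {
        "climatology": clim,
        "calendar": calendar,
        "severity_counts": ehf_mod.severity_day_counts(calendar),
        "exposure": exposure,
        "summary": summary,
        "fits": fits,
        "results": results_table(fits),
        "metadata": {
            "config": dataclasses.asdict(cfg),
            "n_presentations": int(len(presentations)),
        },
    }


def results_table(fits: dict[str, object]) -> pd.DataFrame:
    """Odds-ratio table: one row per analysis population.

    ORs and CI bounds print to two decimals; a ``*`` marks Wald p < 0.05.
    Non-converged or skipped analyses keep their row with a status note and
    no OR.
    """
    rows = []
    for label, fit in fits.items():
        if isinstance(fit, dict):
            rows.append(
                {
                    "group": label,
                    "n_cases": fit.get("n_cases"),
                    "n_informative": fit.get("n_informative"),
                    "or": "",
                    "ci95": "",
                    "p_wald": "",
                    "significant": "",
                    "status": fit["status"],
                }
            )
            continue
        if not fit.converged:
            rows.append(
                {
                    "group": label,
                    "n_cases": fit.n_strata,
                    "n_informative": fit.n_informative,
                    "or": "",
                    "ci95": "",
                    "p_wald": "",
                    "significant": "",
                    "status": f"not converged: {fit.message}",
                }
            )
            continue
        lo, hi = fit.ci95
        rows.append(
            {
                "group": label,
                "n_cases": fit.n_strata,
                "n_informative": fit.n_informative,
                "or": f"{fit.or_:.2f}",
                "ci95": f"{lo:.2f}-{hi:.2f}",
                "p_wald": f"{fit.p_wald:.4f}",
                "significant": "*" if fit.p_wald < 0.05 else "",
                "status": "ok",
            }
        )
    return pd.DataFrame(rows)
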