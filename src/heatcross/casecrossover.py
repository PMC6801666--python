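"""Time-stratified case-crossover dataset construction.

Each emergency-department presentation is the unit of observation and acts as
its own control: its exposure on the presentation day (the *case* day) is
compared with its exposure on *referent* days -- every other day in the same
calendar month and year that falls on the same day of the week.  Every month
contains four or five of each weekday, so each matched stratum has one case
day and three or four referents.  Day-of-week patterns and slow seasonal
trends cancel by design; stable personal characteristics cancel because case
and referents belong to the same person.

Also here: the ICD-10 diagnostic grouping used for subgroup analyses, and the
SEIFA (Socio-Economic Indexes for Areas) decile condensation into low (1-3),
middle (4-7) and high (8-10) relative advantage bands.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import io
from collections.abc import Callable

import numpy as np
import pandas as pd

__all__ = [
    "DIAGNOSTIC_GROUPS",
    "load_presentations",
    "map_diagnostic_groups",
    "diagnostic_group_flags",
    "select_referents",
    "condense_seifa",
    "build_analysis_dataset",
    "AnalysisDataset",
]

#: Diagnostic group -> ICD-10 code ranges (3-character categories, inclusive).
#: A range may be a single category ("I48") or a span ("J45-J46"); groups may
#: overlap (Dementia F00-F03 sits inside Organic mental F00-F09, which sits
#: inside All mental F00-F99).
DIAGNOSTIC_GROUPS: dict[str, tuple[str, ...]] = {
    "All respiratory": ("J00-J99",),
    "Asthma": ("J45-J46",),
    "COPD": ("J40-J44", "J47", "J67"),
    "Diabetes": ("E10-E11", "E13-E14"),
    "All cardiovascular": ("I00-I99", "G45-G46"),
    "Hypertensive": ("I10-I13",),
    "Ischemic heart disease": ("I20-I25",),
    "Atrial fibrillation": ("I48",),
    "Cardiac failure": ("I50",),
    "All mental disorders": ("F00-F99",),
    "Dementia": ("F00-F03",),
    "Neuroses": ("F40-F48",),
    "Psychoses": ("F80-F89",),
    "Organic mental disorders": ("F00-F09",),
    "All renal disorders": ("N00-N39",),
    "Acute renal failure": ("N17",),
    "Renal calculus": ("N20-N21",),
    "Heat and light disorders": ("T67", "X30"),
}

_GENDER_TOKENS = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
}


def _normalize_gender(token: object) -> str:
    if pd.isna(token):
        return "unknown"
    return _GENDER_TOKENS.get(str(token).strip().lower(), "unknown")


def load_presentations(
    source: str | io.TextIOBase, *, sep: str = ","
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Read and validate an ED presentation line list.

    Expects delimited text with columns (presentation_id, date, region_id,
    age, gender, seifa_decile, icd10).  Malformed rows (unparseable date,
    negative age, decile outside 1-10) are dropped and reported; unknown
    gender tokens and blank SEIFA/ICD-10 fields are retained as
    unknown/missing categories rather than rejected.

    Returns
    -------
    (records, rejects)
        ``records`` is the validated frame; ``rejects`` is a list of
        ``(line_number, reason)`` pairs, line numbers counting the header
        as line 1.
    """
    raw = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    required = ["presentation_id", "date", "region_id", "age", "gender", "seifa_decile", "icd10"]
    missing = set(required) - set(raw.columns)
    if missing:
        raise ValueError(f"presentation file missing columns: {sorted(missing)}")
    rejects: list[tuple[int, str]] = []
    date = pd.to_datetime(raw["date"], errors="coerce", format="mixed")
    age = pd.to_numeric(raw["age"], errors="coerce")
    decile = pd.to_numeric(raw["seifa_decile"].replace("", np.nan), errors="coerce")
    keep = np.ones(len(raw), dtype=bool)
    for i in range(len(raw)):
        line = i + 2  # header is line 1
        if pd.isna(date.iloc[i]):
            rejects.append((line, f"unparseable date {raw['date'].iloc[i]!r}"))
            keep[i] = False
        elif pd.isna(age.iloc[i]) or age.iloc[i] < 0 or age.iloc[i] != int(age.iloc[i]):
            rejects.append((line, f"invalid age {raw['age'].iloc[i]!r}"))
            keep[i] = False
        elif not pd.isna(decile.iloc[i]) and not (1 <= decile.iloc[i] <= 10):
            rejects.append((line, f"seifa_decile outside 1-10: {raw['seifa_decile'].iloc[i]!r}"))
            keep[i] = False
    records = pd.DataFrame(
        {
            "presentation_id": raw["presentation_id"],
            "date": date,
            "region_id": raw["region_id"],
            "age": age,
            "gender": raw["gender"].map(_normalize_gender),
            "seifa_decile": decile,
            "icd10": raw["icd10"].str.strip().str.upper().replace("", pd.NA),
        }
    )[keep].reset_index(drop=True)
    if len(records):
        records["age"] = records["age"].astype(int)
    return records, rejects


def _parse_range(spec: str) -> tuple[str, str]:
    if "-" in spec:
        lo, hi = spec.split("-")
    else:
        lo = hi = spec
    return lo.strip().upper(), hi.strip().upper()


def map_diagnostic_groups(
    icd10: str | None, groups: dict[str, tuple[str, ...]] = DIAGNOSTIC_GROUPS
) -> set[str]:
    """Every diagnostic group whose code ranges contain the given code.

    Membership is decided on the 3-character ICD-10 category: "J45.9"
    belongs to J45-J46 (and to J00-J99).  Unknown or empty codes map to the
    empty set -- such presentations still count in whole-population analyses.
    """
    if icd10 is None or (isinstance(icd10, float) and np.isnan(icd10)) or pd.isna(icd10):
        return set()
    category = str(icd10).strip().upper()[:3]
    if len(category) < 3:
        return set()
    hits = set()
    for name, ranges in groups.items():
        for spec in ranges:
            lo, hi = _parse_range(spec)
            if lo <= category <= hi:
                hits.add(name)
                break
    return hits


def diagnostic_group_flags(
    codes: pd.Series, groups: dict[str, tuple[str, ...]] = DIAGNOSTIC_GROUPS
) -> pd.DataFrame:
    """Vectorized boolean membership matrix (rows align with ``codes``)."""
    cats = codes.astype("string").str.strip().str.upper().str.slice(0, 3)
    valid = cats.notna() & (cats.str.len() == 3)
    cat_arr = cats.fillna("").to_numpy(dtype=object).astype(str)
    out = {}
    for name, ranges in groups.items():
        hit = np.zeros(len(codes), dtype=bool)
        for spec in ranges:
            lo, hi = _parse_range(spec)
            hit |= (cat_arr >= lo) & (cat_arr <= hi)
        out[name] = hit & valid.to_numpy()
    return pd.DataFrame(out, index=codes.index)


def select_referents(case_date: dt.date | str | pd.Timestamp) -> list[dt.date]:
    """All other same-weekday days in the case day's calendar month and year.

    Every month has four or five of each weekday, so the result has three or
    four dates, ascending, never including the case day itself.
    """
    d = pd.Timestamp(case_date)
    first = d.replace(day=1)
    # first occurrence of the case weekday in the month
    offset = (d.weekday() - first.weekday()) % 7
    days = []
    day = first + pd.Timedelta(days=offset)
    while day.month == d.month:
        if day != d:
            days.append(day.date())
        day += pd.Timedelta(days=7)
    return days


def condense_seifa(decile: float | int | None) -> str:
    """SEIFA decile -> relative-advantage band: 1-3 low, 4-7 middle, 8-10 high."""
    if decile is None or pd.isna(decile):
        return "unknown"
    d = int(decile)
    if not 1 <= d <= 10:
        return "unknown"
    if d <= 3:
        return "low"
    if d <= 7:
        return "middle"
    return "high"


@dataclasses.dataclass
class AnalysisDataset:
    """Long-format matched dataset: the substrate of the conditional likelihood.

    ``data`` has one row per stratum-day with columns (stratum_id, region_id,
    date, is_case, exposed, pm25, holiday); each stratum is one presentation
    (its case day plus its time-stratified referents).
    """

    data: pd.DataFrame
    label: str
    n_strata: int
    n_informative: int

    @property
    def n_cases(self) -> int:
        return self.n_strata


def _referent_map(case_dates: pd.Series) -> pd.DataFrame:
    """(case_date, date) member pairs, including the case date itself."""
    rows = []
    for d in pd.to_datetime(case_dates.unique()):
        members = [d] + [pd.Timestamp(r) for r in select_referents(d)]
        rows.extend((d, m) for m in sorted(members))
    return pd.DataFrame(rows, columns=["case_date", "date"])


def build_analysis_dataset(
    presentations: pd.DataFrame,
    exposure: pd.DataFrame,
    subgroup_filter: Callable[[pd.DataFrame], pd.Series] | None = None,
    label: str = "whole population",
) -> AnalysisDataset:
    """Matched case-crossover dataset for one analysis population.

    Parameters
    ----------
    presentations : DataFrame
        Validated line list (see :func:`load_presentations`).
    exposure : DataFrame
        Per-region-day covariates (see
        :func:`heatcross.exposure.assemble_exposure_table`); must cover every
        case and referent day.
    subgroup_filter : callable, optional
        Boolean mask over the presentation frame selecting the subgroup
        (e.g. ``lambda df: df["age"] <= 5``).  None keeps every record.

    Returns an :class:`AnalysisDataset`; ``n_informative`` counts strata in
    which the heatwave exposure varies across member days (only these move
    the exposure estimate).
    """
    pres = presentations.copy()
    pres["date"] = pd.to_datetime(pres["date"])
    if subgroup_filter is not None:
        pres = pres[subgroup_filter(pres).to_numpy(dtype=bool)]
    pres = pres.reset_index(drop=True)
    if pres.empty:
        return AnalysisDataset(
            data=pd.DataFrame(
                columns=["stratum_id", "region_id", "date", "is_case", "exposed", "pm25", "holiday"]
            ),
            label=label,
            n_strata=0,
            n_informative=0,
        )
    refmap = _referent_map(pres["date"])
    members = pres[["presentation_id", "region_id", "date"]].rename(
        columns={"date": "case_date"}
    ).merge(refmap, on="case_date", how="left")
    members["is_case"] = (members["date"] == members["case_date"]).astype(int)

    exp = exposure.copy()
    exp["date"] = pd.to_datetime(exp["date"])
    merged = members.merge(exp, on=["region_id", "date"], how="left")
    if merged["exposed"].isna().any():
        missing = merged.loc[merged["exposed"].isna(), ["region_id", "date"]].drop_duplicates()
        first = missing.iloc[0]
        raise ValueError(
            f"exposure table missing {len(missing)} member days "
            f"(first: region {first['region_id']!r} on {first['date'].date()})"
        )
    data = merged.rename(columns={"presentation_id": "stratum_id"})[
        ["stratum_id", "region_id", "date", "is_case", "exposed", "pm25", "holiday"]
    ].copy()
    data["exposed"] = data["exposed"].astype(int)
    data["holiday"] = data["holiday"].astype(int)
    informative = int(
        (data.groupby("stratum_id", sort=False)["exposed"].nunique() > 1).sum()
    )
    return AnalysisDataset(
        data=data,
        label=label,
        n_strata=int(pres["presentation_id"].nunique()),
        n_informative=informative,
    )
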