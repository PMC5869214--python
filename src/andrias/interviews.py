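"""Interview-survey processing: sighting-date normalization, county
summaries, descriptive statistics and the design-level contingency test.

Respondents report the timing of their last giant-salamander sighting in
heterogeneous formats (a calendar year, "N years ago", a decade, or their
own age at the sighting). All are normalised to whole years before the
interview so counties surveyed in different years are comparable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SightingDateError",
    "normalize_sighting_date",
    "normalize_records",
    "summarize_counties",
    "contingency_chi2",
    "dataset_descriptives",
]

logger = logging.getLogger(__name__)

DATE_FORMATS = ("calendar_year", "years_ago", "decade", "age_at_sighting")


class SightingDateError(ValueError):
    """A last-sighting report that is internally inconsistent (e.g. in the
    future relative to the interview)."""


def _parse_decade(value) -> int:
    """Decade start year from e.g. ``"1980s"``, ``"1980"`` or ``1980``."""
    s = str(value).strip().rstrip("s")
    decade = int(s)
    if decade % 10 != 0:
        raise ValueError(f"{value!r} is not a decade")
    return decade


def normalize_sighting_date(
    fmt: str,
    value,
    interview_year: int,
    respondent_age: float | None = None,
    decade_rule: str = "midpoint",
) -> int | None:
    """Convert one raw last-sighting report to whole years before interview.

    - ``calendar_year``: interview_year - value;
    - ``years_ago``: value as given;
    - ``decade``: interview_year minus the decade midpoint (XXX5) by
      default, or the decade start under ``decade_rule="start"``;
    - ``age_at_sighting``: respondent_age - value (the sighting happened
      when the respondent was ``value`` years old).

    A report placing the sighting after the interview raises
    :class:`SightingDateError`; an unparseable report returns ``None`` with
    a logged warning.
    """
    if not (1900 <= interview_year <= 2100):
        raise ValueError(f"implausible interview year {interview_year}")
    if fmt not in DATE_FORMATS:
        logger.warning("unparseable sighting-date format %r", fmt)
        return None
    if fmt == "age_at_sighting" and (respondent_age is None or respondent_age < 0):
        raise ValueError("age_at_sighting format requires a nonnegative respondent age")
    try:
        if fmt == "calendar_year":
            years = interview_year - int(value)
        elif fmt == "years_ago":
            years = int(value)
        elif fmt == "decade":
            decade = _parse_decade(value)
            midpoint = decade + (5 if decade_rule == "midpoint" else 0)
            years = interview_year - midpoint
        else:  # age_at_sighting
            years = int(round(respondent_age - float(value)))
    except (TypeError, ValueError) as exc:
        logger.warning("unparseable sighting-date value %r (%s): %s", value, fmt, exc)
        return None
    if years < 0:
        raise SightingDateError(
            f"sighting dated {years} years before interview (in the future)"
        )
    return years


def normalize_records(records: pd.DataFrame, decade_rule: str = "midpoint") -> pd.DataFrame:
    """Add ``years_before_interview`` to an interview table.

    Expects columns ``reported_sighting``, ``raw_format``, ``raw_value``,
    ``interview_year`` and ``age``. Future-dated reports are flagged in
    ``excluded_future`` rather than raised, and their count is logged;
    unparseable reports get missing ``years_before_interview``.
    """
    out = records.copy()
    years = np.full(len(out), np.nan)
    excluded = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        if not row.reported_sighting or pd.isna(row.raw_format):
            continue
        try:
            y = normalize_sighting_date(
                row.raw_format, row.raw_value, int(row.interview_year),
                respondent_age=row.age, decade_rule=decade_rule,
            )
        except SightingDateError:
            excluded[i] = True
            continue
        if y is not None:
            years[i] = y
    out["years_before_interview"] = years
    out["excluded_future"] = excluded
    n_excl = int(excluded.sum())
    if n_excl:
        logger.warning("excluded %d future-dated sighting reports", n_excl)
    return out


def summarize_counties(
    records: pd.DataFrame, zero_mean_for_undated: bool = True
) -> pd.DataFrame:
    """Collapse respondent records to one row per county.

    Per county: number of respondents, number reporting a sighting, the
    proportion reporting, and the minimum (most recent) and mean years
    since reported sightings among dated reports. Counties with no dated
    reports get missing recency; under ``zero_mean_for_undated`` (default)
    their ``mean_years_ago`` is set to 0 so the zero-containing response
    required by the Tweedie model is produced.
    """
    if records.empty:
        return pd.DataFrame(
            columns=[
                "county_id", "province", "selection_method", "n_respondents",
                "n_reported", "proportion_reported", "min_years_ago", "mean_years_ago",
            ]
        )
    grp = records.groupby("county_id", sort=True)
    rows = []
    for county, sub in grp:
        dated = sub["years_before_interview"].dropna() if "years_before_interview" in sub else pd.Series(dtype=float)
        n = len(sub)
        n_rep = int(sub["reported_sighting"].sum())
        min_y = float(dated.min()) if len(dated) else np.nan
        mean_y = float(dated.mean()) if len(dated) else (0.0 if zero_mean_for_undated else np.nan)
        rows.append(
            {
                "county_id": county,
                "province": sub["province"].iloc[0],
                "selection_method": int(sub["selection_method"].iloc[0]),
                "n_respondents": n,
                "n_reported": n_rep,
                "proportion_reported": n_rep / n,
                "min_years_ago": min_y,
                "mean_years_ago": mean_y,
            }
        )
    return pd.DataFrame(rows)


def contingency_chi2(table, correction: bool = True) -> dict:
    """Pearson chi-squared test on a 2x2 table, Yates-corrected by default.

    ``table`` is [[a, b], [c, d]]; returns ``chi2``, ``df`` and ``p``.
    Used for the design-level comparison: counties with at least one
    sighting report vs none, by county-selection method.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table entries must be nonnegative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be positive")
    res = stats.chi2_contingency(arr, correction=correction)
    return {"chi2": float(res.statistic), "df": 1, "p": float(res.pvalue)}


def dataset_descriptives(records: pd.DataFrame) -> dict:
    """Headline descriptive statistics for an interview dataset.

    Counts of respondents, reporters and dated reports (with percentages to
    1 dp), interviews-per-county summary, age summary, and sex proportions.
    """
    n = len(records)
    n_rep = int(records["reported_sighting"].sum()) if n else 0
    dated = records["years_before_interview"].notna() if "years_before_interview" in records else pd.Series(False, index=records.index)
    n_dated = int(dated.sum())
    per_county = records.groupby("county_id").size() if n else pd.Series(dtype=int)
    out = {
        "n_respondents": n,
        "n_counties": int(records["county_id"].nunique()) if n else 0,
        "n_reported": n_rep,
        "pct_reported": round(100.0 * n_rep / n, 1) if n else np.nan,
        "n_dated": n_dated,
        "pct_dated": round(100.0 * n_dated / n, 1) if n else np.nan,
        "interviews_per_county": {
            "mean": float(per_county.mean()) if n else np.nan,
            "min": int(per_county.min()) if n else 0,
            "max": int(per_county.max()) if n else 0,
            "sd": float(per_county.std(ddof=1)) if len(per_county) > 1 else np.nan,
        },
    }
    if "age" in records and n:
        out["age"] = {
            "mean": float(records["age"].mean()),
            "sd": float(records["age"].std(ddof=1)),
            "min": float(records["age"].min()),
            "max": float(records["age"].max()),
        }
    if "sex" in records and n:
        out["sex_proportions"] = (
            records["sex"].value_counts(normalize=True).round(4).to_dict()
        )
    return out
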