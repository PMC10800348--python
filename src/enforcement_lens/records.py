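"""Ingest and aggregate enforcement and prosecution tables.

The enforcement table holds one row per sanction event — infraction notice
(carrying a prospective fine), land-use embargo, or equipment
confiscation/destruction — with a date, a state code, a theme (``flora`` for
crimes against native vegetation, ``other`` otherwise), an optional planar
location, and a process key shared by sanctions of the same case.  Ingest
deduplicates and applies the study filters: keep the nine Legal Amazon
states, keep only flora-theme infraction notices (embargoes and
confiscations are retained regardless of theme, since sanction exports
carry no key separating deforestation from other flora crimes), keep the
study window.  Downstream helpers build the annual indicator series and the
period summaries (totals, percent changes, paid-fine ratio, embargo
cross-referencing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "LEGAL_AMAZON_STATES",
    "ingest_records",
    "annual_indicators",
    "percent_change",
    "round_percent",
    "period_aggregate",
    "paid_fine_ratio",
    "cross_reference_embargoes",
    "InputError",
]

LEGAL_AMAZON_STATES = ("AC", "AP", "AM", "MA", "MT", "PA", "RO", "RR", "TO")

REQUIRED_COLUMNS = ("record_id", "process_id", "date", "state", "theme",
                    "sanction_type", "fine_value_brl")

_STAGE_ORDER = ["filed", "conciliation", "judged_first", "judged_second", "suspended", "paid"]


class InputError(ValueError):
    """A malformed input table."""


@dataclass(frozen=True)
class FilterConfig:
    legal_amazon_states: tuple[str, ...] = LEGAL_AMAZON_STATES
    flora_only: bool = True
    study_window: tuple[int, int] = (2000, 2020)

    def __post_init__(self) -> None:
        if not self.legal_amazon_states:
            raise ValueError("state set must be non-empty")


def ingest_records(raw: pd.DataFrame, filters: FilterConfig) -> tuple[pd.DataFrame, dict]:
    """Clean and filter a raw sanction export.

    Returns the retained records (dates parsed to Timestamps) and a report
    counting rows dropped per reason: ``duplicates`` (all-fields duplicates
    plus repeated record_ids), ``bad_date``, ``out_of_window``,
    ``out_of_region``, ``non_flora`` (notices only, when ``flora_only``).
    """
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise InputError(f"missing required column {col!r}")
    report = {"duplicates": 0, "bad_date": 0, "out_of_window": 0,
              "out_of_region": 0, "non_flora": 0}
    df = raw.copy()

    n0 = len(df)
    df = df.drop_duplicates()
    df = df.drop_duplicates(subset="record_id", keep="first")
    report["duplicates"] = n0 - len(df)

    dates = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    report["bad_date"] = int(dates.isna().sum())
    df = df[dates.notna()].assign(date=dates[dates.notna()])

    y0, y1 = filters.study_window
    years = df["date"].dt.year
    in_window = (years >= y0) & (years <= y1)
    report["out_of_window"] = int((~in_window).sum())
    df = df[in_window]

    in_region = df["state"].isin(filters.legal_amazon_states)
    report["out_of_region"] = int((~in_region).sum())
    df = df[in_region]

    if filters.flora_only:
        drop = (df["sanction_type"] == "infraction_notice") & (df["theme"] != "flora")
        report["non_flora"] = int(drop.sum())
        df = df[~drop]

    return df.reset_index(drop=True), report


def annual_indicators(
    records: pd.DataFrame,
    prosecutions: pd.DataFrame | None = None,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-year counts, fine totals, geolocation share and paid-fine counts.

    ``fines_mean_brl`` averages over notices with a nonzero fine so that
    total = mean x count-of-nonzero-fines.  ``geolocated_share`` is NaN in
    years without notices.  ``paid_fines_count`` counts prosecution records
    reaching the paid stage in that calendar year.
    """
    years_col = pd.to_datetime(records["date"]).dt.year if len(records) else pd.Series(dtype=int)
    if window is None:
        if len(records) == 0:
            raise ValueError("cannot infer window from an empty table")
        window = (int(years_col.min()), int(years_col.max()))
    years = range(window[0], window[1] + 1)
    out = []
    for y in years:
        sub = records[years_col == y] if len(records) else records
        notices = sub[sub["sanction_type"] == "infraction_notice"] if len(sub) else sub
        n_not = len(notices)
        fines = notices["fine_value_brl"] if n_not else pd.Series(dtype=float)
        nonzero = fines[fines > 0]
        geoloc = (
            float(notices["x"].notna().sum()) / n_not
            if n_not and "x" in notices.columns else (np.nan if n_not == 0 else 0.0)
        )
        paid = 0
        if prosecutions is not None and len(prosecutions):
            sd = pd.to_datetime(prosecutions["stage_date"]).dt.year
            paid = int(((prosecutions["stage"] == "paid") & (sd == y)).sum())
        out.append(
            {
                "year": y,
                "notices_count": n_not,
                "embargoes_count": int((sub["sanction_type"] == "embargo").sum()) if len(sub) else 0,
                "confiscations_count": int((sub["sanction_type"] == "confiscation_destruction").sum()) if len(sub) else 0,
                "fines_total_brl": float(fines.sum()) if n_not else 0.0,
                "fines_mean_brl": float(nonzero.mean()) if len(nonzero) else np.nan,
                "geolocated_share": geoloc,
                "paid_fines_count": paid,
            }
        )
    return pd.DataFrame(out).set_index("year")


def percent_change(reference: float, comparison: float) -> float:
    """Signed percent change 100 x (comparison - reference) / reference."""
    if reference == 0:
        raise ValueError("percent change undefined for a zero reference")
    return 100.0 * (comparison - reference) / reference


def round_percent(x: float) -> int:
    """Round half away from zero to the nearest integer percent."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


_RATIO_COLUMNS = ("geolocated_share", "fines_mean_brl")


def period_aggregate(indicators: pd.DataFrame, period: tuple[int, int], mode: str = "sum") -> pd.Series:
    """Element-wise sum or annual mean of an indicator table over a period.

    In ``sum`` mode, ratio-like columns (mean fine, geolocation share) are
    recomputed from the summed components rather than summed; in ``mean``
    mode missing ratio values are excluded.
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    y0, y1 = period
    if y1 < y0:
        raise ValueError("empty period")
    sub = indicators.loc[(indicators.index >= y0) & (indicators.index <= y1)]
    if sub.empty:
        raise ValueError(f"period {period} not covered by the series")
    if mode == "mean":
        return sub.mean(skipna=True)
    agg = sub.sum()
    for col in _RATIO_COLUMNS:
        if col not in sub.columns:
            continue
        if col == "fines_mean_brl" and "fines_total_brl" in sub.columns:
            n = (sub["fines_total_brl"] / sub["fines_mean_brl"]).where(sub["fines_mean_brl"] > 0).sum()
            agg[col] = sub["fines_total_brl"].sum() / n if n else np.nan
        elif col == "geolocated_share" and "notices_count" in sub.columns:
            n = sub["notices_count"].sum()
            agg[col] = (sub[col] * sub["notices_count"]).sum() / n if n else np.nan
    return agg


def paid_fine_ratio(prosecutions: pd.DataFrame, cohort: tuple[int, int]) -> float:
    """Share of processes filed in the cohort whose terminal stage is paid.

    Cohorts are defined by filing year; a process appears once with its
    terminal stage (when the table carries a stage log, the most advanced
    stage wins).
    """
    if len(prosecutions) == 0:
        raise ValueError("no filed processes in the cohort")
    df = prosecutions.copy()
    df["filed_year"] = pd.to_datetime(df["filed_date"]).dt.year
    y0, y1 = cohort
    df = df[(df["filed_year"] >= y0) & (df["filed_year"] <= y1)]
    if df.empty:
        raise ValueError("no filed processes in the cohort")
    rank = {s: i for i, s in enumerate(_STAGE_ORDER)}
    terminal = df.assign(_rank=df["stage"].map(rank)).sort_values("_rank").groupby("process_id").last()
    return float((terminal["stage"] == "paid").mean())


def cross_reference_embargoes(embargoes: pd.DataFrame, notices: pd.DataFrame) -> float:
    """Share of embargoes whose process matches a flora-theme notice."""
    if len(embargoes) == 0:
        raise ValueError("share undefined for an empty embargo collection")
    flora_pids = set(notices.loc[notices["theme"] == "flora", "process_id"])
    return float(embargoes["process_id"].isin(flora_pids).mean())
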