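"""Standardized-month axis and four-week exposure aggregation.

Law passage is staggered across states, so calendar time is replaced by a
standardized month (STDM): the whole-calendar-month offset of an event from
its state's law-passage month (0 = passage month, negative = before).
Exposure weeks 1-52 of each academic year are summed into thirteen
four-week blocks; a block is mapped to the STDM of the calendar month
containing its central day.  The academic calendar anchors week 1 at the
first full (Monday-starting) week of August by default — surveillance
reporting weeks have no universal anchor, so it is configurable.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

__all__ = [
    "compute_stdm",
    "academic_week",
    "week_start",
    "aggregate_four_week",
    "build_analysis_table",
]

logger = logging.getLogger(__name__)

ANALYSIS_TABLE_COLUMNS = [
    "state",
    "stdm",
    "classification",
    "event_count",
    "athlete_exposures",
    "rtp_group",
    "breadth_group",
    "education_group",
]


def compute_stdm(injury_date: dt.date, passage_date: dt.date) -> int:
    """Calendar-month difference ``injury - passage`` (day of month ignored).

    0 for an event in the passage month, negative before, positive after.
    """
    if injury_date is None or passage_date is None or pd.isna(injury_date) or pd.isna(passage_date):
        raise ValueError("compute_stdm requires non-null dates (exclude such records first)")
    return (injury_date.year * 12 + injury_date.month) - (
        passage_date.year * 12 + passage_date.month
    )


def _first_monday_of_august(year: int) -> dt.date:
    d = dt.date(year, 8, 1)
    return d + dt.timedelta(days=(7 - d.weekday()) % 7)


def week_start(academic_year: int, week: int, anchor=_first_monday_of_august) -> dt.date:
    """Start date of exposure week ``week`` (1-52) of an academic year."""
    if not 1 <= week <= 52:
        raise ValueError("exposure_week must lie in [1, 52]")
    return anchor(academic_year) + dt.timedelta(weeks=week - 1)


def academic_week(date: dt.date, anchor=_first_monday_of_august) -> tuple[int, int]:
    """Map a calendar date to (academic_year, exposure_week 1-52).

    Days past week 52 (the 1-2 leftover days before the next anchor) fold
    into week 52 so every date lands inside a year's 52-week grid.
    """
    ay = date.year if date >= anchor(date.year) else date.year - 1
    week = (date - anchor(ay)).days // 7 + 1
    return ay, min(week, 52)


def _block_of_week(week: int) -> int:
    return (week - 1) // 4 + 1  # weeks 1-4 -> block 1, ..., 49-52 -> block 13


def _block_central_date(academic_year: int, block: int, anchor=_first_monday_of_august) -> dt.date:
    """Midpoint day of the 28-day block (day 14 of its span)."""
    start = week_start(academic_year, 4 * block - 3, anchor)
    return start + dt.timedelta(days=13)


def aggregate_four_week(
    exposures: pd.DataFrame,
    events: pd.DataFrame,
    anchor=_first_monday_of_august,
) -> pd.DataFrame:
    """Sum exposures and events into four-week blocks per state and year.

    Returns one row per state x academic_year x block (1-13) with summed
    athlete-exposures, incident and recurrent event counts, and the block's
    central calendar date (used downstream for the STDM assignment).
    Blocks with no exposure rows for their state-year are not fabricated;
    the thirteen blocks of any state-year that reported all 52 weeks are
    always present.
    """
    if not exposures["exposure_week"].between(1, 52).all():
        raise ValueError("exposure_week outside [1, 52]")
    exp = exposures.copy()
    exp["block"] = exp["exposure_week"].map(_block_of_week)
    blocks = (
        exp.groupby(["state", "academic_year", "block"], as_index=False)[
            "athlete_exposures"
        ].sum()
    )

    ev = events.copy()
    if len(ev):
        if ev["injury_date"].isna().any():
            raise ValueError("events entering aggregation must have injury dates")
        ay_week = ev["injury_date"].map(lambda d: academic_week(d, anchor))
        ev["academic_year"] = [t[0] for t in ay_week]
        ev["block"] = [_block_of_week(t[1]) for t in ay_week]
        counts = (
            ev.groupby(["state", "academic_year", "block", "classification"])
            .size()
            .unstack("classification", fill_value=0)
            .reset_index()
        )
    else:
        counts = pd.DataFrame(
            columns=["state", "academic_year", "block", "incident", "recurrent"]
        )
    for col in ("incident", "recurrent"):
        if col not in counts.columns:
            counts[col] = 0

    out = blocks.merge(
        counts[["state", "academic_year", "block", "incident", "recurrent"]],
        on=["state", "academic_year", "block"],
        how="outer",
    )
    out["athlete_exposures"] = out["athlete_exposures"].fillna(0.0)
    for col in ("incident", "recurrent"):
        out[col] = pd.to_numeric(out[col], errors="coerce").fillna(0).astype(int)
    out["central_date"] = [
        _block_central_date(int(ay), int(b), anchor)
        for ay, b in zip(out["academic_year"], out["block"])
    ]
    return out.sort_values(["state", "academic_year", "block"]).reset_index(drop=True)


def build_analysis_table(
    blocks: pd.DataFrame,
    laws: pd.DataFrame,
    classification: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the state x STDM analysis table from four-week blocks.

    Each block is assigned the STDM of the calendar month containing its
    central day, then labelled with its state's law-language groups.  The
    long-format output has one row per state x STDM x classification
    (incident / recurrent).  Cells with zero athlete-exposures and zero
    events are dropped (the log-AE offset is undefined) with the count
    logged and recorded in ``.attrs['n_dropped_zero_ae']``; a zero-AE cell
    with events is a hard error (its rate is undefined).
    """
    missing_states = sorted(set(blocks["state"]) - set(laws["state"]))
    if missing_states:
        raise ValueError(f"states without a law record: {missing_states}")

    passage = laws.set_index("state")["passage_date"]
    work = blocks.copy()
    work["stdm"] = [
        compute_stdm(cd, passage[st]) for st, cd in zip(work["state"], work["central_date"])
    ]
    # Several blocks can share a calendar month (4-week grid vs months).
    agg = (
        work.groupby(["state", "stdm"], as_index=False)
        .agg(
            athlete_exposures=("athlete_exposures", "sum"),
            incident=("incident", "sum"),
            recurrent=("recurrent", "sum"),
        )
    )

    zero_ae = agg["athlete_exposures"] <= 0
    bad = zero_ae & ((agg["incident"] > 0) | (agg["recurrent"] > 0))
    if bad.any():
        rows = agg.loc[bad, ["state", "stdm"]].to_records(index=False).tolist()
        raise ValueError(f"cells with events but zero athlete-exposures: {rows}")
    n_dropped = int(zero_ae.sum())
    if n_dropped:
        logger.info("dropping %d zero-AE, zero-event cells", n_dropped)
    agg = agg.loc[~zero_ae].reset_index(drop=True)

    long = agg.melt(
        id_vars=["state", "stdm", "athlete_exposures"],
        value_vars=["incident", "recurrent"],
        var_name="classification",
        value_name="event_count",
    )
    long = long.merge(classification, on="state", how="left")
    missing_cls = long["rtp_group"].isna()
    if missing_cls.any():
        raise ValueError(
            f"states without classification: {sorted(long.loc[missing_cls, 'state'].unique())}"
        )
    long = (
        long[ANALYSIS_TABLE_COLUMNS]
        .sort_values(["state", "stdm", "classification"])
        .reset_index(drop=True)
    )
    long["event_count"] = long["event_count"].astype(int)
    long["stdm"] = long["stdm"].astype(int)
    long.attrs["n_dropped_zero_ae"] = n_dropped
    return long
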