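"""Synthetic injury-surveillance generator.

Real state-level concussion surveillance with athlete-exposure (AE)
denominators is restricted-access, so every downstream stage here is
exercised on simulated data whose generative law is the analysis model
itself: per state, a law-passage date drawn from the observed 2009-2014
distribution, a normal random intercept, and per standardized month a
log-normal AE denominator and an NB2 event count whose mean follows a
continuous piecewise log-linear trend with two slope breaks anchored to the
passage date.  Events are split incident:recurrent near 91:9.

Two products are offered:

* :func:`simulate_surveillance` — the aggregated state x month analysis
  table plus the matching law table (what the modelling stages consume);
* :func:`simulate_raw_records` — event-level and exposure-week-level
  records with injected per-field missingness, to exercise the ingest
  filters and the temporal-aggregation pipeline.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd

from .alignment import week_start as _week_start
from .config import (
    EDUCATION_BOTH_SHARE,
    PHYSICIANS_ONLY_SHARE,
    RTP_SPECIFIED_SHARE,
    SimulationConfig,
)

__all__ = [
    "US_JURISDICTIONS",
    "simulate_surveillance",
    "simulate_raw_records",
    "piecewise_log_rate",
]

# The 50 states plus the District of Columbia.
US_JURISDICTIONS = (
    "AK AL AR AZ CA CO CT DC DE FL GA HI IA ID IL IN KS KY LA MA MD ME MI MN "
    "MO MS MT NC ND NE NH NJ NM NV NY OH OK OR PA RI SC SD TN TX UT VA VT WA "
    "WI WV WY"
).split()


def piecewise_log_rate(stdm, config: SimulationConfig):
    """Log event rate per AE at standardized month ``stdm`` (no intercepts).

    Continuous in ``stdm``: the truncated-line knot terms change the slope
    at ``tau1`` and ``tau2`` without introducing jumps.
    """
    m = np.asarray(stdm, dtype=float)
    h1 = np.maximum(0.0, m - config.tau1)
    h2 = np.maximum(0.0, m - config.tau2)
    return config.beta0 + config.beta1 * m + config.gamma1 * h1 + config.gamma2 * h2


def _draw_law_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    states = list(US_JURISDICTIONS[: config.n_states])
    years = np.array(sorted(config.passage_year_weights))
    probs = np.array([config.passage_year_weights[y] for y in years], dtype=float)
    probs = probs / probs.sum()
    chosen_years = rng.choice(years, size=len(states), p=probs)
    months = rng.integers(1, 13, size=len(states))
    days = rng.integers(1, 29, size=len(states))
    specified = rng.random(len(states)) < RTP_SPECIFIED_SHARE
    physicians = rng.random(len(states)) < PHYSICIANS_ONLY_SHARE
    edu_both = rng.random(len(states)) < EDUCATION_BOTH_SHARE
    rows = []
    for i, st in enumerate(states):
        rtp = "specified" if specified[i] else "not_specified"
        if rtp == "specified":
            breadth = "physicians_only" if physicians[i] else "multiple"
        else:
            breadth = "not_applicable"
        rows.append(
            {
                "state": st,
                "passage_date": dt.date(int(chosen_years[i]), int(months[i]), int(days[i])),
                "rtp_provider": rtp,
                "provider_breadth": breadth,
                "education": "both" if edu_both[i] else "either",
            }
        )
    return pd.DataFrame(rows)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 draws with mean mu and variance mu + alpha * mu^2 (Poisson if 0)."""
    if alpha == 0.0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    # Gamma-Poisson mixture keeps the NB2 parameterization explicit.
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def simulate_surveillance(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the aggregated analysis table and its law table.

    Returns ``(cells, laws)``.  ``cells`` has one row per state x STDM x
    classification with columns ``state, stdm, classification, event_count,
    athlete_exposures, rtp_group, breadth_group, education_group`` — the
    same dialect the ingest/alignment pipeline produces from raw records.
    Identical configs (including seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    laws = _draw_law_table(config, rng)
    states = laws["state"].to_numpy()
    n = len(states)
    b = rng.normal(0.0, config.sigma_b, size=n) if config.sigma_b > 0 else np.zeros(n)

    stdm = np.array(config.stdm_values, dtype=int)
    m_grid = stdm.astype(float)
    log_rate = piecewise_log_rate(m_grid, config)

    frames = []
    for i, st in enumerate(states):
        ae = rng.lognormal(config.ae_log_mean, config.ae_log_sd, size=len(stdm))
        mu = ae * np.exp(log_rate + b[i])
        total = _nb_counts(rng, mu, config.dispersion)
        recurrent = rng.binomial(total, config.recurrent_fraction)
        incident = total - recurrent
        frames.append(
            pd.DataFrame(
                {
                    "state": st,
                    "stdm": np.tile(stdm, 2),
                    "classification": np.repeat(["incident", "recurrent"], len(stdm)),
                    "event_count": np.concatenate([incident, recurrent]),
                    "athlete_exposures": np.tile(ae, 2),
                }
            )
        )
    cells = pd.concat(frames, ignore_index=True)
    cells = cells.merge(
        laws[["state", "rtp_provider", "provider_breadth", "education"]].rename(
            columns={
                "rtp_provider": "rtp_group",
                "provider_breadth": "breadth_group",
                "education": "education_group",
            }
        ),
        on="state",
        how="left",
    )
    return cells, laws


def _academic_year_of(date: dt.date) -> int:
    """Academic year starting-year convention: Aug-Jul."""
    return date.year if date.month >= 8 else date.year - 1


def simulate_raw_records(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate event-level and exposure-week-level records.

    Returns ``(events, exposures, laws)``.  Events carry calendar injury
    dates (uniform day within their standardized month), an
    incident/recurrent classification, an injury type and, for recurrent
    events, whether the mechanism was sport-related.  Exposure records hold
    weekly AE for weeks 1-52 of each academic year covered by the configured
    STDM span.  Per-field missingness is injected independently at
    ``config.missingness_rates``; bookkeeping columns prefixed ``_injected``
    record exactly which records were corrupted so filter tests have an
    exact oracle.  The injected-exclusion flag ``_injected_any`` marks
    records that any exclusion rule should remove.
    """
    rng = np.random.default_rng(config.seed)
    laws = _draw_law_table(config, rng)
    rates = {f: float(config.missingness_rates.get(f, 0.0)) for f in (
        "injury_date", "state", "classification", "ae_link",
        "injury_type_unknown", "injury_type_other", "nonsport_mechanism",
    )}

    b = (
        rng.normal(0.0, config.sigma_b, size=len(laws))
        if config.sigma_b > 0
        else np.zeros(len(laws))
    )
    lo, hi = config.stdm_range

    event_rows = []
    exposure_rows = []
    for i, law in laws.iterrows():
        st = law["state"]
        passage: dt.date = law["passage_date"]
        base = passage.year * 12 + (passage.month - 1)
        # Academic years whose weeks cover the configured month span; events
        # are then generated for EVERY month those weeks touch (the
        # piecewise trend extends naturally), so the exposure stream never
        # reaches outside the event-generating window.
        years = set()
        for m in (lo, hi):
            total = base + m
            year, month = divmod(total, 12)
            years.add(_academic_year_of(dt.date(year, month + 1, 15)))
        years = range(min(years), max(years) + 1)

        # Weekly AE is the primitive; monthly AE (the count denominator) is
        # the sum of the weeks starting in that calendar month, so the
        # generative rate per AE survives aggregation.
        month_weeks: dict[int, list[tuple[dt.date, float]]] = {}
        for ay in years:
            weekly = rng.lognormal(
                config.ae_log_mean - math.log(52 / 12), config.ae_log_sd, size=52
            )
            for wk in range(1, 53):
                start = _week_start(ay, wk)
                exposure_rows.append(
                    {
                        "state": st,
                        "academic_year": ay,
                        "exposure_week": wk,
                        "athlete_exposures": weekly[wk - 1],
                    }
                )
                key = start.year * 12 + (start.month - 1)
                month_weeks.setdefault(key, []).append((start, weekly[wk - 1]))

        for key in sorted(month_weeks):
            m = key - base  # standardized month of this calendar month
            weeks = month_weeks[key]
            ae_total = sum(ae for _, ae in weeks)
            mu = ae_total * math.exp(
                float(piecewise_log_rate(float(m), config)) + b[i]
            )
            cnt = int(_nb_counts(rng, np.array([mu]), config.dispersion)[0])
            # Events dated inside the contributing exposure weeks,
            # proportionally to each week's AE, so every event has linked
            # exposure data.
            probs = np.array([ae for _, ae in weeks]) / ae_total
            chosen = rng.choice(len(weeks), size=cnt, p=probs)
            offsets = rng.integers(0, 7, size=cnt)
            recur = rng.random(cnt) < config.recurrent_fraction
            for wk_i, off, is_rec in zip(chosen, offsets, recur):
                event_rows.append(
                    {
                        "state": st,
                        "injury_date": weeks[wk_i][0] + dt.timedelta(days=int(off)),
                        "classification": "recurrent" if is_rec else "incident",
                        "injury_type": "concussion",
                        "recurrent_mechanism_sport": bool(is_rec) or None,
                        "ae_linked": True,
                    }
                )

    events = pd.DataFrame(event_rows)
    exposures = pd.DataFrame(exposure_rows)
    if events.empty:
        events = pd.DataFrame(
            columns=[
                "state", "injury_date", "classification", "injury_type",
                "recurrent_mechanism_sport", "ae_linked",
            ]
        )

    events = _inject_missingness(events, rates, rng)
    return events, exposures, laws


def _days_in_month(year: int, month: int) -> int:
    if month == 12:
        return 31
    return (dt.date(year, month + 1, 1) - dt.date(year, month, 1)).days


def _inject_missingness(
    events: pd.DataFrame, rates: dict[str, float], rng: np.random.Generator
) -> pd.DataFrame:
    """Corrupt fields independently per record; flags record ground truth."""
    n = len(events)
    events = events.copy()
    draw = lambda p: rng.random(n) < p  # noqa: E731

    miss_date = draw(rates["injury_date"])
    miss_state = draw(rates["state"])
    miss_class = draw(rates["classification"])
    miss_ae = draw(rates["ae_link"])
    type_unknown = draw(rates["injury_type_unknown"])
    type_other = draw(rates["injury_type_other"]) & ~type_unknown
    nonsport = draw(rates["nonsport_mechanism"]) & (
        events["classification"].to_numpy() == "recurrent"
    )

    if n:
        events.loc[miss_date, "injury_date"] = None
        events.loc[miss_state, "state"] = None
        events.loc[miss_class, "classification"] = "missing"
        events.loc[miss_ae, "ae_linked"] = False
        events.loc[type_unknown, "injury_type"] = "unknown"
        events.loc[type_other, "injury_type"] = "other"
        events.loc[nonsport, "recurrent_mechanism_sport"] = False

    events["_injected_missing_date"] = miss_date
    events["_injected_missing_state"] = miss_state
    events["_injected_missing_classification"] = miss_class
    events["_injected_missing_ae"] = miss_ae
    events["_injected_type_unknown"] = type_unknown
    events["_injected_type_other"] = type_other
    events["_injected_nonsport"] = nonsport
    events["_injected_any"] = (
        miss_date | miss_state | miss_class | miss_ae | type_unknown | type_other | nonsport
    )
    return events
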