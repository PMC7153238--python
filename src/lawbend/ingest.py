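"""Reading surveillance/law CSVs, exclusion filters, law-language groups.

The exclusion rules mirror standard surveillance hygiene for rate analyses:
events unusable for a state x month rate (missing injury date, state,
incident/recurrent classification, or no linked athlete-exposure data) and
events outside the concussion case definition (type unknown/other, or a
recurrent injury from a non-sport mechanism) are removed.  A record is
removed once no matter how many rules it trips, but every applicable
reason is tallied, so reason counts may sum to more than the number of
excluded records.

Law-language grouping follows the LawAtlas-style fields: states are
dichotomized by whether the law names the category of healthcare provider
who may clear return to play (with the one no-clearance state grouped with
"not specified"), the specified states are further split into
physicians-only versus multiple provider categories, and all states are
split by whether concussion education is required for both coaches and
parents/guardians or only one of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .simulate import US_JURISDICTIONS

__all__ = [
    "EVENT_COLUMNS",
    "EXPOSURE_COLUMNS",
    "LAW_COLUMNS",
    "ExclusionReport",
    "ModelSpec",
    "read_surveillance_csv",
    "read_law_csv",
    "write_surveillance_csv",
    "write_law_csv",
    "apply_exclusions",
    "classify_states",
    "enumerate_model_plan",
]

EVENT_COLUMNS = [
    "state",
    "injury_date",
    "classification",
    "injury_type",
    "recurrent_mechanism_sport",
]
EXPOSURE_COLUMNS = ["state", "academic_year", "exposure_week", "athlete_exposures"]
LAW_COLUMNS = ["state", "passage_date", "rtp_provider", "provider_breadth", "education"]

EXCLUSION_REASONS = (
    "missing_date",
    "missing_state",
    "missing_classification",
    "missing_ae",
    "type_unknown",
    "type_other",
    "recurrent_nonsport",
)


@dataclass
class ExclusionReport:
    """Bookkeeping for the exclusion filter.

    ``n_kept + n_excluded == n_input`` always; ``reasons`` counts every
    rule each excluded record trips, so the reason counts may sum to more
    than ``n_excluded`` (records can be missing several fields at once).
    """

    n_input: int
    n_kept: int
    n_excluded: int
    reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_kept + self.n_excluded != self.n_input:
            raise ValueError("n_kept + n_excluded must equal n_input")

    @property
    def excluded_fraction(self) -> float:
        return self.n_excluded / self.n_input if self.n_input else 0.0

    def to_json(self, path=None) -> str:
        payload = {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_excluded": self.n_excluded,
            "excluded_percent": round(100.0 * self.excluded_fraction, 1),
            "reasons": dict(self.reasons),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _require_columns(df: pd.DataFrame, required: list[str], label: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{label} CSV missing required columns: {missing}")


def _parse_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "": None, "nan": None, "none": None,
    }

    def conv(v):
        if isinstance(v, bool):
            return v
        if pd.isna(v):
            return None
        return mapping.get(str(v).strip().lower(), None)

    return series.map(conv)


def read_surveillance_csv(
    events_path, exposures_path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read event and exposure CSVs into typed frames.

    Unparseable fields (bad dates, unknown codes) become nulls — candidates
    for the exclusion filter — never silent defaults.  Missing required
    columns raise a schema error listing them.
    """
    events = pd.read_csv(events_path, dtype=str, keep_default_na=False)
    _require_columns(events, EVENT_COLUMNS, "events")
    events = events.replace({"": None})
    events["injury_date"] = pd.to_datetime(
        events["injury_date"], format="%Y-%m-%d", errors="coerce"
    ).dt.date
    events["injury_date"] = events["injury_date"].where(
        pd.notna(events["injury_date"]), None
    )
    events["state"] = events["state"].where(
        events["state"].isin(US_JURISDICTIONS), None
    )
    events["classification"] = (
        events["classification"].fillna("missing").str.lower()
    )
    events.loc[
        ~events["classification"].isin(["incident", "recurrent", "unknown"]),
        "classification",
    ] = "missing"
    events["injury_type"] = events["injury_type"].fillna("unknown").str.lower()
    events.loc[
        ~events["injury_type"].isin(["concussion", "other"]), "injury_type"
    ] = "unknown"
    events["recurrent_mechanism_sport"] = _parse_bool(
        events["recurrent_mechanism_sport"]
    )
    if "ae_linked" in events.columns:
        events["ae_linked"] = _parse_bool(events["ae_linked"]).fillna(True)
    else:
        events["ae_linked"] = True

    exposures = pd.read_csv(exposures_path)
    _require_columns(exposures, EXPOSURE_COLUMNS, "exposures")
    exposures["academic_year"] = exposures["academic_year"].astype(int)
    exposures["exposure_week"] = exposures["exposure_week"].astype(int)
    exposures["athlete_exposures"] = exposures["athlete_exposures"].astype(float)
    bad_week = ~exposures["exposure_week"].between(1, 52)
    if bad_week.any():
        raise ValueError(
            f"exposure_week outside 1-52 in {int(bad_week.sum())} rows"
        )
    if (exposures["athlete_exposures"] < 0).any():
        raise ValueError("athlete_exposures must be non-negative")
    return events, exposures


def read_law_csv(path) -> pd.DataFrame:
    laws = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(laws, LAW_COLUMNS, "laws")
    laws = laws.replace({"": None})
    laws["passage_date"] = pd.to_datetime(
        laws["passage_date"], format="%Y-%m-%d", errors="coerce"
    ).dt.date
    for col in ("rtp_provider", "provider_breadth", "education"):
        laws[col] = laws[col].str.lower()
    return laws


def write_surveillance_csv(events: pd.DataFrame, exposures: pd.DataFrame,
                           events_path, exposures_path) -> None:
    cols = EVENT_COLUMNS + (
        ["ae_linked"] if "ae_linked" in events.columns else []
    )
    events[cols].to_csv(events_path, index=False)
    exposures[EXPOSURE_COLUMNS].to_csv(exposures_path, index=False)


def write_law_csv(laws: pd.DataFrame, path) -> None:
    laws[LAW_COLUMNS].to_csv(path, index=False)


def apply_exclusions(events: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion rules; return kept records and the tally.

    Rules, in reporting order: missing injury date; missing state; missing
    incident/recurrent classification; no linked AE data; injury type
    unknown; injury type other; recurrent injury from a non-sport
    mechanism.  Each excluded record counts once in ``n_excluded`` and once
    per applicable reason.
    """
    n = len(events)
    if n == 0:
        return events.copy(), ExclusionReport(0, 0, 0, {r: 0 for r in EXCLUSION_REASONS})

    date_null = events["injury_date"].isna()
    state_null = events["state"].isna() | ~events["state"].isin(US_JURISDICTIONS)
    cls = events["classification"].astype(str)
    class_bad = ~cls.isin(["incident", "recurrent"])
    if "ae_linked" in events.columns:
        ae_missing = ~events["ae_linked"].fillna(True).astype(bool)
    else:
        ae_missing = pd.Series(False, index=events.index)
    type_unknown = events["injury_type"].astype(str) == "unknown"
    type_other = events["injury_type"].astype(str) == "other"
    nonsport = (cls == "recurrent") & (
        events["recurrent_mechanism_sport"].map(lambda v: v is False)
    )

    flags = {
        "missing_date": date_null,
        "missing_state": state_null,
        "missing_classification": class_bad,
        "missing_ae": ae_missing,
        "type_unknown": type_unknown,
        "type_other": type_other,
        "recurrent_nonsport": nonsport,
    }
    any_flag = pd.Series(False, index=events.index)
    for f in flags.values():
        any_flag |= f.astype(bool)

    kept = events.loc[~any_flag].copy()
    report = ExclusionReport(
        n_input=n,
        n_kept=int((~any_flag).sum()),
        n_excluded=int(any_flag.sum()),
        reasons={name: int(f.astype(bool).sum()) for name, f in flags.items()},
    )
    return kept, report


RTP_GROUPS = ("specified", "not_specified")
BREADTH_GROUPS = ("multiple", "physicians_only")
EDUCATION_GROUPS = ("both", "either")


def classify_states(laws: pd.DataFrame) -> pd.DataFrame:
    """Law-language group labels per state, one row per state.

    Returns a frame with columns ``state, rtp_group, breadth_group,
    education_group``; group sizes are stored in ``.attrs['group_sizes']``.
    Raises on duplicate states or label combinations outside the three
    dichotomies (e.g. a specified-provider state with breadth
    ``not_applicable``, or education requirements for neither party).
    """
    if laws["state"].duplicated().any():
        dupes = sorted(laws.loc[laws["state"].duplicated(), "state"].unique())
        raise ValueError(f"duplicate law records for states: {dupes}")
    rtp = laws["rtp_provider"]
    breadth = laws["provider_breadth"]
    edu = laws["education"]
    if not rtp.isin(RTP_GROUPS).all():
        raise ValueError("rtp_provider must be 'specified' or 'not_specified'")
    na_ok = (breadth == "not_applicable") == (rtp == "not_specified")
    if not na_ok.all():
        bad = sorted(laws.loc[~na_ok, "state"])
        raise ValueError(
            "provider_breadth must be not_applicable exactly when rtp_provider "
            f"is not_specified; violated by {bad}"
        )
    spec = rtp == "specified"
    if not breadth[spec].isin(BREADTH_GROUPS).all():
        raise ValueError(
            "provider_breadth for specified states must be 'multiple' or "
            "'physicians_only'"
        )
    if not edu.isin(EDUCATION_GROUPS).all():
        bad = sorted(laws.loc[~edu.isin(EDUCATION_GROUPS), "state"])
        raise ValueError(
            f"education must be 'both' or 'either' (neither is not a valid "
            f"dichotomy cell); violated by {bad}"
        )

    out = pd.DataFrame(
        {
            "state": laws["state"],
            "rtp_group": rtp,
            "breadth_group": breadth,
            "education_group": edu,
        }
    ).reset_index(drop=True)
    out.attrs["group_sizes"] = {
        "rtp_group": out["rtp_group"].value_counts().to_dict(),
        "breadth_group": out.loc[spec.to_numpy(), "breadth_group"]
        .value_counts()
        .to_dict(),
        "education_group": out["education_group"].value_counts().to_dict(),
    }
    return out


@dataclass(frozen=True)
class ModelSpec:
    """One entry of the analysis plan: a stratum filter plus a classification."""

    dimension: str  # overall | rtp_group | breadth_group | education_group
    group: str | None  # None for overall
    classification: str  # incident | recurrent

    @property
    def label(self) -> str:
        stratum = "overall" if self.group is None else f"{self.dimension}={self.group}"
        return f"{stratum}/{self.classification}"

    def select(self, cells: pd.DataFrame) -> pd.DataFrame:
        out = cells[cells["classification"] == self.classification]
        if self.group is not None:
            out = out[out[self.dimension] == self.group]
        return out


def enumerate_model_plan() -> list[ModelSpec]:
    """The 14-model plan: overall plus three stratified dichotomies,
    each fitted separately for incident and recurrent events."""
    plan: list[ModelSpec] = []
    for cls in ("incident", "recurrent"):
        plan.append(ModelSpec("overall", None, cls))
    for dimension, groups in (
        ("rtp_group", RTP_GROUPS),
        ("breadth_group", BREADTH_GROUPS),
        ("education_group", EDUCATION_GROUPS),
    ):
        for group in groups:
            for cls in ("incident", "recurrent"):
                plan.append(ModelSpec(dimension, group, cls))
    return plan
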