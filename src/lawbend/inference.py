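"""Slope inference on the percent scale, group comparisons, bootstrap.

Because the model is log-linear, a slope coefficient ``beta`` translates to
a multiplicative rate change of ``exp(beta)`` per standardized month; all
reports use the percent scale ``100 * (exp(beta) - 1)``.  Confidence
intervals are Wald intervals from the observed-information covariance and
are deliberately labelled *unadjusted for knot selection*: the change
points were themselves chosen by maximizing the likelihood, so these
intervals are narrower than honest post-selection intervals would be.

Group differences (incident vs recurrent, or between law-language strata)
use the large-sample two-sample z statistic
``(beta_a - beta_b) / sqrt(se_a^2 + se_b^2)`` on the log scale, reported on
the percent scale relative to the declared reference fit.

The cluster bootstrap resamples states with replacement and refits at
fixed knots.  Grouped count data with a handful of dominant clusters tends
to produce heavily skewed bootstrap distributions; a skewness diagnostic
flags such distributions as unreliable instead of reporting their
percentiles as if they were trustworthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import FitConfig
from .ingest import ModelSpec
from .model import KnotPair, PiecewiseNBFit, fit_piecewise_model

__all__ = [
    "SlopeChange",
    "GroupComparison",
    "BootstrapSummary",
    "percent_change",
    "percent_change_inverse",
    "slope_wald_ci",
    "compare_slopes",
    "cluster_bootstrap",
    "report_tables",
]

UNADJUSTED_NOTE = "unadjusted for knot-selection"

_KNOT_LABELS = {
    "gamma1": "after_first_change_point",
    "gamma2": "after_second_change_point",
}


def percent_change(log_slope: float) -> float:
    """Percent rate change per STDM implied by a log-scale slope.

    ``100 * (exp(b) - 1)``: strictly increasing with exact inverse
    :func:`percent_change_inverse`; near zero it is approximately
    ``100 * b``.
    """
    return 100.0 * math.expm1(log_slope)


def percent_change_inverse(percent: float) -> float:
    return math.log1p(percent / 100.0)


@dataclass(frozen=True)
class SlopeChange:
    """A slope coefficient expressed as percent change per STDM with Wald CI."""

    label: str  # after_first_change_point | after_second_change_point
    percent_per_stdm: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float
    se: float
    alpha: float = 0.05
    note: str = UNADJUSTED_NOTE

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def slope_wald_ci(
    coef: float,
    se: float,
    alpha: float = 0.05,
    label: str = "after_first_change_point",
) -> SlopeChange:
    """Wald interval and two-sided p-value for a log-scale slope.

    The interval is symmetric on the log scale and mapped through the
    percent transform, so it is (correctly) asymmetric on the percent
    scale for large slopes.
    """
    if not math.isfinite(coef):
        raise ValueError("coefficient must be finite")
    if not (se > 0 and math.isfinite(se)):
        raise ValueError("standard error must be positive and finite")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p = 2.0 * stats.norm.sf(abs(coef) / se)
    return SlopeChange(
        label=label,
        percent_per_stdm=percent_change(coef),
        ci_low=percent_change(coef - z * se),
        ci_high=percent_change(coef + z * se),
        p_value=float(p),
        coef=float(coef),
        se=float(se),
        alpha=alpha,
    )


@dataclass(frozen=True)
class GroupComparison:
    """Difference in a slope between two fits, relative to the reference."""

    label: str
    which: str  # gamma1 | gamma2
    difference_percent: float
    ci_low: float
    ci_high: float
    p_value: float
    statistic: float
    coef_diff: float
    se_diff: float
    reference: str
    alpha: float = 0.05
    note: str = UNADJUSTED_NOTE

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_slopes(
    fit_a: PiecewiseNBFit,
    fit_b: PiecewiseNBFit,
    which: str,
    label: str = "",
    reference: str = "b",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sample large-sample test of a slope difference between fits.

    The statistic ``(coef_a - coef_b) / sqrt(se_a^2 + se_b^2)`` is referred
    to the standard normal (a two-sample t with effectively infinite
    degrees of freedom); the difference and its CI are reported on the
    percent scale, with ``fit_b`` as the reference group by convention
    (``reference`` records the naming for the report).
    """
    if which not in ("gamma1", "gamma2", "beta1"):
        raise ValueError("which must be one of beta1, gamma1, gamma2")
    for name, fit in (("a", fit_a), ("b", fit_b)):
        if not fit.converged:
            raise ValueError(f"fit {name} did not converge; cannot compare slopes")
    diff = fit_a.coef(which) - fit_b.coef(which)
    se = math.sqrt(fit_a.se(which) ** 2 + fit_b.se(which) ** 2)
    if se == 0.0:
        raise ValueError("zero combined standard error")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    statistic = diff / se
    p = 2.0 * stats.norm.sf(abs(statistic))
    return GroupComparison(
        label=label,
        which=which,
        difference_percent=percent_change(diff),
        ci_low=percent_change(diff - z * se),
        ci_high=percent_change(diff + z * se),
        p_value=float(p),
        statistic=float(statistic),
        coef_diff=float(diff),
        se_diff=float(se),
        reference=reference,
        alpha=alpha,
    )


@dataclass
class BootstrapSummary:
    """Cluster-bootstrap SEs, percentile intervals and skew diagnostics."""

    n_boot: int
    n_converged: int
    n_failed: int
    estimates: pd.DataFrame  # one row per converged replicate
    se: dict[str, float]
    percentile_ci: dict[str, tuple[float, float]]
    skewness: dict[str, float]
    unreliable: dict[str, bool]
    skew_threshold: float
    mode: str
    note: str = UNADJUSTED_NOTE


_BOOT_COEFS = ("beta0", "beta1", "gamma1", "gamma2")


def cluster_bootstrap(
    cells: pd.DataFrame,
    knots: KnotPair,
    config: FitConfig | None = None,
    n_boot: int = 200,
    seed: int = 0,
    mode: str = "nonparametric",
    skew_threshold: float = 1.0,
    samples: list[np.ndarray] | None = None,
) -> BootstrapSummary:
    """Bootstrap the fixed effects by resampling states (or simulating).

    ``mode='nonparametric'`` resamples whole states with replacement,
    preserving within-state dependence.  ``mode='parametric'`` refits on
    data simulated from the original fit (NB2 with the fitted dispersion,
    random intercepts redrawn), the remedy suggested when influential
    clusters make the nonparametric distributions unusable.  Replicates
    whose refit fails to converge are counted and excluded, never silently
    dropped.  ``samples`` (a list of state-index arrays) overrides the
    resampling, which gives tests an exact identity path.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if mode not in ("nonparametric", "parametric"):
        raise ValueError("mode must be 'nonparametric' or 'parametric'")
    config = config or FitConfig()
    boot_config = config.replace(polish=False)
    rng = np.random.default_rng(seed)
    states = np.array(sorted(cells["state"].astype(str).unique()))
    n_states = len(states)

    base_fit = fit_piecewise_model(cells, knots, config)
    by_state = {s: g for s, g in cells.groupby(cells["state"].astype(str))}

    rows = []
    n_failed = 0
    for rep in range(n_boot):
        if mode == "nonparametric":
            if samples is not None:
                idx = np.asarray(samples[rep % len(samples)])
            else:
                idx = rng.integers(0, n_states, size=n_states)
            parts = []
            for clone, i in enumerate(idx):
                part = by_state[states[i]].copy()
                # Clone label keeps resampled copies of a state distinct.
                part["state"] = f"{states[i]}#{clone}"
                parts.append(part)
            sample = pd.concat(parts, ignore_index=True)
        else:
            sample = _parametric_draw(cells, base_fit, knots, rng)
        fit = fit_piecewise_model(sample, knots, boot_config)
        if not fit.converged:
            n_failed += 1
            continue
        rows.append({c: fit.coef(c) for c in _BOOT_COEFS})

    estimates = pd.DataFrame(rows, columns=list(_BOOT_COEFS))
    se, pci, skew, unreliable = {}, {}, {}, {}
    for c in _BOOT_COEFS:
        vals = estimates[c].to_numpy()
        if len(vals) >= 2:
            se[c] = float(np.std(vals, ddof=1))
            lo, hi = np.percentile(vals, [2.5, 97.5])
            pci[c] = (float(lo), float(hi))
            sk = float(stats.skew(vals, bias=False)) if len(vals) >= 3 else 0.0
            skew[c] = sk
            unreliable[c] = abs(sk) > skew_threshold
        else:
            se[c] = float("nan")
            pci[c] = (float("nan"), float("nan"))
            skew[c] = float("nan")
            unreliable[c] = False
    return BootstrapSummary(
        n_boot=n_boot,
        n_converged=len(estimates),
        n_failed=n_failed,
        estimates=estimates,
        se=se,
        percentile_ci=pci,
        skewness=skew,
        unreliable=unreliable,
        skew_threshold=skew_threshold,
        mode=mode,
    )


def _parametric_draw(
    cells: pd.DataFrame,
    fit: PiecewiseNBFit,
    knots: KnotPair,
    rng: np.random.Generator,
) -> pd.DataFrame:
    from .model import knot_basis

    out = cells.copy()
    m, h1, h2 = knot_basis(out["stdm"].to_numpy(dtype=float), knots)
    states = out["state"].astype(str)
    b = {s: rng.normal(0.0, fit.sigma_b) for s in states.unique()}
    eta = (
        np.log(out["athlete_exposures"].to_numpy(dtype=float))
        + fit.beta0
        + fit.beta1 * m
        + fit.gamma1 * h1
        + fit.gamma2 * h2
        + states.map(b).to_numpy(dtype=float)
    )
    mu = np.exp(eta)
    if fit.dispersion > 0:
        r = 1.0 / fit.dispersion
        lam = rng.gamma(shape=r, scale=mu / r)
        out["event_count"] = rng.poisson(lam)
    else:
        out["event_count"] = rng.poisson(mu)
    return out


def _stars(p: float, alpha: float = 0.05) -> str:
    return "*" if p < alpha else ""


def report_tables(
    fits: dict[str, PiecewiseNBFit] | list[tuple[ModelSpec, PiecewiseNBFit]],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratum-level and between-group summary tables.

    ``fits`` maps each analysis-plan entry (``ModelSpec`` or its label) to
    its final fit.  The first table has one row per stratum (overall plus
    the six law-language groups) with, for each change point, the
    incident and recurrent percent changes per STDM, Wald CIs,
    significance stars at ``alpha``, and the incident-vs-recurrent
    difference.  The second has one row per law-language comparison with
    incident and recurrent slope differences at each change point.
    Missing plan entries leave explicit gaps (NaN) rather than silently
    shrinking the table.
    """
    if isinstance(fits, list):
        fits = {spec.label: fit for spec, fit in fits}

    strata = [
        ("overall", None),
        ("rtp_group", "specified"),
        ("rtp_group", "not_specified"),
        ("breadth_group", "multiple"),
        ("breadth_group", "physicians_only"),
        ("education_group", "both"),
        ("education_group", "either"),
    ]

    missing_entries: list[str] = []

    def get(dimension, group, cls):
        label = ModelSpec(dimension, group, cls).label
        fit = fits.get(label)
        if fit is None:
            missing_entries.append(label)
        return fit

    rows = []
    for dimension, group in strata:
        row: dict[str, object] = {
            "stratum": "overall" if group is None else f"{dimension}={group}"
        }
        inc = get(dimension, group, "incident")
        rec = get(dimension, group, "recurrent")
        for which, tag in (("gamma1", "cp1"), ("gamma2", "cp2")):
            for cls_label, fit in (("incident", inc), ("recurrent", rec)):
                prefix = f"{tag}_{cls_label}"
                if fit is None or not fit.converged:
                    row[f"{prefix}_percent"] = np.nan
                    row[f"{prefix}_ci_low"] = np.nan
                    row[f"{prefix}_ci_high"] = np.nan
                    row[f"{prefix}_sig"] = ""
                    continue
                sc = slope_wald_ci(
                    fit.coef(which), fit.se(which), alpha, _KNOT_LABELS[which]
                )
                row[f"{prefix}_percent"] = sc.percent_per_stdm
                row[f"{prefix}_ci_low"] = sc.ci_low
                row[f"{prefix}_ci_high"] = sc.ci_high
                row[f"{prefix}_sig"] = _stars(sc.p_value, alpha)
            if inc is not None and rec is not None and inc.converged and rec.converged:
                cmp_ = compare_slopes(
                    rec, inc, which,
                    label=f"{row['stratum']}: recurrent vs incident",
                    reference="incident",
                    alpha=alpha,
                )
                row[f"{tag}_rec_vs_inc_percent"] = cmp_.difference_percent
                row[f"{tag}_rec_vs_inc_ci_low"] = cmp_.ci_low
                row[f"{tag}_rec_vs_inc_ci_high"] = cmp_.ci_high
                row[f"{tag}_rec_vs_inc_sig"] = _stars(cmp_.p_value, alpha)
            else:
                row[f"{tag}_rec_vs_inc_percent"] = np.nan
                row[f"{tag}_rec_vs_inc_ci_low"] = np.nan
                row[f"{tag}_rec_vs_inc_ci_high"] = np.nan
                row[f"{tag}_rec_vs_inc_sig"] = ""
        rows.append(row)
    stratum_table = pd.DataFrame(rows)
    stratum_table.attrs["note"] = UNADJUSTED_NOTE

    comparisons = [
        ("rtp_group", "not_specified", "specified"),
        ("breadth_group", "multiple", "physicians_only"),
        ("education_group", "both", "either"),
    ]
    rows = []
    for dimension, group_a, group_b in comparisons:
        row = {
            "comparison": f"{dimension}: {group_a} vs {group_b}",
            "reference": group_b,
        }
        for cls in ("incident", "recurrent"):
            fa = get(dimension, group_a, cls)
            fb = get(dimension, group_b, cls)
            for which, tag in (("gamma1", "cp1"), ("gamma2", "cp2")):
                prefix = f"{tag}_{cls}"
                if (
                    fa is None or fb is None
                    or not fa.converged or not fb.converged
                ):
                    row[f"{prefix}_diff_percent"] = np.nan
                    row[f"{prefix}_ci_low"] = np.nan
                    row[f"{prefix}_ci_high"] = np.nan
                    row[f"{prefix}_sig"] = ""
                    continue
                cmp_ = compare_slopes(
                    fa, fb, which, label=row["comparison"],
                    reference=group_b, alpha=alpha,
                )
                row[f"{prefix}_diff_percent"] = cmp_.difference_percent
                row[f"{prefix}_ci_low"] = cmp_.ci_low
                row[f"{prefix}_ci_high"] = cmp_.ci_high
                row[f"{prefix}_sig"] = _stars(cmp_.p_value, alpha)
        rows.append(row)
    comparison_table = pd.DataFrame(rows)
    comparison_table.attrs["note"] = UNADJUSTED_NOTE
    if missing_entries:
        import warnings

        warnings.warn(
            f"analysis plan entries missing from report: {sorted(set(missing_entries))}",
            stacklevel=2,
        )
    return stratum_table, comparison_table
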