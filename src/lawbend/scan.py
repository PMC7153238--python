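"""Profile-likelihood change-point search on the six-month knot grid.

The two change points are not estimated inside one optimizer run; instead
the model is refit at every ordered pair (tau1 < tau2) of candidate knots
on a six-month grid anchored at the law-passage month, and the pair with
the largest maximized log likelihood is the profile-likelihood estimate.
All remaining parameters — including the NB2 dispersion and the
random-intercept SD — are re-maximized at every grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FitConfig
from .model import KnotPair, PiecewiseNBFit, _CellData, _check_degenerate, fit_piecewise_model

__all__ = ["ProfileSurface", "enumerate_knot_grid", "profile_search", "select_best"]


def enumerate_knot_grid(stdm_min: int, stdm_max: int, step: int = 6) -> list[KnotPair]:
    """All ordered knot pairs on the step-aligned grid within the range.

    Grid points are the multiples of ``step`` inside ``[stdm_min,
    stdm_max]`` (anchored at STDM 0, i.e. the passage month); pairs are all
    strictly ordered combinations, so ``m`` grid points give C(m, 2) pairs.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if stdm_min >= stdm_max:
        raise ValueError("stdm_min must be < stdm_max")
    lo = -(-stdm_min // step)  # ceil division
    hi = stdm_max // step
    points = [step * k for k in range(lo, hi + 1)]
    if len(points) < 2:
        raise ValueError("knot grid needs at least two points inside the range")
    return [
        KnotPair(points[i], points[j])
        for i in range(len(points))
        for j in range(i + 1, len(points))
    ]


@dataclass
class ProfileSurface:
    """Result of an exhaustive knot-grid scan."""

    entries: pd.DataFrame  # tau1, tau2, loglik, converged, eligible, reason
    best: KnotPair
    best_loglik: float

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def profile_search(
    cells: pd.DataFrame,
    grid: list[KnotPair],
    config: FitConfig | None = None,
) -> tuple[ProfileSurface, PiecewiseNBFit]:
    """Exhaustive profile-likelihood scan over candidate knot pairs.

    Every pair is either fitted or recorded with an ineligibility reason
    (degenerate knots: no data strictly on both sides of a knot).  Scan
    fits reuse the nearest previously converged solution as a warm start
    and skip the final polish; the winning pair — largest converged log
    likelihood, ties broken toward the smallest (tau1, tau2) — is refit at
    full precision for inference.
    """
    if not grid:
        raise ValueError("knot grid is empty")
    config = config or FitConfig()
    data = _CellData(cells)
    scan_config = config.replace(polish=False)

    rows = []
    solutions: dict[KnotPair, np.ndarray] = {}
    ordered = sorted(grid)
    for pair in ordered:
        if _check_degenerate(data, pair):
            rows.append(
                {
                    "tau1": pair.tau1,
                    "tau2": pair.tau2,
                    "loglik": np.nan,
                    "converged": False,
                    "eligible": False,
                    "reason": "degenerate: no data strictly on both sides of a knot",
                }
            )
            continue
        start = _nearest_solution(solutions, pair)
        fit = fit_piecewise_model(
            data, pair, scan_config, start=start, compute_vcov=False
        )
        if fit.converged:
            solutions[pair] = _theta_of(fit)
        rows.append(
            {
                "tau1": pair.tau1,
                "tau2": pair.tau2,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "eligible": True,
                "reason": "",
            }
        )
    entries = pd.DataFrame(rows)

    best = select_best(entries)

    final = fit_piecewise_model(data, best, config, start=solutions.get(best))
    surface = ProfileSurface(entries=entries, best=best, best_loglik=float(final.loglik))
    return surface, final


def select_best(entries: pd.DataFrame, tie_tol: float = 1e-9) -> KnotPair:
    """Winning pair: largest converged log likelihood; logliks within
    ``tie_tol`` of the maximum are treated as tied and the smallest
    (tau1, tau2) wins."""
    ok = entries[entries["converged"] & entries["eligible"]]
    if ok.empty:
        raise ValueError("no eligible, converged knot pair in the grid")
    best_ll = ok["loglik"].max()
    winners = ok[ok["loglik"] >= best_ll - tie_tol].sort_values(["tau1", "tau2"])
    return KnotPair(int(winners.iloc[0]["tau1"]), int(winners.iloc[0]["tau2"]))


def _theta_of(fit: PiecewiseNBFit) -> np.ndarray:
    return np.array(
        [
            fit.beta0,
            fit.beta1,
            fit.gamma1,
            fit.gamma2,
            np.log(max(fit.dispersion, 1e-12)),
            np.log(max(fit.sigma_b, 1e-8)),
        ]
    )


def _nearest_solution(
    solutions: dict[KnotPair, np.ndarray], pair: KnotPair
) -> np.ndarray | None:
    if not solutions:
        return None
    key = min(
        solutions,
        key=lambda p: abs(p.tau1 - pair.tau1) + abs(p.tau2 - pair.tau2),
    )
    return solutions[key]
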