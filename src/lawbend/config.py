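"""Configuration objects for the simulator and the model fitter.

Both are plain dataclasses with eager validation: an invalid field raises
``ValueError`` naming the field, so downstream code never sees a half-valid
configuration.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

# LawAtlas distribution of passage years across the 51 jurisdictions
# (50 states + DC): 2009: 2, 2010: 8, 2011: 27, 2012: 7, 2013: 6, 2014: 1.
DEFAULT_PASSAGE_YEAR_WEIGHTS: dict[int, float] = {
    2009: 2 / 51,
    2010: 8 / 51,
    2011: 27 / 51,
    2012: 7 / 51,
    2013: 6 / 51,
    2014: 1 / 51,
}

# Law-language composition at passage across the 51 jurisdictions:
# 27/51 specified the category of RTP-clearance provider; of those, 7/27
# restricted clearance to physicians; 40/51 required concussion education
# for both coaches and parents/guardians.
RTP_SPECIFIED_SHARE = 27 / 51
PHYSICIANS_ONLY_SHARE = 7 / 27
EDUCATION_BOTH_SHARE = 40 / 51

# Surveillance-wide incident:recurrent split is roughly 91:9.
DEFAULT_RECURRENT_FRACTION = 0.091

#: Missingness fields the raw-record generator knows how to corrupt.
MISSINGNESS_FIELDS = (
    "injury_date",
    "state",
    "classification",
    "ae_link",
    "injury_type_unknown",
    "injury_type_other",
    "nonsport_mechanism",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative world for synthetic concussion surveillance.

    The rate model mirrors the analysis model: for state ``s`` at
    standardized month ``m`` (months since law passage), the expected count is

        AE * exp(beta0 + b_s + beta1*m + gamma1*(m - tau1)+ + gamma2*(m - tau2)+)

    with ``b_s ~ Normal(0, sigma_b^2)`` and NB2 overdispersion ``dispersion``
    (variance ``mu + dispersion * mu^2``).

    Parameters
    ----------
    n_states
        Number of jurisdictions to simulate (at most 51).
    stdm_range
        Inclusive (low, high) standardized-month span, e.g. ``(-96, 108)``.
    beta0
        Baseline log rate (log events per athlete-exposure) at STDM 0
        ignoring slope terms.
    beta1
        Pre-``tau1`` log-linear slope per STDM.
    gamma1, gamma2
        Additional log slopes switched on after ``tau1`` and ``tau2``.
    tau1, tau2
        True change points (STDM months), ``tau1 < tau2``.
    dispersion
        NB2 overdispersion alpha > 0 (0 is allowed and means Poisson).
    sigma_b
        Standard deviation of the state random intercept (>= 0).
    ae_log_mean, ae_log_sd
        Log-normal parameters of the per state-month athlete-exposure
        denominator. The defaults give a median of ~22,000 AE per
        state-month, a plausible statewide high-school figure.
    recurrent_fraction
        Probability an event is a recurrent (repeat) concussion.
    passage_year_weights
        Mapping year -> probability used to draw each state's law-passage
        year; defaults to the observed 2009-2014 LawAtlas distribution.
    missingness_rates
        Mapping field -> probability used by the raw-record generator to
        inject missing/unusable values (see ``MISSINGNESS_FIELDS``).
    seed
        Seed for all randomness; identical configs give identical output.
    """

    n_states: int = 40
    stdm_range: tuple[int, int] = (-96, 108)
    beta0: float = math.log(2.0e-4)
    beta1: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    tau1: int = -12
    tau2: int = 12
    dispersion: float = 0.3
    sigma_b: float = 0.35
    ae_log_mean: float = 10.0
    ae_log_sd: float = 0.5
    recurrent_fraction: float = DEFAULT_RECURRENT_FRACTION
    passage_year_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PASSAGE_YEAR_WEIGHTS)
    )
    missingness_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_states, int) or not 1 <= self.n_states <= 51:
            raise ValueError("n_states must be an integer in [1, 51]")
        lo, hi = self.stdm_range
        if lo >= hi:
            raise ValueError("stdm_range must satisfy low < high")
        if not self.tau1 < self.tau2:
            raise ValueError("tau1 must be strictly less than tau2")
        if not (lo <= self.tau1 <= hi and lo <= self.tau2 <= hi):
            raise ValueError("tau1 and tau2 must lie within stdm_range")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")
        if not 0.0 <= self.recurrent_fraction <= 1.0:
            raise ValueError("recurrent_fraction must lie in [0, 1]")
        if self.ae_log_sd < 0:
            raise ValueError("ae_log_sd must be >= 0")
        w = dict(self.passage_year_weights)
        if not w or any(p < 0 for p in w.values()):
            raise ValueError("passage_year_weights must be non-negative and non-empty")
        if not math.isclose(sum(w.values()), 1.0, abs_tol=1e-6):
            raise ValueError("passage_year_weights must sum to 1")
        for key, rate in dict(self.missingness_rates).items():
            if key not in MISSINGNESS_FIELDS:
                raise ValueError(f"missingness_rates has unknown field {key!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness_rates[{key!r}] must lie in [0, 1]")

    @property
    def stdm_values(self) -> range:
        lo, hi = self.stdm_range
        return range(lo, hi + 1)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stdm_range" in raw:
            raw["stdm_range"] = tuple(raw["stdm_range"])
        if "passage_year_weights" in raw:
            raw["passage_year_weights"] = {
                int(k): float(v) for k, v in raw["passage_year_weights"].items()
            }
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["stdm_range"] = list(self.stdm_range)
        raw["passage_year_weights"] = {
            int(k): float(v) for k, v in self.passage_year_weights.items()
        }
        raw["missingness_rates"] = dict(self.missingness_rates)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class FitConfig:
    """Numerical settings for the mixed-model fitter.

    ``quadrature_nodes`` controls the adaptive Gauss-Hermite rule used to
    integrate the state random intercept out of the likelihood; 15 nodes is
    accurate to well below 1e-4 in log likelihood on realistic data.
    ``polish`` runs a derivative-free refinement after L-BFGS-B so repeated
    fits from different starts agree to ~1e-6 in log likelihood.
    """

    quadrature_nodes: int = 15
    max_iter: int = 300
    tol: float = 1e-10
    n_restarts: int = 2
    seed: int = 0
    polish: bool = True

    def __post_init__(self) -> None:
        if self.quadrature_nodes < 1:
            raise ValueError("quadrature_nodes must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.n_restarts < 0:
            raise ValueError("n_restarts must be >= 0")

    def replace(self, **kwargs) -> "FitConfig":
        return dataclasses.replace(self, **kwargs)
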