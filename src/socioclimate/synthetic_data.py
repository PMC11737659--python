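"""Synthetic inputs: a historical emission ramp and self-consistent ABC targets.

Real runs use an annual anthropogenic CO₂ emission CSV (e.g. a Global
Carbon Budget export).  For development and testing this module supplies
a logistic industrial-era ramp with the same file interface — slow
take-off in the nineteenth century, rapid twentieth-century growth, a
modern plateau — anchored exactly to a configurable 2021 value.  It also
builds calibration fixtures: a target summary vector generated from a
known parameter set, with priors guaranteed to contain the truth, so the
rejection sampler can be exercised end to end without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration_abc import PriorSpec, summarize
from .config import ModelConfig
from .coupling import run_scenario
from .earth_system import EmissionSeries

__all__ = [
    "EmissionRampSpec",
    "make_emission_ramp",
    "default_emissions",
    "make_abc_fixture",
    "DEFAULT_SNAPSHOT_YEARS",
]

DEFAULT_SNAPSHOT_YEARS = (2050, 2100, 2200)

# Natural prior ranges by parameter kind: probabilities live on [0, 1];
# hypothetical parameters get broad bounds around plausible magnitudes.
DEFAULT_PRIOR_RANGES: dict[str, tuple[float, float]] = {
    "beta": (0.0, 1.0), "varsigma": (0.0, 1.0), "eta0": (0.0, 1.0),
    "omega0": (0.0, 1.0), "epsilon": (0.0, 1.0), "zeta": (0.0, 1.0),
    "alpha": (0.0, 1.0), "gamma": (0.0, 1.0), "rho": (0.0, 1.0),
    "sigma": (0.0, 1.0),
    "c_bar": (1.0, 60.0), "d_bar": (0.05, 5.0), "v": (0.0, 1.0),
    "Psi": (0.0, 22.0), "delta": (0.001, 0.05),
    "X": (5.0, 200.0), "m_bar": (5.0, 300.0), "k": (2.0, 10.5),
}


@dataclass(frozen=True)
class EmissionRampSpec:
    """Logistic emission ramp: E(t) = E_end · L(t) / L(end_year)."""

    start_year: int = 1850
    end_year: int = 2021
    E_end: float = 37.0
    midpoint_year: float = 1990.0
    steepness: float = 0.045

    def __post_init__(self) -> None:
        if not self.start_year < self.midpoint_year < self.end_year:
            raise ValueError("require start_year < midpoint_year < end_year")
        if self.E_end <= 0:
            raise ValueError("E_end must be positive")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")


def make_emission_ramp(spec: EmissionRampSpec = EmissionRampSpec()) -> EmissionSeries:
    """Annual emission series following the logistic ramp; monotone
    nondecreasing and anchored so E(end_year) = E_end exactly."""
    years = np.arange(spec.start_year, spec.end_year + 1)

    def logistic(t: float) -> float:
        return 1.0 / (1.0 + math.exp(-spec.steepness * (t - spec.midpoint_year)))

    scale = spec.E_end / logistic(spec.end_year)
    values = np.array([scale * logistic(t) for t in years])
    values[-1] = spec.E_end  # exact anchor against rounding
    return EmissionSeries(years, values)


def default_emissions() -> EmissionSeries:
    return make_emission_ramp()


def make_abc_fixture(
    true_config: ModelConfig,
    emissions: EmissionSeries,
    free_params: tuple[str, ...] = ("omega0", "Psi"),
    snapshot_years: tuple[int, ...] = DEFAULT_SNAPSHOT_YEARS,
) -> tuple[np.ndarray, PriorSpec]:
    """Self-consistent calibration fixture.

    Runs the scenario at ``true_config``, extracts its summary vector as
    the calibration target, and returns priors on ``free_params`` drawn
    from the natural ranges, widened if necessary so the truth is always
    contained.
    """
    result = run_scenario(true_config, emissions)
    target = summarize(result, snapshot_years)
    bounds = {}
    for name in free_params:
        lo, hi = DEFAULT_PRIOR_RANGES[name]
        truth = _lookup(true_config, name)
        lo, hi = min(lo, truth), max(hi, truth)
        bounds[name] = (lo, hi)
    return target, PriorSpec(bounds)


def _lookup(config: ModelConfig, name: str) -> float:
    if name == "k":
        return config.degree.mean_degree()
    if hasattr(config.rumor, name):
        return getattr(config.rumor, name)
    return getattr(config.climate, name)
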