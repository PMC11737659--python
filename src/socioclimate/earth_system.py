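"""One-box carbon and temperature dynamics.

The climate side of the coupled model is deliberately austere: a single
atmospheric carbon stock and a single upper-ocean temperature box.

* Carbon.  ``C`` is the deviation of the atmospheric CO₂ burden from its
  pre-industrial level, carried in GtCO₂ so it adds directly to emissions.
  Before the rumor starts (t ≤ 2021) dC/dt equals the prescribed
  anthropogenic emission series E(t); afterwards emissions are scaled by
  the rejectors' mitigation, E₂₀₂₁·exp(−Ψ·i_R), and the deviation decays
  at the natural dissipation rate δ (ocean/land sinks collapsed into one
  first-order term).

* Forcing.  F = (F₂ₓ/ln 2)·ln(C_atm/C₀) with C_atm = C₀ + C/gt_per_ppm,
  the standard logarithmic CO₂ forcing.

* Temperature.  dT/dt = (q·F − T)/d: the upper ocean relaxes toward the
  equilibrium anomaly q·F with e-folding time d years.  A ``literal``
  mode dT/dt = q·F − T·d is selectable for sensitivity to the alternative
  reading of the governing equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ClimateParams",
    "CarbonTempState",
    "EmissionSeries",
    "radiative_forcing",
    "temperature_rhs",
    "carbon_rhs",
    "spin_up",
]

RUMOR_START_YEAR = 2021


@dataclass(frozen=True)
class ClimateParams:
    """Earth-system and emission parameters.

    q      thermal adjustment of the upper ocean (°C per W m⁻²)
    d      thermal equilibrium timescale of the upper ocean (years)
    F2x    forcing from a CO₂ doubling (W m⁻²)
    C0     pre-industrial atmospheric CO₂ (ppm)
    delta  natural dissipation rate of the CO₂ deviation (per year)
    Psi    emission-limiting constant of the rejectors (dimensionless)
    E2021  baseline emissions in 2021, absent rejectors (GtCO₂ per year)
    gt_per_ppm  mass-to-concentration conversion (GtCO₂ per ppm)
    """

    q: float = 0.33
    d: float = 4.1
    F2x: float = 3.74
    C0: float = 278.0
    delta: float = 0.01
    Psi: float = 11.0
    E2021: float = 37.0
    gt_per_ppm: float = 7.82

    def __post_init__(self) -> None:
        for name in ("q", "d", "F2x", "C0", "gt_per_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("delta", "Psi", "E2021"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_updates(self, **kwargs: float) -> "ClimateParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CarbonTempState:
    """Carbon deviation (GtCO₂) and temperature anomaly (°C) at one time."""

    C: float = 0.0
    T: float = 0.0


class EmissionSeries:
    """Annual anthropogenic emission series (year, GtCO₂ per year).

    Values between tabulated years are linearly interpolated; querying
    outside the covered range raises ``ValueError``.
    """

    def __init__(self, years, values) -> None:
        years = np.asarray(years, dtype=float)
        values = np.asarray(values, dtype=float)
        if years.ndim != 1 or years.size != values.size or years.size == 0:
            raise ValueError("years and values must be equal-length 1-D arrays")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("emissions must be nonnegative")
        self.years = years
        self.values = values

    def __call__(self, t: float) -> float:
        if t < self.years[0] or t > self.years[-1]:
            raise ValueError(
                f"year {t} outside emission coverage "
                f"[{self.years[0]:.0f}, {self.years[-1]:.0f}]"
            )
        return float(np.interp(t, self.years, self.values))

    def covers(self, start: float, end: float) -> bool:
        return self.years[0] <= start and end <= self.years[-1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"year": self.years.astype(int), "GtCO2_per_year": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmissionSeries":
        df = pd.read_csv(path)
        if "year" not in df.columns or "GtCO2_per_year" not in df.columns:
            raise ValueError("emission CSV requires 'year' and 'GtCO2_per_year' columns")
        return cls(df["year"].to_numpy(), df["GtCO2_per_year"].to_numpy())


def radiative_forcing(C: float, params: ClimateParams) -> float:
    """Logarithmic CO₂ forcing (W m⁻²) at carbon deviation C (GtCO₂)."""
    c_atm = params.C0 + C / params.gt_per_ppm
    if c_atm <= 0:
        raise ValueError("atmospheric CO₂ must be positive")
    return params.F2x / math.log(2.0) * math.log(c_atm / params.C0)


def temperature_rhs(
    T: float, F: float, params: ClimateParams, mode: str = "box"
) -> float:
    """dT/dt (°C per year) for forcing F.

    ``box`` (default): (q·F − T)/d — relaxation toward q·F with timescale d.
    ``literal``: q·F − T·d, the alternative reading with d as a rate.
    """
    if mode == "box":
        return (params.q * F - T) / params.d
    if mode == "literal":
        return params.q * F - T * params.d
    raise ValueError(f"unknown temperature mode {mode!r}")


def carbon_rhs(
    C: float,
    t: float,
    iR_total: float,
    params: ClimateParams,
    emissions: EmissionSeries,
) -> float:
    """dC/dt (GtCO₂ per year): historical emissions before the rumor era,
    mitigation-scaled emissions minus first-order dissipation afterwards."""
    if not 0.0 <= iR_total <= 1.0 + 1e-9:
        raise ValueError("rejector fraction must lie in [0, 1]")
    if t <= RUMOR_START_YEAR:
        return emissions(t)
    return params.E2021 * math.exp(-params.Psi * iR_total) - params.delta * C


def spin_up(
    emissions: EmissionSeries,
    params: ClimateParams,
    start_year: float = 1850,
    apply_sink: bool = False,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> CarbonTempState:
    """Integrate carbon and temperature from zero state to 2021.

    The default follows the governing carbon equation literally (no sink
    before 2021, i.e. a 100% airborne fraction over the historical
    window); ``apply_sink`` subtracts δ·C throughout instead.
    """
    if not emissions.covers(start_year, RUMOR_START_YEAR):
        raise ValueError("emission series does not cover the spin-up window")

    def rhs(t, y):
        C, T = y
        dC = emissions(t) - (params.delta * C if apply_sink else 0.0)
        dT = temperature_rhs(T, radiative_forcing(max(C, 0.0), params), params)
        return [dC, dT]

    sol = solve_ivp(
        rhs,
        (start_year, RUMOR_START_YEAR),
        [0.0, 0.0],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        max_step=1.0,
    )
    if not sol.success:
        raise RuntimeError(f"spin-up integration failed: {sol.message}")
    return CarbonTempState(C=float(sol.y[0, -1]), T=float(sol.y[1, -1]))
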