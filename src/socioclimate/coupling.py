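"""The coupled rumor–carbon–temperature system.

Coupling runs in both directions.  Climate → society: the believing
probabilities decay exponentially with the temperature anomaly,
η(T) = η₀·e^(−v·T) and ω(T) = ω₀·e^(−v·T) — people who feel the warming
stop believing the denial rumor.  Society → climate: post-2021 emissions
are scaled by the rejector fraction, E = E₂₀₂₁·e^(−Ψ·i_R) — rejectors act
as mitigators with strength Ψ.

A scenario is: spin up carbon and temperature on the historical emission
series to 2021, seed the rumor in an all-susceptible population, then
integrate the joint ODE to the horizon.  The default integrator is
adaptive LSODA (rtol 1e-8 / atol 1e-10) sampled annually; a fixed-step
RK4 mode is available when exact step-for-step reproducibility across
component decompositions matters.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import ModelConfig
from .earth_system import (
    CarbonTempState,
    EmissionSeries,
    radiative_forcing,
    spin_up,
    temperature_rhs,
)
from .rumor_dynamics import RumorState, aggregate, rumor_rhs

__all__ = [
    "CoupledState",
    "ScenarioResult",
    "believing_prob",
    "coupled_rhs",
    "run_scenario",
    "run_rumor_only",
    "run_climate_only",
]

logger = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass(frozen=True)
class CoupledState:
    rumor: RumorState
    climate: CarbonTempState

    def pack(self) -> np.ndarray:
        return np.concatenate([self.rumor.pack(), [self.climate.C, self.climate.T]])

    @classmethod
    def unpack(cls, y: np.ndarray, n_classes: int) -> "CoupledState":
        return cls(
            RumorState.unpack(y[: 4 * n_classes], n_classes),
            CarbonTempState(C=float(y[-2]), T=float(y[-1])),
        )


@dataclass
class ScenarioResult:
    """Annual trajectories of a coupled run.

    Aggregate compartment fractions are p_k-weighted population fractions;
    ``emissions`` is the gross anthropogenic flux E₂₀₂₁·e^(−Ψ·i_R)
    (GtCO₂/yr), ``C`` the carbon deviation (GtCO₂), ``T`` the temperature
    anomaly (°C).  ``rumor_per_class`` keeps the raw per-degree-class
    compartments, shape (n_times, 4, n_classes), for diagnostics.
    """

    times: np.ndarray
    s: np.ndarray
    h: np.ndarray
    iB: np.ndarray
    iR: np.ndarray
    emissions: np.ndarray
    C: np.ndarray
    T: np.ndarray
    rumor_per_class: np.ndarray
    config: ModelConfig | None = None

    def at(self, year: float, series: str) -> float:
        idx = int(np.argmin(np.abs(self.times - year)))
        if abs(self.times[idx] - year) > 0.5:
            raise ValueError(f"year {year} outside scenario window")
        return float(getattr(self, series)[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.times,
                "s": self.s,
                "h": self.h,
                "iB": self.iB,
                "iR": self.iR,
                "emissions_GtCO2_per_year": self.emissions,
                "C_GtCO2": self.C,
                "T_degC": self.T,
            }
        )

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar and self.config is not None:
            self.config.to_json_sidecar(Path(path).with_suffix(".config.json"))

    def log_summary(self) -> None:
        peak_idx = int(np.argmax(self.emissions))
        crossing = self.times[self.T >= 1.5]
        logger.info(
            "peak emission %.2f GtCO2/yr in %d; T crosses 1.5degC %s; final T %.3f degC",
            self.emissions[peak_idx],
            int(self.times[peak_idx]),
            f"in {int(crossing[0])}" if crossing.size else "never",
            self.T[-1],
        )


def believing_prob(base: float, v: float, T: float) -> float:
    """Temperature-modulated believing probability base·e^(−v·T), capped at 1.

    Equals ``base`` at T = 0 and decreases in T for v > 0; a cooling
    (T < 0) can push it above ``base``, in which case it is capped at 1.
    """
    if not 0.0 <= base <= 1.0:
        raise ValueError("base probability must lie in [0, 1]")
    if v < 0:
        raise ValueError("temperature sensitivity v must be nonnegative")
    val = base * math.exp(-v * T)
    if val > 1.0:
        logger.warning("believing probability capped at 1 (T=%.3f)", T)
        return 1.0
    return val


def coupled_rhs(
    y: np.ndarray, t: float, config: ModelConfig, emissions: EmissionSeries
) -> np.ndarray:
    """Packed derivative of [rumor classes..., C, T] at year t (t ≥ 2021)."""
    rp, cp, dd = config.rumor, config.climate, config.degree
    n = dd.n_classes
    state = RumorState.unpack(y, n)
    C, T = float(y[-2]), float(y[-1])

    eta = believing_prob(rp.eta0, rp.v, T)
    omega = believing_prob(rp.omega0, rp.v, T)
    deriv = rumor_rhs(state, rp, dd, eta, omega, config.term_mode)

    iR_total = aggregate(state.iR, dd, config.aggregate_mode)
    dC = cp.E2021 * math.exp(-cp.Psi * iR_total) - cp.delta * C
    dT = temperature_rhs(T, radiative_forcing(C, cp), cp, config.temperature_mode)
    return np.concatenate([deriv.pack(), [dC, dT]])


def _rk4(
    f: Callable[[float, np.ndarray], np.ndarray],
    t0: float,
    t1: float,
    y0: np.ndarray,
    n_per_year: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step classic RK4 sampled at integer years."""
    h = 1.0 / n_per_year
    n_years = int(round(t1 - t0))
    times = t0 + np.arange(n_years + 1, dtype=float)
    out = np.empty((n_years + 1, y0.size))
    out[0] = y0
    y = y0.copy()
    t = t0
    for yr in range(n_years):
        for i in range(n_per_year):
            k1 = f(t, y)
            k2 = f(t + h / 2, y + h / 2 * k1)
            k3 = f(t + h / 2, y + h / 2 * k2)
            k4 = f(t + h, y + h * k3)
            y = y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
            t = t0 + yr + (i + 1) * h
        out[yr + 1] = y
    return times, out


def _integrate(
    f: Callable[[float, np.ndarray], np.ndarray],
    t0: float,
    t1: float,
    y0: np.ndarray,
    method: str,
    rtol: float,
    atol: float,
    n_per_year: int,
) -> tuple[np.ndarray, np.ndarray]:
    if method == "rk4":
        return _rk4(f, t0, t1, y0, n_per_year)
    t_eval = np.arange(t0, t1 + 0.5)
    sol = solve_ivp(
        f, (t0, t1), y0, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if sol.t.size else t0}: {sol.message}"
        )
    return sol.t, sol.y.T


def run_scenario(
    config: ModelConfig,
    emissions: EmissionSeries,
    initial: RumorState | None = None,
    spinup_state: CarbonTempState | None = None,
    method: str = "lsoda",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_per_year: int = 20,
) -> ScenarioResult:
    """Full scenario: historical spin-up, then the coupled rumor-climate run.

    ``initial`` defaults to the all-susceptible population.  A precomputed
    ``spinup_state`` skips the historical integration (the spin-up is
    independent of the rumor parameters, so calibration loops reuse it).
    Deterministic for fixed inputs.
    """
    dd = config.degree
    if initial is None:
        initial = RumorState.seeded(dd.n_classes, config.rumor_seed)
    if initial.n_classes != dd.n_classes:
        raise ValueError("initial state not aligned with degree distribution")
    if config.horizon_end <= config.rumor_start:
        raise ValueError("horizon_end must exceed rumor_start")
    if spinup_state is None:
        spinup_state = spin_up(
            emissions, config.climate, config.spinup_start, config.sink_in_spinup
        )

    y0 = np.concatenate([initial.pack(), [spinup_state.C, spinup_state.T]])
    times, ys = _integrate(
        lambda t, y: coupled_rhs(y, t, config, emissions),
        float(config.rumor_start),
        float(config.horizon_end),
        y0,
        method,
        rtol,
        atol,
        n_per_year,
    )

    n = dd.n_classes
    per_class = ys[:, : 4 * n].reshape(len(times), 4, n)
    agg = {
        name: np.array(
            [aggregate(per_class[i, j], dd, config.aggregate_mode) for i in range(len(times))]
        )
        for j, name in enumerate(("s", "h", "iB", "iR"))
    }
    cp = config.climate
    emis = cp.E2021 * np.exp(-cp.Psi * agg["iR"])
    result = ScenarioResult(
        times=times,
        s=agg["s"],
        h=agg["h"],
        iB=agg["iB"],
        iR=agg["iR"],
        emissions=emis,
        C=ys[:, -2],
        T=ys[:, -1],
        rumor_per_class=per_class,
        config=config,
    )
    result.log_summary()
    return result


def run_rumor_only(
    config: ModelConfig,
    t_end: float,
    eta: float | None = None,
    omega: float | None = None,
    initial: RumorState | None = None,
    t_start: float = 0.0,
    method: str = "lsoda",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_per_year: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the rumor system alone at frozen believing probabilities.

    Returns (times, packed trajectories with shape (n_times, 4·n_classes)).
    ``eta``/``omega`` default to the baseline η₀, ω₀ (i.e. T = 0).
    """
    rp, dd = config.rumor, config.degree
    eta = rp.eta0 if eta is None else eta
    omega = rp.omega0 if omega is None else omega
    if initial is None:
        initial = RumorState.all_susceptible(dd.n_classes)

    def f(t, y):
        state = RumorState.unpack(y, dd.n_classes)
        return rumor_rhs(state, rp, dd, eta, omega, config.term_mode).pack()

    return _integrate(f, t_start, t_end, initial.pack(), method, rtol, atol, n_per_year)


def run_climate_only(
    config: ModelConfig,
    emissions: EmissionSeries,
    iR_total: float = 0.0,
    spinup_state: CarbonTempState | None = None,
    method: str = "lsoda",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_per_year: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate carbon and temperature alone at a frozen rejector fraction.

    Returns (times, array (n_times, 2) of [C, T]) over the scenario window.
    """
    cp = config.climate
    if spinup_state is None:
        spinup_state = spin_up(emissions, cp, config.spinup_start, config.sink_in_spinup)

    def f(t, y):
        C, T = y
        dC = cp.E2021 * math.exp(-cp.Psi * iR_total) - cp.delta * C
        dT = temperature_rhs(T, radiative_forcing(C, cp), cp, config.temperature_mode)
        return np.array([dC, dT])

    return _integrate(
        f,
        float(config.rumor_start),
        float(config.horizon_end),
        np.array([spinup_state.C, spinup_state.T]),
        method,
        rtol,
        atol,
        n_per_year,
    )
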