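"""Sensitivity instruments over the coupled scenario.

Three one-at-a-time/two-at-a-time designs, each a thin orchestration of
:func:`socioclimate.coupling.run_scenario` with named overrides:

* univariate sweeps — one parameter over a grid, recording each output
  series at its peak, in 2050 and in 2200;
* parameter planes — two parameters on a grid product, with emissions,
  temperature and rejector matrices at snapshot years;
* tornado — ±fraction perturbations of a parameter list, ranked by the
  span of the 2200 temperature anomaly.

Cells are independent and reproducible in isolation; outputs convert to
tidy long-format tables for external plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, set_param
from .coupling import ScenarioResult, run_scenario
from .earth_system import CarbonTempState, EmissionSeries, spin_up

__all__ = [
    "SweepResult",
    "PlaneResult",
    "TornadoResult",
    "univariate_sweep",
    "parameter_plane",
    "tornado",
]

OUTPUT_SERIES = ("s", "h", "iB", "iR", "emissions", "T")
_SPINUP_FIELDS = {"q", "d", "F2x", "C0", "gt_per_ppm", "delta"}

logger = logging.getLogger(__name__)


def _try_run(cfg: ModelConfig, emissions: EmissionSeries, spinup) -> ScenarioResult | None:
    """Run one cell; failed integrations (the model can blow up in corners
    of parameter space) yield None and are reported as NaN."""
    try:
        return run_scenario(cfg, emissions, spinup_state=spinup)
    except (RuntimeError, ValueError, OverflowError) as exc:
        logger.warning("scenario failed for one grid cell: %s", exc)
        return None


def _cached_spinup(config: ModelConfig, emissions: EmissionSeries, varied: set[str]):
    """Spin-up is rumor-independent; reuse it unless a varied parameter
    reaches the historical window."""
    if varied & _SPINUP_FIELDS:
        return None
    return spin_up(emissions, config.climate, config.spinup_start, config.sink_in_spinup)


def _peak(result: ScenarioResult, series: str) -> tuple[float, float]:
    """Maximum over the scenario window and the (earliest) year it occurs."""
    values = getattr(result, series)
    idx = int(np.argmax(values))
    return float(values[idx]), float(result.times[idx])


@dataclass
class SweepResult:
    param: str
    grid: np.ndarray
    records: pd.DataFrame  # long format: value, output, peak, peak_year, at_2050, at_2200

    def to_frame(self) -> pd.DataFrame:
        return self.records


@dataclass
class PlaneResult:
    param1: str
    param2: str
    grid1: np.ndarray
    grid2: np.ndarray
    snapshots: tuple[int, ...]
    emissions: dict[int, np.ndarray]  # snapshot -> (len(grid1), len(grid2))
    T: dict[int, np.ndarray]
    iR: dict[int, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for snap in self.snapshots:
            for i, v1 in enumerate(self.grid1):
                for j, v2 in enumerate(self.grid2):
                    for name, mat in (
                        ("emissions", self.emissions),
                        ("T", self.T),
                        ("iR", self.iR),
                    ):
                        rows.append(
                            {
                                self.param1: v1,
                                self.param2: v2,
                                "snapshot": snap,
                                "output": name,
                                "value": mat[snap][i, j],
                            }
                        )
        return pd.DataFrame(rows)


@dataclass
class TornadoResult:
    baseline_T: float
    outcome_year: int
    rows: pd.DataFrame  # param, T_minus, T_plus, span

    def to_frame(self) -> pd.DataFrame:
        return self.rows

    def ranking(self) -> list[str]:
        return list(self.rows.sort_values("span", ascending=False)["param"])


def univariate_sweep(
    param: str,
    grid,
    baseline: ModelConfig,
    emissions: EmissionSeries,
    snapshots: tuple[int, ...] = (2050, 2200),
) -> SweepResult:
    """One full scenario per grid value of ``param``, all else at baseline.

    For each output series the record keeps the post-rumor-start peak
    (value and year) and the value at each snapshot year (columns
    ``at_<year>``, default mid-century and end-of-horizon).  Varying ``X``
    or ``m_bar`` recomputes the group degree Ḡ = X·m̄/N.
    """
    grid = np.asarray(grid, dtype=float)
    spinup = _cached_spinup(baseline, emissions, {param})
    rows = []
    for value in grid:
        cfg = set_param(baseline, param, float(value))
        result = _try_run(cfg, emissions, spinup)
        for series in OUTPUT_SERIES:
            if result is None:
                peak = peak_year = float("nan")
                at = {y: float("nan") for y in snapshots}
            else:
                peak, peak_year = _peak(result, series)
                at = {y: result.at(y, series) for y in snapshots}
            rows.append(
                {
                    "param": param,
                    "value": float(value),
                    "output": series,
                    "peak": peak,
                    "peak_year": peak_year,
                    **{f"at_{y}": at[y] for y in snapshots},
                }
            )
    return SweepResult(param=param, grid=grid, records=pd.DataFrame(rows))


def parameter_plane(
    param1: str,
    param2: str,
    grid1,
    grid2,
    baseline: ModelConfig,
    emissions: EmissionSeries,
    snapshots: tuple[int, ...] = (2021, 2070, 2200),
) -> PlaneResult:
    """Grid product of two parameters; emissions, temperature and rejector
    matrices at each snapshot year."""
    if param1 == param2:
        raise ValueError("parameter_plane requires two distinct parameters")
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    spinup = _cached_spinup(baseline, emissions, {param1, param2})
    shape = (grid1.size, grid2.size)
    emis = {s: np.empty(shape) for s in snapshots}
    temp = {s: np.empty(shape) for s in snapshots}
    rej = {s: np.empty(shape) for s in snapshots}
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            cfg = set_param(set_param(baseline, param1, float(v1)), param2, float(v2))
            result = _try_run(cfg, emissions, spinup)
            for s in snapshots:
                emis[s][i, j] = result.at(s, "emissions") if result else float("nan")
                temp[s][i, j] = result.at(s, "T") if result else float("nan")
                rej[s][i, j] = result.at(s, "iR") if result else float("nan")
    return PlaneResult(param1, param2, grid1, grid2, tuple(snapshots), emis, temp, rej)


def tornado(
    baseline: ModelConfig,
    params: list[str],
    emissions: EmissionSeries,
    fraction: float = 0.10,
    outcome_year: int = 2200,
) -> TornadoResult:
    """±``fraction`` one-at-a-time perturbations ranked by the span of the
    temperature anomaly at ``outcome_year``.

    Probability parameters pushed outside [0, 1] are clamped (with the
    clamp logged by :func:`socioclimate.config.set_param`), matching the
    ability to perturb near-boundary baselines.
    """
    if fraction < 0:
        raise ValueError("fraction must be nonnegative")
    spinup = _cached_spinup(baseline, emissions, set(params))
    base_result = run_scenario(baseline, emissions, spinup_state=spinup)
    base_T = base_result.at(outcome_year, "T")
    rows = []
    for name in params:
        value = _baseline_value(baseline, name)
        outcomes = {}
        for sign, factor in (("minus", 1 - fraction), ("plus", 1 + fraction)):
            cfg = set_param(baseline, name, value * factor, clamp_probabilities=True)
            sp = spinup if name not in _SPINUP_FIELDS else None
            result = run_scenario(cfg, emissions, spinup_state=sp)
            outcomes[sign] = result.at(outcome_year, "T")
        rows.append(
            {
                "param": name,
                "T_minus": outcomes["minus"],
                "T_plus": outcomes["plus"],
                "span": abs(outcomes["plus"] - outcomes["minus"]),
                "baseline_T": base_T,
            }
        )
    return TornadoResult(
        baseline_T=base_T, outcome_year=outcome_year, rows=pd.DataFrame(rows)
    )


def _baseline_value(config: ModelConfig, name: str) -> float:
    if name == "k":
        return config.degree.mean_degree()
    if hasattr(config.rumor, name):
        return getattr(config.rumor, name)
    if hasattr(config.climate, name):
        return getattr(config.climate, name)
    raise KeyError(f"unknown parameter {name!r}")
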