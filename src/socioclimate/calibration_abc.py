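"""Rejection-sampling Approximate Bayesian Computation over model parameters.

Likelihood-free calibration: draw parameter sets from independent uniform
priors, simulate each through the full coupled scenario, summarize the
trajectories, and keep the draws whose summaries fall closest to a target
vector.  Acceptance uses a quantile tolerance (keep the best fraction),
so a run always returns an ensemble; distances are Euclidean after
normalizing each summary entry by the target's scale (or by the
prior-predictive spread when the target entry is zero) to stop
large-magnitude entries from dominating.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig, set_param
from .coupling import ScenarioResult, run_scenario
from .earth_system import CarbonTempState, EmissionSeries, spin_up

__all__ = ["PriorSpec", "AbcResult", "summarize", "abc_rejection"]

# Spin-up depends only on these fields (plus the emission series itself);
# anything else can be perturbed without recomputing the historical run.
_SPINUP_FIELDS = {"q", "d", "F2x", "C0", "gt_per_ppm", "delta"}


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform prior bounds keyed by parameter name."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        probability_params = {
            "beta", "varsigma", "eta0", "omega0", "epsilon",
            "zeta", "alpha", "gamma", "rho", "sigma",
        }
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name!r} must have lower < upper")
            if name in probability_params and not (0.0 <= lo and hi <= 1.0):
                raise ValueError(f"prior for probability {name!r} must lie in [0, 1]")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo = np.array([self.bounds[k][0] for k in self.names])
        hi = np.array([self.bounds[k][1] for k in self.names])
        return lo + (hi - lo) * rng.random((n, len(self.names)))


@dataclass
class AbcResult:
    """Accepted draws of a rejection-ABC run, with full provenance."""

    param_names: list[str]
    accepted: np.ndarray          # (n_accepted, n_params)
    distances: np.ndarray         # (n_accepted,)
    summaries: np.ndarray         # (n_accepted, n_summaries)
    tolerance: float              # distance of the worst accepted draw
    acceptance_rate: float
    seed: int
    all_params: np.ndarray = field(repr=False, default=None)
    all_distances: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.accepted, columns=self.param_names)
        df["distance"] = self.distances
        return df

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {
                "seed": self.seed,
                "acceptance_rate": self.acceptance_rate,
                "tolerance": self.tolerance,
                "n_accepted": int(self.accepted.shape[0]),
                "param_names": self.param_names,
            }
            Path(path).with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    def posterior_histogram(self, name: str, bins: int = 20) -> pd.DataFrame:
        """Histogram of one accepted parameter (plot-ready table)."""
        idx = self.param_names.index(name)
        counts, edges = np.histogram(self.accepted[:, idx], bins=bins)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )


def summarize(result: ScenarioResult, snapshot_years=(2050, 2100, 2200)) -> np.ndarray:
    """Summary vector of one scenario: rejector fraction and temperature
    anomaly at each snapshot year, plus peak emission value and its year
    (earliest year on ties)."""
    for year in snapshot_years:
        if year < result.times[0] or year > result.times[-1]:
            raise ValueError(f"snapshot year {year} outside scenario window")
    peak_idx = int(np.argmax(result.emissions))
    entries = [result.at(y, "iR") for y in snapshot_years]
    entries += [result.at(y, "T") for y in snapshot_years]
    entries += [float(result.emissions[peak_idx]), float(result.times[peak_idx])]
    return np.asarray(entries)


def _distances(summaries: np.ndarray, target: np.ndarray) -> np.ndarray:
    scale = np.abs(target).astype(float)
    zero = scale == 0.0
    if np.any(zero):
        # prior-predictive spread as fallback scale for exactly-zero targets
        spread = summaries.std(axis=0)
        scale[zero] = np.where(spread[zero] > 0, spread[zero], 1.0)
    z = (summaries - target) / scale
    return np.sqrt(np.mean(z**2, axis=1))


def abc_rejection(
    priors: PriorSpec,
    target: np.ndarray,
    baseline: ModelConfig,
    emissions: EmissionSeries,
    n_draws: int = 500,
    quantile: float = 0.01,
    seed: int = 0,
    fixed: dict[str, float] | None = None,
    snapshot_years=(2050, 2100, 2200),
) -> AbcResult:
    """Plain rejection ABC with a quantile acceptance tolerance.

    Parameters not in ``priors`` come from ``fixed`` overrides applied to
    ``baseline``.  Draws failing to simulate are assigned infinite
    distance.  Reproducible for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    target = np.asarray(target, dtype=float)

    base = baseline
    for name, value in (fixed or {}).items():
        base = set_param(base, name, value)

    rng = np.random.default_rng(seed)
    draws = priors.sample(n_draws, rng)

    spinup: CarbonTempState | None = None
    if not (_SPINUP_FIELDS & set(priors.names)) and not (
        _SPINUP_FIELDS & set(fixed or {})
    ):
        spinup = spin_up(emissions, base.climate, base.spinup_start, base.sink_in_spinup)

    summaries = np.full((n_draws, target.size), np.nan)
    ok = np.zeros(n_draws, dtype=bool)
    for i in range(n_draws):
        cfg = base
        for j, name in enumerate(priors.names):
            cfg = set_param(cfg, name, float(draws[i, j]))
        try:
            result = run_scenario(cfg, emissions, spinup_state=spinup)
            summaries[i] = summarize(result, snapshot_years)
            ok[i] = True
        except (RuntimeError, ValueError):
            continue
    if not ok.any():
        raise RuntimeError("all ABC simulations failed")

    dist = np.full(n_draws, np.inf)
    dist[ok] = _distances(summaries[ok], target)

    n_accept = max(1, int(math.ceil(quantile * n_draws)))
    order = np.argsort(dist, kind="stable")
    keep = order[:n_accept]
    keep = keep[np.isfinite(dist[keep])]
    return AbcResult(
        param_names=priors.names,
        accepted=draws[keep],
        distances=dist[keep],
        summaries=summaries[keep],
        tolerance=float(dist[keep].max()),
        acceptance_rate=len(keep) / n_draws,
        seed=seed,
        all_params=draws,
        all_distances=dist,
    )
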