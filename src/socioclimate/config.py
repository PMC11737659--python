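"""Run configuration: parameter bundles, named overrides, flat-file I/O.

A :class:`ModelConfig` carries everything one scenario needs — rumor and
climate parameters, the degree distribution, the population constant N,
mode flags and the time window — and is the unit that the sensitivity and
calibration layers perturb.  Overrides are applied by *name* through
:func:`set_param`, which also encodes the structural rules:

* ``X`` and ``m_bar`` reach the dynamics only through the group degree
  Ḡ = X·m̄/N, so varying either recomputes ``G_bar``;
* ``k`` (the network's mean degree) rebuilds the truncated-power-law
  degree distribution so its first moment matches the requested value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .degree_network import DegreeDistribution, powerlaw_matching_mean
from .earth_system import ClimateParams
from .rumor_dynamics import RumorParams

__all__ = ["ModelConfig", "baseline_config", "set_param", "parameter_names"]

_RUMOR_FIELDS = {f.name for f in dataclasses.fields(RumorParams)}
_CLIMATE_FIELDS = {f.name for f in dataclasses.fields(ClimateParams)}
_PROB_FIELDS = {
    "beta", "varsigma", "eta0", "omega0", "epsilon",
    "zeta", "alpha", "gamma", "rho", "sigma",
}

DEFAULT_MEAN_DEGREE = 10.0
DEFAULT_K_MIN = 1
DEFAULT_K_MAX = 20
DEFAULT_POPULATION = 10_000.0


@dataclass(frozen=True)
class ModelConfig:
    rumor: RumorParams = field(default_factory=RumorParams)
    climate: ClimateParams = field(default_factory=ClimateParams)
    degree: DegreeDistribution = field(
        default_factory=lambda: powerlaw_matching_mean(
            DEFAULT_MEAN_DEGREE, DEFAULT_K_MIN, DEFAULT_K_MAX
        )
    )
    population: float = DEFAULT_POPULATION
    closure_mode: str = "uncorrelated"
    term_mode: str = "standard"          # "standard" | "literal"
    temperature_mode: str = "box"        # "box" | "literal"
    aggregate_mode: str = "weighted"     # "weighted" | "sum"
    sink_in_spinup: bool = False
    spinup_start: int = 1850
    rumor_start: int = 2021
    horizon_end: int = 2200
    # Believer fraction seeded into every degree class at rumor onset; the
    # all-susceptible state is a fixed point, so 0 freezes the rumor.
    rumor_seed: float = 0.01

    def with_updates(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)

    # -- flat serialization ------------------------------------------------

    def to_flat_dict(self) -> dict:
        out = {f"rumor.{k}": v for k, v in dataclasses.asdict(self.rumor).items()}
        out.update({f"climate.{k}": v for k, v in dataclasses.asdict(self.climate).items()})
        out.update(
            {
                "degree.mean": self.degree.mean_degree(),
                "degree.k_min": int(self.degree.degrees[0]),
                "degree.k_max": int(self.degree.degrees[-1]),
                "population": self.population,
                "closure_mode": self.closure_mode,
                "term_mode": self.term_mode,
                "temperature_mode": self.temperature_mode,
                "aggregate_mode": self.aggregate_mode,
                "sink_in_spinup": self.sink_in_spinup,
                "spinup_start": self.spinup_start,
                "rumor_start": self.rumor_start,
                "horizon_end": self.horizon_end,
                "rumor_seed": self.rumor_seed,
            }
        )
        return out

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "ModelConfig":
        base = cls()
        rumor = base.rumor.with_updates(
            **{k.split(".", 1)[1]: v for k, v in flat.items() if k.startswith("rumor.")}
        )
        climate = base.climate.with_updates(
            **{k.split(".", 1)[1]: v for k, v in flat.items() if k.startswith("climate.")}
        )
        degree = powerlaw_matching_mean(
            flat.get("degree.mean", DEFAULT_MEAN_DEGREE),
            int(flat.get("degree.k_min", DEFAULT_K_MIN)),
            int(flat.get("degree.k_max", DEFAULT_K_MAX)),
        )
        simple = {
            k: flat[k]
            for k in (
                "population", "closure_mode", "term_mode", "temperature_mode",
                "aggregate_mode", "sink_in_spinup", "spinup_start",
                "rumor_start", "horizon_end", "rumor_seed",
            )
            if k in flat
        }
        return base.with_updates(rumor=rumor, climate=climate, degree=degree, **simple)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_flat_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        return cls.from_flat_dict(yaml.safe_load(Path(path).read_text()))

    def to_json_sidecar(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_flat_dict(), indent=2, sort_keys=True))


def baseline_config() -> ModelConfig:
    """The package's baseline study conditions (see docs/methods.md)."""
    return ModelConfig()


def parameter_names() -> list[str]:
    """Names accepted by :func:`set_param`."""
    return sorted(_RUMOR_FIELDS | _CLIMATE_FIELDS | {"k"})


def set_param(
    config: ModelConfig, name: str, value: float, clamp_probabilities: bool = False
) -> ModelConfig:
    """Return a new config with one named parameter overridden.

    ``clamp_probabilities`` clips probability parameters into [0, 1]
    instead of erroring (used by the tornado analysis, which perturbs
    near-boundary baselines multiplicatively).
    """
    if clamp_probabilities and name in _PROB_FIELDS and not 0.0 <= value <= 1.0:
        clamped = min(1.0, max(0.0, value))
        logging.getLogger(__name__).warning(
            "probability %s=%.4g clamped to %.4g", name, value, clamped
        )
        value = clamped
    if name == "k":
        k_min = int(config.degree.degrees[0])
        k_max = int(config.degree.degrees[-1])
        return config.with_updates(degree=powerlaw_matching_mean(value, k_min, k_max))
    if name in _RUMOR_FIELDS:
        updates = {name: value}
        if name in ("X", "m_bar"):
            X = value if name == "X" else config.rumor.X
            m = value if name == "m_bar" else config.rumor.m_bar
            updates["G_bar"] = X * m / config.population
        return config.with_updates(rumor=config.rumor.with_updates(**updates))
    if name in _CLIMATE_FIELDS:
        return config.with_updates(climate=config.climate.with_updates(**{name: value}))
    raise KeyError(f"unknown parameter {name!r}; known: {parameter_names()}")
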