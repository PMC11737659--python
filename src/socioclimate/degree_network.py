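"""Statistical representation of the heterogeneous contact network.

The rumor model never tracks an explicit graph; nodes are grouped into
degree classes and interact through the edge-following conditional
probability p(j|k) (the probability that an edge attached to a degree-k
node leads to a degree-j node).  For uncorrelated networks this closure is

    p(j|k) = j * p_j / <k>,

independent of k.  This module holds the degree distribution, its moments,
and the closure kernel used by the mean-field equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "DegreeDistribution",
    "make_truncated_powerlaw",
    "powerlaw_matching_mean",
    "mean_degree",
    "conditional_degree_prob",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class DegreeDistribution:
    """Discrete degree distribution over a finite support.

    Parameters
    ----------
    degrees
        Strictly increasing distinct node degrees, all >= 1.
    probs
        Probability of each degree; nonnegative, summing to 1 within 1e-12.
    """

    degrees: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        deg = np.asarray(self.degrees, dtype=float)
        pr = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "degrees", deg)
        object.__setattr__(self, "probs", pr)
        if deg.ndim != 1 or pr.ndim != 1 or deg.size != pr.size or deg.size == 0:
            raise ValueError("degrees and probs must be equal-length 1-D arrays")
        if np.any(deg < 1) or np.any(deg != np.round(deg)):
            raise ValueError("degrees must be positive integers")
        if np.any(np.diff(deg) <= 0):
            raise ValueError("degrees must be strictly increasing")
        if np.any(pr < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(pr.sum() - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities must sum to 1 (got {pr.sum()!r})")

    @property
    def n_classes(self) -> int:
        return int(self.degrees.size)

    def mean_degree(self) -> float:
        """First moment <k> = sum_k k p_k."""
        return float(np.dot(self.degrees, self.probs))

    def second_moment(self) -> float:
        """<k^2>, controls the neighbor-degree bias <k^2>/<k>."""
        return float(np.dot(self.degrees**2, self.probs))

    def neighbor_weights(self, term_mode: str = "standard") -> np.ndarray:
        """Closure weights w_j such that the contact sum is w . x.

        ``standard`` gives w_j = j p_j / <k>  (so sum_j w_j = 1).
        ``literal`` keeps the extra p_j factor that appears in the printed
        degree-block equations: w_j = j p_j^2 / <k>.
        """
        base = self.degrees * self.probs / self.mean_degree()
        if term_mode == "standard":
            return base
        if term_mode == "literal":
            return base * self.probs
        raise ValueError(f"unknown term_mode {term_mode!r}")

    # -- serialization -----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"degree": self.degrees.astype(int), "probability": self.probs}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DegreeDistribution":
        df = pd.read_csv(path)
        return cls(df["degree"].to_numpy(), df["probability"].to_numpy())


def make_truncated_powerlaw(exponent: float, k_min: int, k_max: int) -> DegreeDistribution:
    """Truncated power-law degree distribution p_k ∝ k^(-exponent) on [k_min, k_max].

    ``exponent = 0`` degenerates to the uniform distribution.  Deterministic.
    """
    if k_min > k_max:
        raise ValueError(f"k_min ({k_min}) must not exceed k_max ({k_max})")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if exponent < 0:
        raise ValueError("exponent must be nonnegative")
    degrees = np.arange(int(k_min), int(k_max) + 1, dtype=float)
    weights = degrees**(-float(exponent))
    return DegreeDistribution(degrees, weights / weights.sum())


def powerlaw_matching_mean(
    target_mean: float, k_min: int = 1, k_max: int = 20
) -> DegreeDistribution:
    """Truncated power law whose exponent is solved so <k> equals ``target_mean``.

    Used to pin the network's mean degree (a named model parameter) while
    retaining a heavy-tailed class structure.  The attainable range is
    (k_min, uniform mean]; the exponent is found by bisection.
    """
    if not (k_min < target_mean <= (k_min + k_max) / 2):
        raise ValueError(
            f"target mean {target_mean} not attainable on [{k_min}, {k_max}] "
            "with a nonnegative exponent"
        )

    def gap(expo: float) -> float:
        return make_truncated_powerlaw(expo, k_min, k_max).mean_degree() - target_mean

    expo = brentq(gap, 0.0, 50.0, xtol=1e-12)
    return make_truncated_powerlaw(expo, k_min, k_max)


def mean_degree(dd: DegreeDistribution) -> float:
    """Functional alias for :meth:`DegreeDistribution.mean_degree`."""
    return dd.mean_degree()


def conditional_degree_prob(
    dd: DegreeDistribution, j: int, k: int, mode: str = "uncorrelated"
) -> float:
    """Edge-following probability p(j|k).

    In the uncorrelated closure p(j|k) = j p_j / <k>, independent of k; the
    ``k`` argument is validated against the support so correlated closures
    can slot in later.
    """
    if mode != "uncorrelated":
        raise ValueError(f"unknown closure mode {mode!r}")
    degs = dd.degrees
    if j not in degs or k not in degs:
        raise ValueError(f"degree {j if j not in degs else k} not in support")
    idx = int(np.searchsorted(degs, j))
    return float(degs[idx] * dd.probs[idx] / dd.mean_degree())
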