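"""Degree-structured rumor contagion with individual and group channels.

Four compartments per degree class k (fractions of the class):

* ``s``  — susceptible: has not met the rumor;
* ``h``  — hesitator: met the rumor, still deciding;
* ``iB`` — believer: accepts the climate-denying rumor and forwards it;
* ``iR`` — rejector: dismisses the rumor and acts as a mitigator.

The individual channel moves mass at rates proportional to c̄·k times a
contact sum over neighboring classes (the degree-block closure from
:mod:`socioclimate.degree_network`).  The group channel broadcasts through
the coefficient Ḡ·m̄·d̄ acting on local class densities.  Network turnover
enters as a joining flow B into ``s`` and an exit rate μ from every
compartment.  The believing probabilities η, ω are supplied by the caller
(the coupling layer evaluates them at the current temperature anomaly).

The equations are implemented exactly as the source model prints them,
including two idiosyncrasies kept deliberately: the believer-forgetting
and hesitator-resolution fluxes are driven by the *neighborhood* densities
(contact sums over iB_j and h_j) rather than the class's own density, and
the rejector-forgetting term γ·c̄·k·iR_k carries no contact sum.  Both
choices cancel in the per-class total, so mass is conserved when B = μ = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import root

from .degree_network import DegreeDistribution

__all__ = [
    "RumorParams",
    "RumorState",
    "contact_term",
    "rumor_rhs",
    "aggregate",
    "find_equilibrium",
    "EquilibriumResult",
]

_PROB_FIELDS = (
    "beta",
    "varsigma",
    "eta0",
    "omega0",
    "epsilon",
    "zeta",
    "alpha",
    "gamma",
    "rho",
    "sigma",
)


@dataclass(frozen=True)
class RumorParams:
    """Social parameters of the rumor system (rates per year).

    Probabilities are dimensionless in [0, 1]; B and μ are network
    turnover rates; c̄ is the average individual contact rate; d̄ the
    average messages transmitted per group; Ḡ the average number of
    groups an individual belongs to; X the total number of groups and m̄
    the average group size (these reach the dynamics only through Ḡ, see
    :func:`socioclimate.config.set_param`); v is the temperature
    sensitivity of believing (per °C).
    """

    B: float = 0.01
    mu: float = 0.01
    beta: float = 0.3
    varsigma: float = 0.3
    eta0: float = 0.2
    omega0: float = 0.2
    epsilon: float = 0.3
    zeta: float = 0.3
    alpha: float = 0.05
    gamma: float = 0.01
    rho: float = 0.05
    sigma: float = 0.01
    c_bar: float = 27.0
    d_bar: float = 1.0
    G_bar: float = 0.28
    X: float = 40.0
    m_bar: float = 70.0
    v: float = 0.2

    def __post_init__(self) -> None:
        for name in _PROB_FIELDS:
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        for name in ("B", "mu", "c_bar", "d_bar", "G_bar", "v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.X < 1:
            raise ValueError("X must be >= 1")
        if self.m_bar < 1:
            raise ValueError("m_bar must be >= 1")

    @property
    def group_coefficient(self) -> float:
        """Ḡ·m̄·d̄ — the broadcast rate multiplying every group-channel term."""
        return self.G_bar * self.m_bar * self.d_bar

    def with_updates(self, **kwargs: float) -> "RumorParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RumorState:
    """Per-degree-class compartment fractions aligned with a DegreeDistribution."""

    s: np.ndarray
    h: np.ndarray
    iB: np.ndarray
    iR: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("s", "h", "iB", "iR"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError("compartment arrays must share length")
            arrays[name] = arr
            object.__setattr__(self, name, arr)
        if any(np.any(a < 0) for a in arrays.values()):
            raise ValueError("compartment fractions must be nonnegative")

    @property
    def n_classes(self) -> int:
        return int(self.s.size)

    @classmethod
    def all_susceptible(cls, n_classes: int) -> "RumorState":
        z = np.zeros(n_classes)
        return cls(np.ones(n_classes), z.copy(), z.copy(), z.copy())

    @classmethod
    def seeded(cls, n_classes: int, believer_seed: float = 0.01) -> "RumorState":
        """All-susceptible state with a small believer fraction in every
        class (the all-susceptible state is itself an equilibrium, so a
        rumor outbreak needs a seed; seed 0 gives the literal state)."""
        if not 0.0 <= believer_seed < 1.0:
            raise ValueError("believer_seed must lie in [0, 1)")
        z = np.zeros(n_classes)
        return cls(
            np.full(n_classes, 1.0 - believer_seed),
            z.copy(),
            np.full(n_classes, believer_seed),
            z.copy(),
        )

    def pack(self) -> np.ndarray:
        return np.concatenate([self.s, self.h, self.iB, self.iR])

    @classmethod
    def unpack(cls, y: np.ndarray, n_classes: int) -> "RumorState":
        y = np.asarray(y, dtype=float)
        s, h, iB, iR = (y[i * n_classes : (i + 1) * n_classes] for i in range(4))
        obj = cls.__new__(cls)
        for name, arr in zip(("s", "h", "iB", "iR"), (s, h, iB, iR)):
            object.__setattr__(obj, name, arr)
        return obj

    def per_class_total(self) -> np.ndarray:
        return self.s + self.h + self.iB + self.iR


def contact_term(
    x: np.ndarray, dd: DegreeDistribution, term_mode: str = "standard"
) -> float:
    """Contact sum Θ = Σ_j p(j|k)·x_j under the uncorrelated closure.

    Independent of k, so a scalar is returned.  ``literal`` mode keeps the
    extra p_j factor of the printed equations.
    """
    x = np.asarray(x, dtype=float)
    if x.size != dd.n_classes:
        raise ValueError("state vector not aligned with degree distribution")
    return float(np.dot(dd.neighbor_weights(term_mode), x))


def aggregate(x: np.ndarray, dd: DegreeDistribution, mode: str = "weighted") -> float:
    """Population-level fraction of a per-class quantity.

    ``weighted`` (default) is Σ_k p_k·x_k, bounded in [0, 1] for fractional
    x; ``sum`` is the literal unweighted Σ_k x_k, whose value depends on
    the number of degree classes and is provided for sensitivity checks.
    """
    x = np.asarray(x, dtype=float)
    if x.size != dd.n_classes:
        raise ValueError("state vector not aligned with degree distribution")
    if mode == "weighted":
        return float(np.dot(dd.probs, x))
    if mode == "sum":
        return float(x.sum())
    raise ValueError(f"unknown aggregate mode {mode!r}")


def rumor_rhs(
    state: RumorState,
    params: RumorParams,
    dd: DegreeDistribution,
    eta: float,
    omega: float,
    term_mode: str = "standard",
) -> RumorState:
    """Time derivatives of the four compartments for every degree class.

    ``eta`` and ``omega`` are the believing probabilities already evaluated
    at the current temperature.
    """
    if not (0.0 <= eta <= 1.0 and 0.0 <= omega <= 1.0):
        raise ValueError("eta and omega must lie in [0, 1]")
    if state.n_classes != dd.n_classes:
        raise ValueError("state not aligned with degree distribution")
    p = params
    k = dd.degrees
    w = dd.neighbor_weights(term_mode)
    theta_iB = float(np.dot(w, state.iB))
    theta_h = float(np.dot(w, state.h))
    ck = p.c_bar * k
    g = p.group_coefficient

    s, h, iB, iR = state.s, state.h, state.iB, state.iR
    ds = (
        p.B
        - p.beta * ck * s * theta_iB
        + p.alpha * ck * theta_iB
        + p.gamma * ck * iR
        - g * p.varsigma * s * iB
        + g * p.sigma * iR
        + g * p.rho * iB
        - p.mu * s
    )
    dh = (
        p.beta * ck * s * theta_iB
        - (eta + p.epsilon) * ck * theta_h
        + g * p.varsigma * s * iB
        - g * omega * h
        - g * p.zeta * h
        - p.mu * h
    )
    diB = (
        eta * ck * theta_h
        - p.alpha * ck * theta_iB
        + g * omega * h
        - g * p.rho * iB
        - p.mu * iB
    )
    diR = (
        p.epsilon * ck * theta_h
        - p.gamma * ck * iR
        + g * p.zeta * h
        - g * p.sigma * iR
        - p.mu * iR
    )
    out = RumorState.__new__(RumorState)
    for name, arr in zip(("s", "h", "iB", "iR"), (ds, dh, diB, diR)):
        object.__setattr__(out, name, np.asarray(arr, dtype=float))
    return out


def _packed_rhs(
    y: np.ndarray,
    params: RumorParams,
    dd: DegreeDistribution,
    eta: float,
    omega: float,
    term_mode: str,
) -> np.ndarray:
    state = RumorState.unpack(y, dd.n_classes)
    deriv = rumor_rhs(state, params, dd, eta, omega, term_mode)
    return deriv.pack()


class EquilibriumResult(NamedTuple):
    state: RumorState
    residual: float
    leading_eigenvalue_real: float
    stable: bool


def numerical_jacobian(
    y: np.ndarray,
    params: RumorParams,
    dd: DegreeDistribution,
    eta: float,
    omega: float,
    term_mode: str = "standard",
    step: float = 1e-7,
) -> np.ndarray:
    """Central finite-difference Jacobian of the packed rumor vector field."""
    n = y.size
    jac = np.empty((n, n))
    for i in range(n):
        dy = np.zeros(n)
        dy[i] = step
        f_plus = _packed_rhs(y + dy, params, dd, eta, omega, term_mode)
        f_minus = _packed_rhs(y - dy, params, dd, eta, omega, term_mode)
        jac[:, i] = (f_plus - f_minus) / (2 * step)
    return jac


def find_equilibrium(
    params: RumorParams,
    dd: DegreeDistribution,
    eta: float,
    omega: float,
    guess: RumorState,
    term_mode: str = "standard",
    residual_tol: float = 1e-10,
) -> EquilibriumResult:
    """Numerical fixed point of the rumor system at frozen η, ω.

    Solves rumor_rhs = 0 from ``guess`` and reports the real part of the
    Jacobian's leading eigenvalue as a local stability verdict.  Raises
    ``RuntimeError`` when the residual does not reach ``residual_tol``.
    """
    sol = root(
        _packed_rhs,
        guess.pack(),
        args=(params, dd, eta, omega, term_mode),
        method="hybr",
        tol=1e-13,
    )
    residual = float(np.max(np.abs(_packed_rhs(sol.x, params, dd, eta, omega, term_mode))))
    if residual > residual_tol:
        raise RuntimeError(
            f"equilibrium search did not converge (max |rhs| = {residual:.3e})"
        )
    jac = numerical_jacobian(sol.x, params, dd, eta, omega, term_mode)
    lead = float(np.max(np.linalg.eigvals(jac).real))
    state = RumorState.unpack(np.clip(sol.x, 0.0, None), dd.n_classes)
    return EquilibriumResult(state, residual, lead, lead < 0.0)
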