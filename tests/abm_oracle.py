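"""Stochastic agent-based oracle for the degree-block mean-field equations.

Simulates the individual rumor channel on an explicit configuration-model
graph with the same per-contact transition structure as the ODE system
(group channel and turnover off):

* susceptible -> hesitator        at rate β·c̄·(# believer neighbors)
* hesitator  -> believer/rejector at rate (η+ε)·c̄·(own degree), split η : ε
* believer   -> susceptible       at rate α·c̄·(own degree)
* rejector   -> susceptible       at rate γ·c̄·(own degree)

Each individual makes c̄ contacts per unit time along each of its edges;
exposure requires the contacted neighbor to be a believer, while
resolution and forgetting fire per contact regardless of the contact's
state.  The ODE's resolution/forgetting fluxes are written against the
degree-biased neighborhood densities Θ rather than the class's own
density; summed over classes both formulations give the identical
population flux (Σ_k p_k·k·x_k = ⟨k⟩·Θ_x), so the aggregate compartments
— what the fidelity check compares — follow the same mean-field limit.

Two contact structures are provided.  ``annealed`` (the fidelity oracle)
redraws the contacted partner at every event with the edge-following
probability p(j) ∝ j·p_j — exactly the closure the ODE assumes — so the
only deviations left are finite population size and stochasticity.
``quenched`` wires a static configuration-model graph and additionally
carries the pair correlations that the mean-field closure neglects; it
is kept for measuring that structural gap.

Discrete-time binomial stepping with step dt; rates are small enough in
the test configurations that first-order exponential probabilities are
accurate.  Entirely test-harness code: the package itself never builds
explicit graphs.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy import sparse

S, H, B, R = 0, 1, 2, 3


def build_configuration_graph(
    degrees: np.ndarray, probs: np.ndarray, n_nodes: int, rng: np.random.Generator
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Configuration-model adjacency for a degree distribution.

    Self-loops and parallel edges are discarded, so realized degrees are
    approximately the requested sequence (the standard simple-graph
    projection).  Returns (adjacency, realized degree per node).
    """
    seq = rng.choice(degrees.astype(int), size=n_nodes, p=probs)
    if seq.sum() % 2:  # configuration model needs an even stub count
        seq[0] += 1
    g = nx.configuration_model(seq, seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # collapse parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))
    adj = nx.to_scipy_sparse_array(g, format="csr", dtype=np.int8)
    realized = np.asarray(adj.sum(axis=1)).ravel()
    return sparse.csr_matrix(adj), realized


def simulate_abm(
    adj: sparse.csr_matrix | None,
    degrees: np.ndarray,
    params,
    eta: float,
    t_end: float,
    dt: float,
    believer_seed: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """One stochastic run; returns final compartment fractions.

    ``adj`` None selects the annealed contact structure: the probability
    that any given contact hits a believer is the empirical stub-weighted
    believer fraction Σ_{i∈B} k_i / Σ_i k_i (edge-following sampling).
    Otherwise contacts run along the fixed graph ``adj``.
    """
    n = degrees.size
    state = np.full(n, S, dtype=np.int8)
    n_seed = max(1, int(round(believer_seed * n)))
    state[rng.choice(n, size=n_seed, replace=False)] = B
    c = params.c_bar
    total_stubs = float(degrees.sum())
    n_steps = int(round(t_end / dt))
    p_resolve = 1.0 - np.exp(-(eta + params.epsilon) * c * degrees * dt)
    p_forget_b = 1.0 - np.exp(-params.alpha * c * degrees * dt)
    p_forget_r = 1.0 - np.exp(-params.gamma * c * degrees * dt)
    for _ in range(n_steps):
        if adj is None:
            theta_b = float(degrees[state == B].sum()) / total_stubs
            n_b = degrees * theta_b  # expected believer contacts per unit c·dt
        else:
            n_b = adj @ (state == B).astype(np.int8)
        u = rng.random(n)
        new_state = state.copy()

        sus = state == S
        p_expose = 1.0 - np.exp(-params.beta * c * n_b * dt)
        new_state[sus & (u < p_expose)] = H

        hes = state == H
        resolving = hes & (u < p_resolve)
        to_believer = rng.random(n) < eta / (eta + params.epsilon)
        new_state[resolving & to_believer] = B
        new_state[resolving & ~to_believer] = R

        bel = state == B
        new_state[bel & (u < p_forget_b)] = S

        rej = state == R
        new_state[rej & (u < p_forget_r)] = S

        state = new_state
    return {
        "s": float(np.mean(state == S)),
        "h": float(np.mean(state == H)),
        "iB": float(np.mean(state == B)),
        "iR": float(np.mean(state == R)),
    }


def abm_final_rejectors(
    degrees: np.ndarray,
    probs: np.ndarray,
    params,
    eta: float,
    n_nodes: int = 2000,
    n_reps: int = 50,
    t_end: float = 25.0,
    dt: float = 0.02,
    believer_seed: float = 0.05,
    seed: int = 0,
    contact_structure: str = "annealed",
) -> float:
    """Mean final rejector fraction over ``n_reps`` independent runs."""
    rng = np.random.default_rng(seed)
    totals = []
    for _ in range(n_reps):
        if contact_structure == "annealed":
            realized = rng.choice(degrees.astype(int), size=n_nodes, p=probs).astype(float)
            adj = None
        elif contact_structure == "quenched":
            adj, realized = build_configuration_graph(degrees, probs, n_nodes, rng)
        else:
            raise ValueError(f"unknown contact structure {contact_structure!r}")
        out = simulate_abm(adj, realized, params, eta, t_end, dt, believer_seed, rng)
        totals.append(out["iR"])
    return float(np.mean(totals))
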