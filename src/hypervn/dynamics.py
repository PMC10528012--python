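"""Discrete-time nonlinear SIR contagion on hypergraphs.

Nodes are susceptible (S), infected (I) or recovered (R).  At each step a
susceptible node is infected through each incident hyperedge ``e_j`` with
rate ``β(r_j, η_j) = α · η_j^κ``, where ``η_j`` counts the *infected* members
of the hyperedge (recovered members do not transmit); ``κ = 1`` recovers
linear per-contact transmission.  Rates from multiple incident hyperedges
add, and the sum is clamped at 1 to remain a Bernoulli probability (at the
α scale of interest the clamp is essentially never active).  Infected nodes
recover independently with probability ``γ``; recovery is absorbing.

Updates are synchronous: all η counts and infection probabilities use the
start-of-step state, and a node infected in a step cannot recover in that
same step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypergraph import Hypergraph

S, I, R = 0, 1, 2


@dataclass(frozen=True)
class SIRTrajectory:
    """Per-step compartment counts of one stochastic run.

    ``prevalence[t] = (|I| + |R|)/N`` is non-decreasing because recovery is
    absorbing; index 0 is the seeded initial state.
    """

    s_counts: np.ndarray
    i_counts: np.ndarray
    r_counts: np.ndarray
    prevalence: np.ndarray
    seed_nodes: tuple[str, ...]
    rng_seed: "int | None" = None

    @property
    def num_steps(self) -> int:
        return len(self.prevalence) - 1


@dataclass(frozen=True)
class InfluenceResult:
    """Mean final prevalence over repeated runs, with per-run values."""

    mean: float
    per_run: np.ndarray

    @property
    def std_error(self) -> float:
        n = len(self.per_run)
        return float(self.per_run.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0


def infection_probability(h: Hypergraph, status: np.ndarray, node: str,
                          alpha: float, kappa: float) -> float:
    """Per-step infection probability of a susceptible node.

    ``min(1, Σ_{e_j ∋ node} α · η_j^κ)`` over incident hyperedges with at
    least one infected member.
    """
    i = h.node_index(node)
    if status[i] != S:
        raise ValueError(f"node {node!r} is not susceptible")
    total = 0.0
    for j in h.incident_edges(node):
        eta = int(sum(status[k] == I for k in h.member_indices(j)))
        if eta > 0:
            total += alpha * eta ** kappa
    return min(1.0, total)


def _step(B: np.ndarray, status: np.ndarray, alpha: float, kappa: float,
          gamma: float, rng: np.random.Generator) -> np.ndarray:
    """One synchronous update; B is the M×N incidence matrix."""
    infected = (status == I).astype(float)
    eta = B @ infected
    kernel = np.zeros_like(eta)
    active = eta > 0
    kernel[active] = alpha * eta[active] ** kappa
    pressure = np.minimum(1.0, B.T @ kernel)
    # Fixed node-order draws keep trajectories bit-identical for a given seed.
    u_inf = rng.random(status.shape[0])
    u_rec = rng.random(status.shape[0])
    new_status = status.copy()
    new_status[(status == S) & (u_inf < pressure)] = I
    new_status[(status == I) & (u_rec < gamma)] = R
    return new_status


def sir_step(h: Hypergraph, status: np.ndarray, alpha: float, kappa: float,
             gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Advance one step from a compartment array (values in {0:S, 1:I, 2:R})."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return _step(h.incidence_matrix().astype(float), np.asarray(status), alpha,
                 kappa, gamma, rng)


def simulate(h: Hypergraph, seeds, alpha: float, kappa: float, gamma: float,
             t_max: int, rng: "np.random.Generator | int") -> SIRTrajectory:
    """Run one stochastic trajectory for ``t_max`` steps from seed nodes."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed set must be non-empty")
    rng_seed = rng if isinstance(rng, (int, np.integer)) else None
    if rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
    n = h.num_nodes
    status = np.zeros(n, dtype=np.int8)
    for v in seeds:
        status[h.node_index(v)] = I
    B = h.incidence_matrix().astype(float)
    s_c, i_c, r_c = [int((status == S).sum())], [len(set(seeds))], [0]
    for _ in range(t_max):
        status = _step(B, status, alpha, kappa, gamma, rng)
        s_c.append(int((status == S).sum()))
        i_c.append(int((status == I).sum()))
        r_c.append(int((status == R).sum()))
    s_arr, i_arr, r_arr = map(np.array, (s_c, i_c, r_c))
    return SIRTrajectory(s_counts=s_arr, i_counts=i_arr, r_counts=r_arr,
                         prevalence=(i_arr + r_arr) / n,
                         seed_nodes=tuple(seeds), rng_seed=rng_seed)


def influence(h: Hypergraph, seeds, alpha: float, kappa: float, gamma: float,
              t: int, n_runs: int, rng: "np.random.Generator | int") -> InfluenceResult:
    """Mean prevalence at step ``t`` over ``n_runs`` independent trajectories."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    finals = np.empty(n_runs)
    for k, child in enumerate(rng.spawn(n_runs)):
        finals[k] = simulate(h, seeds, alpha, kappa, gamma, t, child).prevalence[-1]
    return InfluenceResult(mean=float(finals.mean()), per_run=finals)


def top_fraction_seeds(ranking: list[str], n_nodes: int, fraction: float) -> list[str]:
    """Top ``⌈fraction·N⌉`` (at least 1) nodes of a ranking, as a seed set."""
    k = max(1, int(np.ceil(fraction * n_nodes)))
    return ranking[:k]
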