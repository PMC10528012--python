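"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from scratch against the raw
definitions (pair loops, dict-based BFS, per-node stochastic updates) so
that agreement with the package is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import math
import random

import numpy as np


def laplacian_entropy(adj: np.ndarray) -> float:
    """−Σ λ ln λ of L/(2m) by direct dense eigendecomposition; 0 if edgeless."""
    adj = np.asarray(adj, dtype=float)
    m = adj.sum() / 2.0
    if m == 0:
        return 0.0
    lap = np.diag(adj.sum(axis=1)) - adj
    lam = np.linalg.eigvalsh(lap / (2.0 * m))
    lam = lam[lam > 1e-14]
    return float(-(lam * np.log(lam)).sum())


def line_graph_adjacency(edge_sets: list[set], s: int) -> np.ndarray:
    """M×M adjacency of the order-s line graph by explicit pair enumeration."""
    m = len(edge_sets)
    A = np.zeros((m, m))
    for j in range(m):
        for k in range(j + 1, m):
            if len(edge_sets[j] & edge_sets[k]) >= s:
                A[j, k] = A[k, j] = 1.0
    return A


def naive_hvc(edge_sets: list[set], node_order: list) -> dict:
    """Reference high-order entropy centrality built from first principles.

    Rebuilds every line graph by pair loops and recomputes every entropy by
    dense eigendecomposition after zeroing the removed vertex's row/column.
    """
    smax = 0
    for j in range(len(edge_sets)):
        for k in range(j + 1, len(edge_sets)):
            smax = max(smax, len(edge_sets[j] & edge_sets[k]))
    scores = {v: 0.0 for v in node_order}
    for s in range(1, smax + 1):
        A = line_graph_adjacency(edge_sets, s)
        theta0 = laplacian_entropy(A)
        delta = []
        for j in range(len(edge_sets)):
            reduced = A.copy()
            reduced[j, :] = 0.0
            reduced[:, j] = 0.0
            delta.append(theta0 - laplacian_entropy(reduced))
        for v in node_order:
            phi = sum(delta[j] / len(edge_sets[j])
                      for j in range(len(edge_sets)) if v in edge_sets[j])
            scores[v] += phi / s
    return scores


def bfs_components(nodes: list, edges: set) -> list[set]:
    """Connected components by hand-rolled BFS on an undirected edge set."""
    neighbours: dict = {v: set() for v in nodes}
    for a, b in edges:
        neighbours[a].add(b)
        neighbours[b].add(a)
    seen: set = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for w in neighbours[v]:
                if w not in comp:
                    comp.add(w)
                    frontier.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def two_section_edges(edge_sets: list[set]) -> set:
    """Unique unordered co-membership pairs, by brute-force enumeration."""
    pairs = set()
    for members in edge_sets:
        ordered = sorted(members)
        for a in range(len(ordered)):
            for b in range(a + 1, len(ordered)):
                pairs.add((ordered[a], ordered[b]))
    return pairs


def naive_sir_mean_prevalence(edge_sets: list[set], nodes: list, seeds: list,
                              alpha: float, kappa: float, gamma: float,
                              t_max: int, n_runs: int,
                              rng: random.Random) -> np.ndarray:
    """Per-run prevalence at t_max from a per-node, pure-python SIR simulator."""
    finals = np.empty(n_runs)
    for run in range(n_runs):
        status = {v: "S" for v in nodes}
        for v in seeds:
            status[v] = "I"
        for _ in range(t_max):
            eta = [sum(1 for v in e if status[v] == "I") for e in edge_sets]
            new_status = dict(status)
            for v in nodes:
                if status[v] == "S":
                    rate = sum(alpha * eta[j] ** kappa
                               for j, e in enumerate(edge_sets)
                               if v in e and eta[j] > 0)
                    if rng.random() < min(1.0, rate):
                        new_status[v] = "I"
                elif status[v] == "I":
                    if rng.random() < gamma:
                        new_status[v] = "R"
            status = new_status
        finals[run] = sum(1 for v in nodes if status[v] != "S") / len(nodes)
    return finals


def random_graph_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Erdős–Rényi adjacency matrix (symmetric, zero diagonal)."""
    upper = rng.random((n, n)) < p
    A = np.triu(upper, 1).astype(float)
    return A + A.T
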