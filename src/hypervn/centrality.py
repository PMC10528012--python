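"""Node centralities for hypergraphs.

Entropy-based methods
---------------------
*HVC* (high-order von Neumann entropy centrality) scores a node by how much
the hyperedges it belongs to change the complexity of the hypergraph's
s-line graphs:

1. project ``H`` to ``L_s(H)`` for every order ``s`` in the chosen set
   (default ``1..s_max``);
2. for each hyperedge ``e_j`` compute the von Neumann entropy change
   ``ΔΘ_s(e_j)`` caused by isolating it in ``L_s``;
3. map back to nodes with cardinality down-weighting,
   ``Φ_s(v_i) = Σ_{j ∈ Γ(v_i)} ΔΘ_s(e_j) / r_j``;
4. fuse orders with harmonic weights, ``HVC(v_i) = Σ_s Φ_s(v_i) / s``.

*semi-SAVC* is the efficiency variant: the quadratic entropy approximation
replaces the spectral entropy, and only orders up to ``⌊s_max/2⌋`` are used
(cumulative mode; ``single`` mode uses exactly order ``⌊s_max/2⌋``).

Baselines
---------
HDC (hyperdegree), CC (closeness on the 2-section, Wasserman–Faust scaled on
disconnected graphs), VC (vector centrality: eigenvector centrality of the
1-line graph mapped to nodes with 1/r_j weights), and SHC (sub-hypergraph
centrality: diagonal of the matrix exponential of the hypergraph adjacency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .entropy import EntropyKind, entropy_profile
from .hypergraph import Hypergraph


@dataclass(frozen=True)
class ScoreTable:
    """Node → score map for one method, with tie-aware stable ranking."""

    method: str
    scores: dict[str, float]
    node_order: tuple[str, ...] = field(repr=False, default=())

    def __post_init__(self):
        if not self.node_order:
            object.__setattr__(self, "node_order", tuple(self.scores))
        for label, s in self.scores.items():
            if not np.isfinite(s):
                raise ValueError(f"non-finite score for node {label!r}")

    def ranking(self) -> list[str]:
        """Node labels by descending score; ties keep first-appearance order."""
        return sorted(self.node_order, key=lambda v: -self.scores[v])

    def top(self, k: int) -> list[str]:
        return self.ranking()[:k]

    def values(self) -> np.ndarray:
        """Scores in node order."""
        return np.array([self.scores[v] for v in self.node_order], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        ranking = self.ranking()
        rank = {v: r + 1 for r, v in enumerate(ranking)}
        return pd.DataFrame(
            {"node": list(self.node_order),
             "score": [self.scores[v] for v in self.node_order],
             "rank": [rank[v] for v in self.node_order]}
        ).sort_values("rank", kind="stable").reset_index(drop=True)


def rank_nodes(table: ScoreTable) -> list[str]:
    """Descending-score node list with stable first-appearance tie-breaking."""
    return table.ranking()


# ---------------------------------------------------------------------------
# Entropy-based methods
# ---------------------------------------------------------------------------


def hvc_scores(h: Hypergraph, orders: "list[int] | None" = None,
               entropy: EntropyKind = "exact",
               method_name: str = "HVC") -> ScoreTable:
    """High-order von Neumann entropy centrality.

    Parameters
    ----------
    orders:
        Line-graph orders to fuse; default ``1..s_max``.  Truncated sets give
        the order-saturation variants.  If ``s_max = 0`` (a single hyperedge
        or pairwise-disjoint hyperedges) every score is 0.
    entropy:
        ``"exact"`` spectral entropy or the ``"quadratic"`` approximation.
    """
    smax = h.max_overlap()
    if orders is None:
        orders = list(range(1, smax + 1))
    else:
        orders = sorted(set(int(s) for s in orders))
        if orders and orders[0] < 1:
            raise ValueError("line-graph orders must be >= 1")
    phi_total = {v: 0.0 for v in h.nodes}
    for s in orders:
        lg = h.s_line_graph(s)
        profile = entropy_profile(lg.to_networkx(), order=s, kind=entropy)
        for v in h.nodes:
            phi = sum(profile.delta[j] / h.cardinality(j)
                      for j in h.incident_edges(v))
            phi_total[v] += phi / s
    return ScoreTable(method=method_name, scores=phi_total, node_order=h.nodes)


def semi_savc_scores(h: Hypergraph, mode: str = "cumulative") -> ScoreTable:
    """Semi-quadratic approximate von Neumann entropy centrality.

    Quadratic entropy with half the order range: ``{1..⌊s_max/2⌋}`` in
    ``cumulative`` mode (default) or the single order ``max(1, ⌊s_max/2⌋)``
    in ``single`` mode.  Both floors are clamped to at least 1.
    """
    if mode not in ("cumulative", "single"):
        raise ValueError(f"unknown semi-SAVC mode {mode!r}")
    smax = h.max_overlap()
    if smax < 1:
        return ScoreTable(method="semi-SAVC",
                          scores={v: 0.0 for v in h.nodes}, node_order=h.nodes)
    half = max(1, smax // 2)
    orders = list(range(1, half + 1)) if mode == "cumulative" else [half]
    return hvc_scores(h, orders=orders, entropy="quadratic",
                      method_name="semi-SAVC")


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


def hdc_scores(h: Hypergraph) -> ScoreTable:
    """Hyperdegree centrality: number of incident hyperedges."""
    return ScoreTable(method="HDC",
                      scores={v: float(h.hyperdegree(v)) for v in h.nodes},
                      node_order=h.nodes)


def cc_scores(h: Hypergraph) -> ScoreTable:
    """Closeness centrality on the 2-section graph.

    Connected graphs give the classical ``(N−1)/Σ_j d_ij``; disconnected
    2-sections use the Wasserman–Faust component scaling
    ``((n_i−1)/(N−1)) · ((n_i−1)/Σ d)`` so scores stay comparable across
    components.
    """
    g = h.two_section_graph()
    cc = nx.closeness_centrality(g, wf_improved=True)
    return ScoreTable(method="CC",
                      scores={v: float(cc[v]) for v in h.nodes},
                      node_order=h.nodes)


def _perron_vector(A: np.ndarray, tol: float = 1e-12,
                   max_iter: int = 100_000) -> np.ndarray:
    """Dominant eigenvector of a symmetric nonnegative matrix by power iteration.

    Iterates on ``A + I`` (same eigenvectors, no sign oscillation on
    bipartite components), uniform positive start, L2 normalisation,
    convergence in max norm.
    """
    n = A.shape[0]
    x = np.full(n, 1.0 / np.sqrt(n))
    shifted = A + np.eye(n)
    for _ in range(max_iter):
        y = shifted @ x
        y /= np.linalg.norm(y)
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    return x


def vc_scores(h: Hypergraph) -> ScoreTable:
    """Vector centrality: 1-line-graph eigenvector centrality mapped to nodes.

    Hyperedge centralities ``c(e_j)`` are the L2-normalised Perron vector of
    the 1-line-graph adjacency (isolated hyperedges get 0); the node score
    bucketed by cardinality collapses to ``VC(v_i) = Σ_{j ∈ Γ(v_i)} c(e_j)/r_j``.
    All scores are 0 when the 1-line graph has no edges.
    """
    lg = h.s_line_graph(1)
    M = h.num_edges
    if lg.num_edges == 0:
        return ScoreTable(method="VC", scores={v: 0.0 for v in h.nodes},
                          node_order=h.nodes)
    A = np.zeros((M, M))
    for j, k in lg.edges:
        A[j, k] = A[k, j] = 1.0
    c = _perron_vector(A)
    degree = A.sum(axis=1)
    c = np.where(degree > 0, c, 0.0)
    norm = np.linalg.norm(c)
    if norm > 0:
        c = c / norm
    scores = {v: float(sum(c[j] / h.cardinality(j) for j in h.incident_edges(v)))
              for v in h.nodes}
    return ScoreTable(method="VC", scores=scores, node_order=h.nodes)


def shc_scores(h: Hypergraph) -> ScoreTable:
    """Sub-hypergraph centrality: ``SHC(v_i) = Σ_j ξ_ij² e^{λ_j}``.

    λ, ξ are the spectrum of the hypergraph adjacency matrix; the score is
    the i-th diagonal entry of ``exp(A)``, a weighted count of closed walks
    through the node.
    """
    A = h.adjacency_matrix().astype(float)
    lam, xi = np.linalg.eigh(A)
    diag = (xi ** 2) @ np.exp(lam)
    scores = {v: float(diag[i]) for i, v in enumerate(h.nodes)}
    return ScoreTable(method="SHC", scores=scores, node_order=h.nodes)


ALL_METHODS = {
    "hvc": hvc_scores,
    "semi-savc": semi_savc_scores,
    "hdc": hdc_scores,
    "cc": cc_scores,
    "vc": vc_scores,
    "shc": shc_scores,
}
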