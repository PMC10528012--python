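"""Hypergraph data model, text I/O, matrix views, and s-line-graph projection.

A hypergraph ``H = (V, E)`` is a node set ``V`` (``|V| = N``) together with a
list of hyperedges ``E`` (``|E| = M``), each hyperedge a non-empty subset of
``V``; the union of all hyperedges must cover ``V``.  Hyperedges are addressed
by their position in the list, so duplicate hyperedges are legal and kept
distinct (empirical co-occurrence data routinely contains them).

Two projections to ordinary graphs are provided:

* the *2-section* (clique expansion): an edge joins two nodes whenever some
  hyperedge contains both;
* the *s-line graph* ``L_s(H)``: vertices are the hyperedges, and two
  hyperedges are adjacent iff they share at least ``s`` nodes.  The line
  graphs are nested, ``E(L_{s+1}) ⊆ E(L_s)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import networkx as nx
import numpy as np


class HypergraphError(ValueError):
    """Raised for structurally invalid hypergraph input."""


class Hypergraph:
    """Immutable node-set / hyperedge-list container.

    Parameters
    ----------
    hyperedges:
        Iterable of iterables of node labels.  Labels are arbitrary strings
        (other hashables are converted to ``str``).  Node order is
        first-appearance order across hyperedges; hyperedge IDs are list
        positions.
    """

    def __init__(self, hyperedges: Iterable[Iterable[str]]) -> None:
        nodes: list[str] = []
        index: dict[str, int] = {}
        edges: list[frozenset[int]] = []
        for members in hyperedges:
            mem_idx: set[int] = set()
            for label in members:
                label = str(label)
                if label not in index:
                    index[label] = len(nodes)
                    nodes.append(label)
                mem_idx.add(index[label])
            if not mem_idx:
                raise HypergraphError("empty hyperedge")
            edges.append(frozenset(mem_idx))
        if not edges:
            raise HypergraphError("hypergraph must contain at least one hyperedge")
        self._nodes: tuple[str, ...] = tuple(nodes)
        self._index = index
        self._edges: tuple[frozenset[int], ...] = tuple(edges)
        self._incident: tuple[tuple[int, ...], ...] | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """Node labels in first-appearance order."""
        return self._nodes

    @property
    def num_nodes(self) -> int:
        return len(self._nodes)

    @property
    def num_edges(self) -> int:
        return len(self._edges)

    def node_index(self, label: str) -> int:
        return self._index[label]

    def members(self, j: int) -> frozenset[str]:
        """Node labels of hyperedge ``j``."""
        return frozenset(self._nodes[i] for i in self._edges[j])

    def member_indices(self, j: int) -> frozenset[int]:
        return self._edges[j]

    def cardinality(self, j: int) -> int:
        """``r_j``, the number of nodes in hyperedge ``j``."""
        return len(self._edges[j])

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(len(e) for e in self._edges)

    def incident_edges(self, label: str) -> tuple[int, ...]:
        """IDs of hyperedges containing the node (``Γ(v_i)``)."""
        return self._incidence_lists()[self._index[label]]

    def hyperdegree(self, label: str) -> int:
        return len(self.incident_edges(label))

    def _incidence_lists(self) -> tuple[tuple[int, ...], ...]:
        if self._incident is None:
            lists: list[list[int]] = [[] for _ in self._nodes]
            for j, e in enumerate(self._edges):
                for i in e:
                    lists[i].append(j)
            self._incident = tuple(tuple(l) for l in lists)
        return self._incident

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Hypergraph(N={self.num_nodes}, M={self.num_edges})"

    # -- matrix views ------------------------------------------------------

    def incidence_matrix(self) -> np.ndarray:
        """M×N binary matrix ``B`` with ``B[j, i] = 1`` iff node i ∈ hyperedge j."""
        B = np.zeros((self.num_edges, self.num_nodes), dtype=np.int8)
        for j, e in enumerate(self._edges):
            B[j, list(e)] = 1
        return B

    def adjacency_matrix(self) -> np.ndarray:
        """N×N binary co-membership matrix: symmetric, zero diagonal."""
        B = self.incidence_matrix().astype(np.int64)
        A = (B.T @ B > 0).astype(np.int8)
        np.fill_diagonal(A, 0)
        return A

    def two_section_graph(self) -> nx.Graph:
        """Clique-expansion graph on the node labels."""
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        for j in range(self.num_edges):
            g.add_edges_from(itertools.combinations(sorted(self.members(j)), 2))
        return g

    # -- overlaps and line graphs -----------------------------------------

    def overlap_size(self, j: int, k: int) -> int:
        """Number of nodes shared by hyperedges ``j`` and ``k`` (``j ≠ k``)."""
        if j == k:
            raise ValueError("self-overlap is undefined")
        return len(self._edges[j] & self._edges[k])

    def overlap_matrix(self) -> np.ndarray:
        """M×M matrix of pairwise intersection sizes, zero diagonal."""
        B = self.incidence_matrix().astype(np.int64)
        O = B @ B.T
        np.fill_diagonal(O, 0)
        return O

    def max_overlap(self) -> int:
        """``s_max``: largest pairwise hyperedge overlap (0 if M = 1 or all disjoint)."""
        if self.num_edges < 2:
            return 0
        return int(self.overlap_matrix().max())

    def s_line_graph(self, s: int) -> "LineGraph":
        """Project to the order-``s`` line graph.

        Vertices are all M hyperedge IDs (isolates included); an edge joins
        ``(j, k)`` exactly when ``|e_j ∩ e_k| ≥ s``.
        """
        if s < 1:
            raise ValueError(f"line-graph order must be >= 1, got {s}")
        O = self.overlap_matrix()
        js, ks = np.nonzero(np.triu(O, 1) >= s)
        return LineGraph(order=s, num_vertices=self.num_edges,
                         edges=tuple(zip(js.tolist(), ks.tolist())))


@dataclass(frozen=True)
class LineGraph:
    """Ordinary graph whose vertices are hyperedge IDs of the source hypergraph."""

    order: int
    num_vertices: int
    edges: tuple[tuple[int, int], ...]

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.num_vertices))
        g.add_edges_from(self.edges)
        return g


# ---------------------------------------------------------------------------
# Text I/O.  Primary dialect: one hyperedge per line, comma-separated labels,
# '#' comments.  Secondary dialect: bipartite TSV (node <TAB> hyperedge label),
# hyperedge order = first appearance.
# ---------------------------------------------------------------------------


def read_hyperedge_list(source: IO[str] | str) -> Hypergraph:
    """Parse the comma-separated hyperedge-list format.

    Blank lines and ``#`` comments are skipped; whitespace around labels is
    stripped; duplicate labels within one line collapse to a set.
    """
    lines = source.splitlines() if isinstance(source, str) else source
    hyperedges: list[list[str]] = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        labels = [tok.strip() for tok in line.split(",") if tok.strip()]
        if not labels:
            raise HypergraphError(f"line {lineno}: hyperedge collapses to the empty set")
        hyperedges.append(labels)
    if not hyperedges:
        raise HypergraphError("no hyperedges found in input")
    return Hypergraph(hyperedges)


def write_hyperedge_list(h: Hypergraph, dest: IO[str]) -> None:
    """Write the comma-separated dialect; members in node (first-appearance) order."""
    for j in range(h.num_edges):
        members = sorted(h.member_indices(j))
        dest.write(",".join(h.nodes[i] for i in members) + "\n")


def read_bipartite_tsv(source: IO[str] | str) -> Hypergraph:
    """Parse the two-column node<TAB>hyperedge-label dialect."""
    lines = source.splitlines() if isinstance(source, str) else source
    order: list[str] = []
    groups: dict[str, list[str]] = {}
    for lineno, raw in enumerate(lines, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise HypergraphError(f"line {lineno}: expected 2 tab-separated columns")
        node, edge = parts[0].strip(), parts[1].strip()
        if not node or not edge:
            raise HypergraphError(f"line {lineno}: empty label")
        if edge not in groups:
            groups[edge] = []
            order.append(edge)
        groups[edge].append(node)
    if not order:
        raise HypergraphError("no records found in input")
    return Hypergraph([groups[e] for e in order])


def write_bipartite_tsv(h: Hypergraph, dest: IO[str]) -> None:
    for j in range(h.num_edges):
        for i in sorted(h.member_indices(j)):
            dest.write(f"{h.nodes[i]}\te{j}\n")
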