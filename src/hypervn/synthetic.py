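"""Synthetic hypergraph generators for experiments and tests.

Provides the canonical 11-node / 4-hyperedge worked example, random
hypergraphs with a configurable cardinality distribution, a generator with
a planted maximum overlap (controlled ``s_max``), and a "planted high-order
noise" construction used for order-saturation experiments.

All generators enforce the coverage condition (every node belongs to at
least one hyperedge) by patching uncovered nodes into randomly chosen
hyperedges, which slightly perturbs the requested cardinality distribution;
patch counts are reported through the ``logging`` channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hypergraph import Hypergraph

logger = logging.getLogger(__name__)


def figure1_fixture() -> Hypergraph:
    """The canonical small worked example: 11 nodes, 4 hyperedges.

    ``e1 = {v1,v2,v3}``, ``e2 = {v2..v7}``, ``e3 = {v5,v6,v7,v8}``,
    ``e4 = {v4,v9,v10,v11}``.  Overlap structure: ``|e1∩e2| = 2``,
    ``|e2∩e3| = 3``, ``|e2∩e4| = 1``, all other pairs disjoint; hence
    ``s_max = 3`` and the 1-line graph is a star centred on ``e2``.
    """
    return Hypergraph([
        ["v1", "v2", "v3"],
        ["v2", "v3", "v4", "v5", "v6", "v7"],
        ["v5", "v6", "v7", "v8"],
        ["v4", "v9", "v10", "v11"],
    ])


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for :func:`random_hypergraph`.

    ``cardinality`` names the hyperedge-size distribution: ``"poisson"``
    (shifted, ``1 + Poisson(param)``), ``"powerlaw"`` (Zipf with exponent
    ``param``, heavy-tailed sizes), or ``"constant"`` (all sizes
    ``int(param)``).  Sizes are clamped to ``[1, n]``.
    """

    n: int
    m: int
    cardinality: str = "poisson"
    param: float = 4.0
    seed: "int | None" = None

    def __post_init__(self):
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be positive")
        if self.cardinality not in ("poisson", "powerlaw", "constant"):
            raise ValueError(f"unknown cardinality distribution {self.cardinality!r}")
        if self.cardinality == "constant" and not 1 <= int(self.param) <= self.n:
            raise ValueError("constant cardinality must lie in [1, n]")


def _draw_cardinality(spec: GeneratorSpec, rng: np.random.Generator) -> int:
    if spec.cardinality == "poisson":
        r = 1 + rng.poisson(spec.param)
    elif spec.cardinality == "powerlaw":
        r = int(rng.zipf(spec.param))
    else:
        r = int(spec.param)
    return int(np.clip(r, 1, spec.n))


def _patch_coverage(memberships: list[list[str]], labels: list[str],
                    rng: np.random.Generator) -> int:
    covered = set().union(*(set(e) for e in memberships))
    uncovered = [v for v in labels if v not in covered]
    for v in uncovered:
        j = int(rng.integers(len(memberships)))
        memberships[j].append(v)
    if uncovered:
        logger.info("coverage patching added %d node(s) to random hyperedges",
                    len(uncovered))
    return len(uncovered)


def random_hypergraph(spec: GeneratorSpec) -> Hypergraph:
    """Sample a random hypergraph: iid hyperedge sizes, uniform members.

    Each of ``m`` hyperedges draws its cardinality from the spec
    distribution and its members uniformly without replacement from the
    ``n`` nodes; uncovered nodes are patched in afterwards.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [f"n{i}" for i in range(spec.n)]
    memberships = []
    for _ in range(spec.m):
        r = _draw_cardinality(spec, rng)
        members = rng.choice(spec.n, size=r, replace=False)
        memberships.append([labels[i] for i in members])
    _patch_coverage(memberships, labels, rng)
    return Hypergraph(memberships)


def planted_overlap_hypergraph(n: int, m: int, cardinality: int, overlap: int,
                               seed: "int | None" = None,
                               max_tries: int = 10_000) -> Hypergraph:
    """Random hypergraph whose maximum pairwise overlap is exactly ``overlap``.

    The first two hyperedges share exactly ``overlap`` nodes; every other
    pair is rejection-sampled to overlap strictly less.  Requires
    ``1 ≤ overlap ≤ cardinality`` and enough nodes for the designated pair
    (``n ≥ 2·cardinality − overlap``).
    """
    if not 1 <= overlap <= cardinality <= n:
        raise ValueError("need 1 <= overlap <= cardinality <= n")
    if m < 2:
        raise ValueError("need at least two hyperedges to plant an overlap")
    if n < 2 * cardinality - overlap:
        raise ValueError("not enough nodes for the designated pair")
    rng = np.random.default_rng(seed)
    labels = [f"n{i}" for i in range(n)]
    first = rng.choice(n, size=cardinality, replace=False)
    shared = first[:overlap]
    outside = np.setdiff1d(np.arange(n), first)
    rest = rng.choice(outside, size=cardinality - overlap, replace=False)
    edges_idx: list[set[int]] = [set(first.tolist()),
                                 set(shared.tolist()) | set(rest.tolist())]
    for _ in range(m - 2):
        for _attempt in range(max_tries):
            cand = set(rng.choice(n, size=cardinality, replace=False).tolist())
            if all(len(cand & e) < overlap for e in edges_idx):
                edges_idx.append(cand)
                break
        else:
            raise ValueError("could not sample hyperedges below the planted "
                             "overlap; reduce m or cardinality, or raise n")
    memberships = [[labels[i] for i in sorted(e)] for e in edges_idx]
    _patch_coverage(memberships, labels, rng)
    return Hypergraph(memberships)


def planted_noise_hypergraph(n: int = 200, hub_edges: int = 15,
                             hub_edge_size: int = 6,
                             noise_overlap: int = 8,
                             noise_edge_size: int = 10,
                             seed: "int | None" = None) -> Hypergraph:
    """Hub core plus a peripheral high-overlap triangle of hyperedges.

    The construction separates spreading power from high-order structure:

    * two *hub* nodes each sit in ``hub_edges`` hyperedges of size
      ``hub_edge_size`` whose other members are drawn from the core pool, so
      core hyperedge overlaps stay small (≤ 2, enforced by rejection) and
      all the low-order line-graph signal concentrates on the hubs;
    * three *peripheral* hyperedges of size ``noise_edge_size`` share a
      common block of ``noise_overlap`` nodes and touch nothing else, so for
      every order ``2 < s ≤ noise_overlap`` the s-line graph is exactly that
      triangle — a strong high-order entropy signal carried by nodes that
      can infect at most the small peripheral block.

    With the defaults ``s_max = noise_overlap`` and the top of the
    entropy-centrality ranking flips from the hubs (orders {1}) to the
    peripheral block (full orders), which is what an order-saturation
    experiment needs to detect.
    """
    if noise_overlap >= noise_edge_size:
        raise ValueError("noise_overlap must be < noise_edge_size")
    n_periph = noise_overlap + 3 * (noise_edge_size - noise_overlap)
    if n < n_periph + 2 + hub_edge_size * 2:
        raise ValueError("n too small for the requested structure")
    rng = np.random.default_rng(seed)
    labels = [f"n{i}" for i in range(n)]
    hubs = [0, 1]
    periph = list(range(2, 2 + n_periph))
    core_pool = np.arange(2 + n_periph, n)

    common = periph[:noise_overlap]
    uniq = periph[noise_overlap:]
    per_edge = noise_edge_size - noise_overlap
    edges_idx: list[set[int]] = [
        set(common) | set(uniq[k * per_edge:(k + 1) * per_edge])
        for k in range(3)
    ]
    for k in range(hub_edges * 2):
        hub = hubs[k % 2]
        for _attempt in range(10_000):
            members = rng.choice(core_pool, size=hub_edge_size - 1,
                                 replace=False)
            cand = {hub} | set(members.tolist())
            if all(len(cand & e) <= 2 for e in edges_idx[3:]):
                edges_idx.append(cand)
                break
        else:  # pragma: no cover - defensive
            raise ValueError("could not keep core overlaps small; raise n")
    memberships = [[labels[i] for i in sorted(e)] for e in edges_idx]
    _patch_coverage(memberships, labels, rng)
    return Hypergraph(memberships)
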