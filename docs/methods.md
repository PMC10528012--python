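# Methods

## Data model

A hypergraph `H = (V, E)` stores an ordered node set (first-appearance
order, arbitrary string labels) and an ordered list of non-empty hyperedges;
the union of hyperedges must cover `V`. Duplicate hyperedges are kept as
distinct IDs: empirical co-occurrence data contains them, and they are
legitimate distinct vertices of the line graphs. Hyperedges of cardinality
1 are legal; they contribute no 2-section edges and no overlaps. With a
single hyperedge, or pairwise-disjoint hyperedges, `s_max = 0` and the
entropy centralities degrade gracefully to all-zero scores.

Two plain-text dialects are supported (UTF-8, `#` comments): one hyperedge
per line with comma-separated labels, and a bipartite TSV
(`node<TAB>hyperedge`). Round-trips are lossless up to member order.

## Von Neumann entropy

For a graph with `m ≥ 1` edges, `ρ = (D − A)/(2m)` is trace-one PSD with
spectrum in [0, 1]; `S = −Σ λ ln λ` (natural log, `0 ln 0 = 0`). Numerical
choices: dense symmetric eigendecomposition (suitable up to a few thousand
vertices; no sparse path), eigenvalues clipped at 0 to absorb −1e−16-scale
noise. Edgeless graphs get `S := 0` by convention — a zero-edge system
carries no vertex–edge entanglement — which keeps entropy changes finite
when a removal disconnects a tiny line graph entirely.

The quadratic approximation replaces `−ρ ln ρ` with `ρ(I − ρ)`:
`S ≈ (x ln x/(x−1)) (1 − (1/4m²) Σ_v (d_v² + d_v))`, where `x` counts all
vertices including isolates (the only reading under which the prefactor is
well-defined and stable).

**Entropy change under removal.** `ΔΘ(v) = S(G) − S(G with v's incident
edges removed)`; the vertex is retained as an isolate. For the exact
spectral entropy this is indistinguishable from deleting the vertex
(isolates only add zero eigenvalues); for the quadratic form it keeps `x`
fixed across removals, so the prefactor never changes within one line
graph. The sign is preserved — no absolute value — although in practice
isolating a vertex was never observed to increase entropy in randomized
searches.

## Centralities

**HVC.** Orders default to `1..s_max`; truncated order sets serve the
saturation experiments. Per order: build `L_s`, compute `ΔΘ_s(e_j)` for
every hyperedge (isolated line-graph vertices get exactly 0 without
recomputation), map to nodes as `Φ_s(v_i) = Σ_{j∈Γ(v_i)} ΔΘ_s(e_j)/r_j`
(small hyperedges concentrate their entropy impact on fewer nodes, hence
the `1/r_j` weight), and fuse as `Σ_s Φ_s/s` (lower orders carry the bulk
of the structural signal). Cost is dominated by `O(M³)` eigendecompositions
per hyperedge and order; fine for `M` up to a few hundred.

**semi-SAVC.** Quadratic entropy plus half the order range. The half-range
is read cumulatively (`{1..⌊s_max/2⌋}`, consistent with the harmonic fusion
and the saturation narrative); a `single` mode computing only order
`⌊s_max/2⌋` is provided for the stricter reading. `⌊s_max/2⌋` is floored
and clamped to ≥ 1.

**Baselines.** HDC is the incidence column sum. CC runs BFS on the
2-section; disconnected graphs use the Wasserman–Faust component scaling
`((n_i−1)/(N−1))((n_i−1)/Σd)` so scores remain comparable across
components. VC computes the Perron vector of the 1-line-graph adjacency by
power iteration — iterating on `A + I` (identical eigenvectors, no
oscillation on bipartite components), uniform positive start, L2
normalization, max-norm tolerance 1e−12, cap 1e5 iterations; isolated
line-graph vertices get 0, and every observed cardinality is bucketed
(including 1). Rankings are invariant to the normalization choice. SHC is
the diagonal of `exp(A)` via the full symmetric eigendecomposition.

Ranking everywhere is descending score with stable first-appearance
tie-breaking, so runs are deterministic and reproducible.

## Nonlinear SIR

Synchronous discrete time. Per step, with start-of-step state: a
susceptible node's infection probability is
`min(1, Σ_{e_j ∋ v} α η_j^κ)` over incident hyperedges with `η_j ≥ 1`
infected members (recovered members do not count); infected nodes recover
with probability γ; a node infected this step cannot recover this step.
The clamp at 1 makes the summed rate a valid Bernoulli probability; at the
α ~ 1e−4 scale typical for large hypergraphs it is essentially never
active. Defaults follow the standard nonlinear-contagion setting
α = 1e−4, κ = 1.25, γ = 0.2, t = 5 and 100 repetitions; influence is the
mean prevalence `(|I|+|R|)/N` at the horizon. Randomness comes from a
seeded `numpy` Generator, with per-run children spawned from the parent so
trajectories are bit-reproducible; uniform draws happen for all nodes in
fixed node order each step, which makes single trajectories bit-identical
under a fixed seed.

## Evaluation

* **Monotonicity** `M(R) = (1 − Σ N_r(N_r−1)/(N(N−1)))²` over tie groups;
  the squared form matches the stated [0, 1] endpoints (1 all-distinct,
  0 all-tied). Ties are detected after rounding scores to 10 decimals:
  floating-point scores essentially never tie by accident, integer scores
  (hyperdegree) tie exactly.
* **Pearson matrix** via pandas on node-aligned score vectors;
  zero-variance vectors give flagged NaN entries rather than errors.
* **Robustness**: remove the top `⌈f·N⌉` ranked nodes from every hyperedge,
  drop emptied hyperedges, report the largest connected component of the
  residual 2-section (remaining isolates count as size-1 components).
  The 2-section is the connectivity convention used throughout.
* **Saturation sweep**: for each grid entry `i`, rank with orders `{1..i}`
  (exact entropy), seed the top 1 % (⌈·⌉, min 1), measure influence.

## Synthetic generators

`random_hypergraph` draws iid hyperedge sizes (shifted Poisson by default,
mean ≈ 5; discrete power-law option for heavy-tailed cardinalities;
constant for edge cases) and members uniformly without replacement.
Coverage is enforced by patching uncovered nodes into random hyperedges —
this slightly perturbs the size distribution (logged) but cannot change
pairwise overlaps, since a patched node was in no other hyperedge.

`planted_overlap_hypergraph` plants one designated pair with exactly `k`
shared nodes and rejection-samples the rest below `k`, giving controlled
`s_max = k`.

`planted_noise_hypergraph` separates spreading power from high-order
structure: two hub nodes each sit in 15 six-node hyperedges over a large
core pool (overlaps ≤ 2 enforced), while three ten-node peripheral
hyperedges share a common eight-node block and touch nothing else. Orders
s ≥ 3 therefore see only the peripheral triangle, whose members can infect
at most the 14-node periphery. Rankings fused to low orders select the
hubs; fusing all orders up to `s_max = 8` promotes the peripheral block —
the structural situation in which order saturation appears.

What these generators do **not** emulate: the heavy-tailed hyperdegree
distributions, multi-scale overlap spectra (s_max up to ~60) and community
structure of large empirical co-occurrence hypergraphs. Passing tests on
them validates the algebra, the contracts and the qualitative phenomena,
not performance claims on any real dataset.

## Experiment scale choices

Validation experiments run at desk scale: random hypergraphs with
`N ≤ 40, M ≤ 15` for oracle-equivalence checks, a 200-node / 60-hyperedge
hypergraph for SIR cross-validation, and the 200-node planted-noise
hypergraph (M = 33) with 200 runs per grid point for the saturation
experiment. For that synthetic scale the transmissibility is set to
α = 5e−3 (κ, γ, t unchanged): the α = 1e−4 default targets hypergraphs
with thousands of nodes and very large hyperedges, and at N = 200 it
produces almost no transmission, leaving nothing to compare. The choice
follows the magnitude argument α·η^κ·(incident hyperedges) ≈ 0.1 per step
near a hub.

## Known limitations

* Dense eigendecompositions bound practical sizes to a few thousand
  hyperedges; no Lanczos/sparse path.
* No weighted, directed or temporal hypergraphs.
* CC distances are 2-section shortest paths; hyperedge-walk distances are
  not implemented.
* The saturation effect is demonstrated qualitatively on a construction
  designed to exhibit it; where the saturation point falls on real data
  depends on the dataset.
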