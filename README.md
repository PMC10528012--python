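# hypervn

Vital-node identification on hypergraphs via von Neumann graph entropy,
together with the baselines, contagion dynamics and evaluation instruments
needed to judge such rankings.

Many systems — co-authorship, group discussions, co-purchasing, metabolic
complexes — are naturally *hypergraphs*: one interaction (hyperedge) joins
any number of nodes. Which nodes matter most? `hypervn` implements an
entropy-based answer plus everything around it:

* **HVC** — high-order von Neumann entropy centrality. Project the
  hypergraph to its s-line graphs `L_s(H)` (vertices = hyperedges, adjacent
  iff they share ≥ s nodes, for s = 1..s_max). In each line graph, measure
  for every hyperedge `e_j` the entropy change
  `ΔΘ_s(e_j) = Θ(L_s) − Θ(L_s \ e_j)` of the Laplacian density operator
  `ρ = L/(2m)`, `Θ = −Σ λ ln λ`. Map back to nodes with cardinality
  weights and fuse orders harmonically:

      Φ_s(v_i) = Σ_{j ∈ Γ(v_i)} ΔΘ_s(e_j)/r_j ,   HVC(v_i) = Σ_s Φ_s(v_i)/s

* **semi-SAVC** — the efficiency variant: quadratic entropy approximation
  `S ≈ (x ln x/(x−1))(1 − (1/4m²) Σ_v (d_v²+d_v))` and only orders up to
  `⌊s_max/2⌋`.
* **Baselines** — hyperdegree (HDC), closeness on the 2-section (CC),
  vector centrality (VC), sub-hypergraph centrality (SHC = diag exp(A)).
* **Dynamics** — a discrete-time nonlinear SIR model where a hyperedge with
  η infected members infects each susceptible member with rate `α·η^κ`.
* **Evaluation** — seed influence, targeted-attack robustness (residual
  largest connected component), Pearson correlation between methods,
  monotonicity (tie-freeness) of rankings, and an order-saturation sweep.
* **Synthetic generators** — the canonical 11-node worked example, random
  hypergraphs, planted-overlap hypergraphs with controlled `s_max`, and a
  planted high-order-noise construction for saturation experiments.

## Worked example

```bash
python examples/worked_example.py
```

```
hypergraph: N=11 nodes, M=4 hyperedges, smax=3
  L1: 3 edge(s): e0-e1, e1-e2, e1-e3
  L2: 2 edge(s): e0-e1, e1-e2
  L3: 1 edge(s): e1-e2
L1 entropy Θ = 0.867563 nats; isolating the hub hyperedge e1 drops it by 0.867563

HVC ranking (score = entropy impact mapped back to nodes):
    v2  0.386920
    v3  0.386920
    v5  0.338054
    ...
   v11  0.076307
```

The 1-line graph is a star centred on the six-node hyperedge `e1`; isolating
it destroys all vertex–edge entanglement, so its entropy change equals the
whole star entropy (0.867563 nats). Nodes v2/v3 top the ranking because
they sit in both the hub hyperedge and a small (hence heavily weighted)
hyperedge. Other examples: `centrality_comparison.py` (all six methods,
correlation and monotonicity), `sir_influence.py` (top-1% seed influence)
and `order_saturation.py`, which shows that fusing line-graph orders beyond
a saturation point *lowers* seed quality — high-order structure can be
ranking noise.

Equivalent shell workflows are available through the `hypervn` CLI
(`generate`, `project`, `entropy`, `rank`, `sir`, `evaluate`); every command
that writes results also writes a manifest for bit-exact reproduction.

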