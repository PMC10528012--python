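"""Seed the nonlinear SIR process with top-ranked nodes and measure influence.

Transmission through a hyperedge with η infected members happens with
probability α·η^κ per susceptible member; κ>1 makes crowded hyperedges
super-linearly infectious.  Influence is the mean fraction of ever-infected
nodes (I+R) after t steps, averaged over repeated runs.
"""

import numpy as np

import hypervn as hv

h = hv.random_hypergraph(hv.GeneratorSpec(n=200, m=60, cardinality="poisson",
                                          param=5.0, seed=30))
alpha, kappa, gamma, t, runs = 1e-3, 1.25, 0.2, 5, 100

print(f"hypergraph: N={h.num_nodes}, M={h.num_edges}; "
      f"SIR with alpha={alpha}, kappa={kappa}, gamma={gamma}, t={t}\n")

for name in ["hvc", "semi-savc", "hdc", "cc"]:
    table = hv.ALL_METHODS[name](h)
    seeds = hv.top_fraction_seeds(table.ranking(), h.num_nodes, 0.01)
    res = hv.influence(h, seeds, alpha, kappa, gamma, t, runs,
                       rng=np.random.default_rng(1))
    print(f"{table.method:>9}: seeds {seeds} -> influence "
          f"{res.mean:.4f} ± {res.std_error:.4f}")

print("\nHigher influence means the method's top-1% nodes reach more of the "
      "hypergraph within the time horizon.")
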