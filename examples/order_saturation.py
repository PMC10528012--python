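"""Demonstrate the order-saturation effect of high-order line-graph fusion.

The synthetic hypergraph plants its high-order overlap structure on a
weakly connected periphery while two hub nodes carry the real spreading
power.  Rankings fused up to a moderate line-graph order pick the hubs;
fusing every order up to smax lets the peripheral high-order signal crowd
them out, and seed influence drops — more high-order information is not
automatically better.
"""

import numpy as np

import hypervn as hv

h = hv.planted_noise_hypergraph(seed=42)
smax = h.max_overlap()
print(f"hypergraph: N={h.num_nodes}, M={h.num_edges}, smax={smax}\n")

results = hv.saturation_sweep(h, [1, 2, 4, 6, smax], alpha=5e-3, kappa=1.25,
                              gamma=0.2, t=5, n_runs=200,
                              rng=np.random.default_rng(0))
for order, res in results.items():
    top = hv.hvc_scores(h, orders=list(range(1, order + 1))).ranking()[:2]
    print(f"orders 1..{order}: seeds {top} -> influence "
          f"{res.mean:.4f} ± {res.std_error:.4f}")

best = max(results, key=lambda k: results[k].mean)
print(f"\nBest influence at max order {best}, not at smax={smax}: past the "
      "saturation point the extra orders act as ranking noise.")
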