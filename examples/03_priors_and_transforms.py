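"""How priors and data transformations change the inferred network.

Compares (a) the flat Guelzim prior against an informative per-edge prior,
and (b) inference with and without the two data transformations when the
data carry a strong shared perturbation trajectory.
"""

import numpy as np

from scanbma import (
    PriorEdgeMatrix,
    ScanOptions,
    SimulationConfig,
    edge_universe,
    evaluate,
    gold_standard_from_network,
    guelzim_prior,
    infer_network,
    precision_at,
    simulate_dataset,
)

opts = ScanOptions()

# --- informative prior: 0.9 on true edges, 0.01 elsewhere ------------------
net, ts = simulate_dataset(SimulationConfig(seed=3))
gold = gold_standard_from_network(net)
universe = edge_universe(ts.gene_ids, ts.gene_ids)

flat = guelzim_prior(ts.gene_ids, ts.gene_ids)
probs = np.full((ts.n_genes, ts.n_genes), 0.01)
idx = {g: i for i, g in enumerate(ts.gene_ids)}
for (r, t) in net.edges:
    probs[idx[r], idx[t]] = 0.9
informative = PriorEdgeMatrix(ts.gene_ids, ts.gene_ids, probs)

for name, prior in (("flat (Guelzim 2.76/6000)", flat), ("informative", informative)):
    rep = evaluate(infer_network(ts, prior, opts).edges, gold, universe=universe)
    print(f"{name:28s} AUROC {rep.auroc:.3f}  AUPRC {rep.auprc:.3f}")

# --- transforms under a strong shared trajectory ---------------------------
net5, ts5 = simulate_dataset(SimulationConfig(seed=3, amplitude=5.0))
gold5 = gold_standard_from_network(net5)
flat5 = guelzim_prior(ts5.gene_ids, ts5.gene_ids)
print("\nwith a strong drug-response trajectory (amplitude 5):")
for mode in ("none", "time", "time+self"):
    inferred = infer_network(ts5, flat5, opts, transform_mode=mode)
    _, tp, fp = precision_at(inferred.edges, gold5, 0.95)
    print(f"  transform={mode:10s} edges@0.95: TP={tp:3d} FP={fp:3d}")
print("The shared trajectory correlates every gene pair; time adjustment")
print("removes it and cuts the false positives, as does removing each")
print("gene's own autoregressive trend.")
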