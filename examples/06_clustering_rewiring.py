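"""Triangle density slows spreading: clustering-targeted rewiring.

Rewires a small-world network (degree-preserving swaps) to three clustering
targets and measures mean arrival times per BFS layer under regulatory
dynamics (B = alpha = 1, a = 0.8, b = 0.5).
"""

import motifresponse as mr

model = mr.make_model("regulatory", {"B": 1.0, "alpha": 1.0, "a": 0.8, "b": 0.5})
df = mr.clustering_sweep(model, targets=(0.05, 0.2, 0.4), n=200, k=10,
                         beta=0.05, n_sources=5, seed=2)
table = df.groupby(["target_C", "layer"])["tau"].mean().unstack("target_C")
print("mean arrival time per layer, by clustering target:")
print(table.round(3))
print()
print("Within each layer, arrival is later at higher clustering: triangles")
print("route signal mass back into already-perturbed neighbourhoods.")
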