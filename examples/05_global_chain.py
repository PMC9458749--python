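"""Global propagation along a degree-controlled chain.

An 8-node chain with a degree-5 hub in the middle, regulatory dynamics
a = 0.8, b = 0.5.  Prints per-layer arrival times from the Newton
recursion next to direct threshold crossings, and the product-form
prediction g^T D with constants calibrated on the first layers.
"""

import numpy as np

import motifresponse as mr

model = mr.make_model("regulatory", {"B": 0.01, "alpha": 0.01, "a": 0.8, "b": 0.5})
seq = [2, 2, 2, 2, 5, 2, 2, 2]
pred, res, G, path = mr.chain_response(model, seq)

est = mr.scaling_exponents(model)
E_seq = np.full(len(path) - 1, 0.0)
C1, C2, scale = mr.calibrate_constants(
    seq[1:], pred.T[1:], est.theta_J, est.theta_Q, 0.5
)
D = mr.build_D(seq[1:], est.theta_J, est.theta_Q, C1, C2, 0.5)
prod = mr.global_times_product(E_seq, D)
prod = prod / prod[0] * pred.T[1]

print("layer degree  T_recursion  T_direct  T_product_form")
for k in range(1, len(path)):
    print(f"{k:>5} {seq[k]:>6}  {pred.T[k]:>11.2f} {pred.T_direct[k]:>9.2f} {prod[k-1]:>15.2f}")
print(f"calibrated constants: C1 = {C1:.3f}, C2 = {C2:.3f}")
print()
print("Arrival times accumulate layer by layer; the degree-5 hub at layer 4")
print("adds a visibly larger increment because theta_J > 0 for this dynamics.")
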