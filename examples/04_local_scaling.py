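"""Response-time scaling of a high-degree target (small demonstration).

Sweeps the degree of a target embedded in an ER bulk for regulatory
dynamics (a=1.2, b=2.0) and compares the fitted log-log slope of tau(d)
with the predicted exponent theta_J = 1/a - 1.
"""

import motifresponse as mr

model = mr.make_model("regulatory", {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 2.0})
df = mr.star_response_sweep(model, (10, 20, 40, 80), kind="edges",
                            bulk_n=800, bulk_degree=16.0, seed=0)
slope, r2 = mr.fit_loglog(df["d"], df["tau"])
pred = mr.predicted_scaling(model, "independent_edges")
print(df[["d", "tau", "J", "E"]].round(4).to_string(index=False))
print(f"fitted slope {slope:+.3f} (R^2 = {r2:.3f}); predicted theta_J = {pred.exponent:+.3f}")
print()
print("tau shrinks with target degree as d^theta_J: for this dynamics the")
print("adjacent term decays (theta_Q < 0) and self-dynamics alone sets the scaling.")
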