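# motifresponse

How do basic network motifs — independent edges and triangles — shape the
time it takes a networked dynamical system to respond to a small permanent
perturbation?  `motifresponse` is a Python library for researchers in
systems biology and network science who study perturbation propagation on
graphs: it simulates prototypical nonlinear dynamics (gene regulation,
SIS epidemics, population flow, mutualistic, biochemical, neuronal and
social-activity models), censuses the motif content of the underlying
network, and implements the linear-response theory that predicts each
node's response time and how that time scales with degree.

## The model

Node states evolve under pairwise coupling on an undirected graph `A`:

    dx_i/dt = F(x_i) + Σ_j A_ij H1(x_i) H2(x_j)

A perturbation experiment clamps a source node m at `x_m* (1 + ε)` and
tracks every node's response ratio `δ_i(t) = Δx_i(t) / Δx_i(∞)`; the
response time `τ_im` is the first crossing of a threshold η (default 0.5).

Linearising around the steady state gives each node an intrinsic
relaxation time `J_i` and an adjacent-dynamics term `E_im(t)` collecting
the feedback from neighbours that have not yet equilibrated.  With
mean-field steady states `x_i* = R⁻¹(d_i·Hbar)` (where `R = −F/H1`), both
quantities acquire leading powers in the node degree,

    J_i ~ d_i^θ_J,        E_im ~ d_i^θ_Q,

and these two exponents — properties of the dynamics alone — organise the
response-time regimes: `τ ~ d^θ_J` when the adjacent term fades, and
`τ ~ d^(θ_J + 1)` when the source–target edge is buried in triangles whose
partners respond in near synchrony with the target (`f ≈ 1`).  Along a
propagation path, arrival times accumulate layer by layer through a
Newton-type recursion with a product form `T(m→i_k) ~ gᵀD` in which the
degree *sequence* (not just its mean) matters.

## A worked example

```python
import motifresponse as mr

model = mr.make_model("population", {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 1.1})
G, m, i, h, j = mr.four_node_motif()   # triangle m-i-h plus independent edge i-j
steady = mr.find_steady_state(model, G)
res = mr.perturb_and_track(model, G, steady, m)
print({k: round(float(res.tau[v]), 3) for k, v in {"i": i, "h": h, "j": j}.items()})
print(round(mr.E_im_from_trajectories(res, model, G, steady, i).summary, 3))
```

prints

```
{'i': 28.705, 'h': 24.76, 'j': 50.077}
0.601
```

The nodes inside the triangle (one hop from the source) respond well before
the node `j` on the independent edge two hops away, and the adjacent-dynamics
term at the
target is far from zero — the neighbours of `i` are still in transit when
`i` crosses the threshold, which is exactly the effect the theory corrects
for.  The scripts in `examples/` walk through each capability: exponent
extraction, motif census, the perturbation protocol, local scaling sweeps,
chain propagation, and clustering-controlled rewiring.

A thin CLI mirrors the main entry points:

```bash
motifresponse exponents --model population --params B=0.01,alpha=0.01,a=1.2,b=1.1
motifresponse motifs --input edges.tsv --max-n 5
motifresponse scaling --panel edges_regulatory_self
```

Empirical networks load through `read_edgelist` (two-column TSV, 0- or
1-based ids); all shipped experiments run on synthetic graphs.

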