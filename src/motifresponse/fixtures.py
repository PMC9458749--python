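"""Canonical experiment fixtures and the sweep engines built on them.

This module pins down the study conditions used throughout the tests and
examples: the four-node motif network, the random-graph ensembles, the
local star sweeps behind the response-time scaling panels, the degree-
sequence chains, and the clustering-rewiring experiment.  Everything is
deterministic given a seed.

Scaling-panel windows
---------------------
The scaling claims are asymptotic, and each regime has a finite window in
which its leading term dominates while the mean-field premise (target
neighbours with degree-independent steady states) still holds.  The panel
definitions therefore fix, per dynamics, the bulk mean degree and the
degree range of the sweep:

* independent-edge panels use a leaf source and a bulk of mean degree 16;
  the sweep stays well below the degree at which the target's feedback
  starts shifting its own neighbours' states.
* triangle panels embed the source in a sparse bulk (mean degree 4, which
  raises the mean-field adjacent factor Qbar) and sweep degrees high
  enough that the triangle amplification C ~ d Qbar dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import linregress

from .dynamics import DynamicsModel, make_model, self_time_J
from .errors import ParameterError
from .io import ExperimentConfig, config_hash, dump_json
from .networks import (
    chain_with_degrees,
    embedded_star,
    generate_er,
    generate_small_world,
    local_star,
    random_degree_sequence,
    rewire_to_clustering,
)
from .simulate import find_steady_state, layers, perturb_and_track, perturb_linear_response
from .theory import E_im_from_trajectories, adjacent_amplification, global_times_recursive

__all__ = [
    "four_node_motif",
    "fixture_suite",
    "ScalingPanel",
    "SCALING_PANELS",
    "star_response_sweep",
    "fit_loglog",
    "chain_response",
    "chain_ensemble",
    "clustering_sweep",
    "run_experiment",
]


def four_node_motif() -> tuple[nx.Graph, int, int, int, int]:
    """The four-node motif example: source m, target i, with m-i-h a
    triangle and i-j an independent edge.  Returns (G, m, i, h, j)."""
    G = nx.Graph()
    m, i, h, j = 0, 1, 2, 3
    G.add_edges_from([(m, i), (m, h), (i, h), (i, j)])
    return G, m, i, h, j


def fixture_suite(seed: int = 0) -> dict[str, ExperimentConfig]:
    """The named battery of test networks with their dynamics parameters."""
    pop_reference = {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 1.1}
    reg_chain = {"B": 0.01, "alpha": 0.01, "a": 0.8, "b": 0.5}
    reg_cluster = {"B": 1.0, "alpha": 1.0, "a": 0.8, "b": 0.5}
    suite = {
        "motif4": ExperimentConfig(
            model="population", params=pop_reference,
            topology={"generator": "four_node_motif", "args": {}},
            source=0, seed=seed, label="four-node motif example",
        ),
        "er100": ExperimentConfig(
            model="population", params=pop_reference,
            topology={"generator": "generate_er", "args": {"n": 100, "p": 0.10, "seed": seed}},
            source=0, seed=seed, label="Erdos-Renyi N=100, p=0.10",
        ),
        "smallworld100": ExperimentConfig(
            model="population", params=pop_reference,
            topology={"generator": "generate_small_world",
                      "args": {"n": 100, "k": 10, "beta": 0.05, "seed": seed}},
            source=0, seed=seed, label="small-world N=100, <k>=10",
        ),
        "star_edges_d20": ExperimentConfig(
            model="population", params={"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 0.6},
            topology={"generator": "local_star", "args": {"d": 20, "kind": "edges"}},
            source=0, seed=seed, label="independent-edge star, d=20",
        ),
        "star_triangles_d20": ExperimentConfig(
            model="regulatory", params={"B": 0.01, "alpha": 0.01, "a": 10.0, "b": 2.0},
            topology={"generator": "local_star", "args": {"d": 20, "kind": "source_triangles"}},
            source=0, seed=seed, label="triangle star, d=20",
        ),
        "chain8": ExperimentConfig(
            model="regulatory", params=reg_chain,
            topology={"generator": "chain_with_degrees",
                      "args": {"degrees_seq": [2, 2, 2, 2, 5, 2, 2, 2]}},
            source=0, seed=seed, label="8-node chain with one hub",
        ),
        "smallworld200_cluster": ExperimentConfig(
            model="regulatory", params=reg_cluster,
            topology={"generator": "generate_small_world",
                      "args": {"n": 200, "k": 10, "beta": 0.05, "seed": seed}},
            source=0, seed=seed, label="clustering-rewiring base network",
        ),
    }
    return suite


_GENERATORS = {
    "four_node_motif": lambda: four_node_motif()[0],
    "generate_er": generate_er,
    "generate_small_world": generate_small_world,
    "local_star": lambda **kw: local_star(**kw)[0],
    "chain_with_degrees": lambda **kw: chain_with_degrees(**kw)[0],
}


def build_topology(spec: dict) -> nx.Graph:
    gen = spec.get("generator")
    if gen not in _GENERATORS:
        raise ParameterError(f"unknown topology generator {gen!r}")
    return _GENERATORS[gen](**spec.get("args", {}))


# --- local scaling panels -------------------------------------------------

@dataclass(frozen=True)
class ScalingPanel:
    """One response-time scaling experiment: dynamics, fixture, window, claim."""

    name: str
    model: str
    params: dict
    kind: str  # 'edges' or 'triangles' (through the source-target edge)
    degrees: tuple[int, ...]
    bulk_degree: float
    bulk_n: int
    source_in_bulk: bool
    expected_exponent: str  # 'theta_J', 'theta_J-theta_Q', 'theta_J+1', 'zero'
    f_regime: str | None = None


SCALING_PANELS: dict[str, ScalingPanel] = {
    p.name: p
    for p in [
        ScalingPanel(
            "edges_regulatory_self", "regulatory",
            {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 2.0},
            "edges", (10, 20, 40, 80, 160), 16.0, 1500, False, "theta_J",
        ),
        ScalingPanel(
            "edges_population_degree_limited", "population",
            {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 1.0},
            "edges", (6, 12, 24, 48), 16.0, 1500, False, "theta_J",
        ),
        ScalingPanel(
            "edges_population_distance_limited", "population",
            {"B": 0.01, "alpha": 0.01, "a": 1.0, "b": 0.2},
            "edges", (10, 20, 40, 80, 160), 16.0, 1500, False, "zero",
        ),
        ScalingPanel(
            "edges_population_composite", "population",
            {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 0.6},
            "edges", (10, 20, 40, 80, 160), 16.0, 1500, False, "theta_J-theta_Q",
        ),
        ScalingPanel(
            "triangles_population_f_small", "population",
            {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 0.5},
            "triangles", (200, 400, 800, 1600), 2.0, 2600, True, "theta_J",
            f_regime="small",
        ),
        ScalingPanel(
            "triangles_regulatory_f_near_one", "regulatory",
            {"B": 0.01, "alpha": 0.01, "a": 10.0, "b": 2.0},
            "triangles", (480, 960, 1920), 4.0, 2600, True, "theta_J+1",
            f_regime="near_one",
        ),
    ]
}


def star_response_sweep(
    model: DynamicsModel,
    degrees_list: Sequence[int],
    kind: str = "edges",
    bulk_n: int = 1500,
    bulk_degree: float = 16.0,
    source_in_bulk: bool = False,
    seed: int = 0,
    eta: float = 0.5,
    epsilon: float = 0.01,
    measure_E: bool = True,
) -> pd.DataFrame:
    """Simulated response time of an embedded-star target across degrees.

    For each degree the target is wired into the same seeded bulk (nested
    neighbour sets, so the sweep shares its random environment), the full
    nonlinear system is relaxed, perturbed at the source and integrated
    until the target's response ratio crosses eta.  Returns one row per
    degree with tau, the analytic J at the target's steady state, the
    measured adjacent-dynamics summary E, and the triangle amplification C.
    """
    rows = []
    for d in degrees_list:
        G, m, i = embedded_star(
            d, kind, bulk_n=bulk_n, bulk_degree=bulk_degree, seed=seed,
            source_in_bulk=source_in_bulk,
        )
        steady = find_steady_state(model, G, check_stability=False)
        res = perturb_and_track(model, G, steady, m, epsilon=epsilon, eta=eta, track=[i])
        row = {
            "d": d,
            "tau": float(res.tau[i]),
            "J": self_time_J(model, steady.x[i]),
            "x_target": float(steady.x[i]),
        }
        if measure_E:
            row["E"] = E_im_from_trajectories(res, model, G, steady, i).summary
            row["C"] = adjacent_amplification(model, G, steady, res.delta_x_inf, m, i)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_loglog(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Log-log least-squares slope and R^2."""
    fit = linregress(np.log(np.asarray(x, float)), np.log(np.asarray(y, float)))
    return float(fit.slope), float(fit.rvalue**2)


def run_panel(
    panel: ScalingPanel, seed: int = 0, eta: float = 0.5, epsilon: float = 0.01
) -> dict:
    """Run one scaling panel: sweep, slope fit, and the predicted exponent."""
    from .dynamics import scaling_exponents

    model = make_model(panel.model, panel.params)
    df = star_response_sweep(
        model,
        panel.degrees,
        kind=panel.kind,
        bulk_n=panel.bulk_n,
        bulk_degree=panel.bulk_degree,
        source_in_bulk=panel.source_in_bulk,
        seed=seed,
        eta=eta,
        epsilon=epsilon,
    )
    slope, r2 = fit_loglog(df["d"], df["tau"])
    est = scaling_exponents(model)
    tj, tq = est.theta_J, est.theta_Q
    expected = {
        "theta_J": tj,
        "theta_J-theta_Q": tj - tq,
        "theta_J+1": tj + 1.0,
        "zero": 0.0,
    }[panel.expected_exponent]
    return {
        "panel": panel.name,
        "slope": slope,
        "r2": r2,
        "expected": expected,
        "theta_J": tj,
        "theta_Q": tq,
        "sweep": df,
    }


# --- chains (global propagation) -----------------------------------------

def chain_response(
    model: DynamicsModel,
    degrees_seq: Sequence[int],
    eta: float = 0.5,
    epsilon: float = 0.01,
    mode: str = "linear",
):
    """Track a perturbation travelling down a degree-controlled chain.

    Returns (prediction, result, graph, path): the layer-time recursion
    (with direct crossing times), the raw perturbation result, and the
    backbone path.  ``mode='linear'`` (default) propagates the linearised
    response, which resolves the far layers whose asymptotic responses
    attenuate many orders of magnitude below the states themselves;
    ``mode='nonlinear'`` integrates the full clamped system.
    """
    G, source, path = chain_with_degrees(degrees_seq)
    steady = find_steady_state(model, G, check_stability=False)
    if mode == "linear":
        res = perturb_linear_response(model, G, steady, source, epsilon=epsilon, eta=eta)
    else:
        res = perturb_and_track(
            model, G, steady, source, epsilon=epsilon, eta=eta, track=list(path)
        )
    pred = global_times_recursive(res, model, G, path, eta=eta)
    return pred, res, G, path


def chain_ensemble(
    model: DynamicsModel,
    n_chains: int,
    length: int = 8,
    mean_range: tuple[float, float] = (3.0, 10.0),
    variance: float = 3.0,
    seed: int = 0,
    eta: float = 0.5,
) -> pd.DataFrame:
    """Arrival time at the chain end for an ensemble of random degree sequences."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_chains):
        mean = float(rng.uniform(*mean_range))
        try:
            seq = random_degree_sequence(length, mean, variance, seed=int(rng.integers(2**31)))
        except Exception:
            continue
        pred, res, G, path = chain_response(model, seq, eta=eta)
        rows.append(
            {
                "chain": k,
                "mean_degree": float(np.mean(seq)),
                "var_degree": float(np.var(seq)),
                "T_end": float(pred.T[-1]),
                "degrees": tuple(seq),
            }
        )
    return pd.DataFrame(rows)


# --- clustering sweep (global, triangles) --------------------------------

def clustering_sweep(
    model: DynamicsModel,
    targets: Sequence[float] = (0.05, 0.2, 0.4),
    n: int = 200,
    k: int = 10,
    beta: float = 0.05,
    n_sources: int = 5,
    seed: int = 0,
    eta: float = 0.5,
    max_steps: int = 60_000,
) -> pd.DataFrame:
    """Mean per-layer arrival times on small-worlds rewired to target clustering.

    The same base small-world graph is rewired (degree-preserving) to each
    clustering target; the perturbation is repeated from ``n_sources``
    seeded sources and arrival times are averaged per BFS layer.
    """
    base = generate_small_world(n, k, beta, seed=seed)
    rng = np.random.default_rng(seed + 1)
    sources = rng.choice(n, size=n_sources, replace=False)
    rows = []
    for target_C in targets:
        rw = rewire_to_clustering(base, target_C, seed=seed, max_steps=max_steps)
        G = rw.graph
        steady = find_steady_state(model, G, check_stability=False)
        for src in sources:
            res = perturb_and_track(model, G, steady, int(src), eta=eta)
            dist = layers(G, int(src))
            for node, ell in dist.items():
                if node == src or not math.isfinite(ell):
                    continue
                t = res.tau[node]
                if np.isfinite(t):
                    rows.append(
                        {
                            "target_C": target_C,
                            "clustering": rw.clustering,
                            "source": int(src),
                            "layer": int(ell),
                            "tau": float(t),
                        }
                    )
    return pd.DataFrame(rows)


# --- generic experiment runner -------------------------------------------

def run_experiment(cfg: ExperimentConfig, outdir: str | Path) -> dict:
    """Steady state -> perturbation -> response-time table, serialised.

    Writes ``manifest.json`` (config, hash, stage status), ``tau.tsv``
    (per-node response times with layers) and ``trajectories.tsv`` (time
    column plus one response-ratio column per node) under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "hash": config_hash(cfg), "stages": {}}
    try:
        model = make_model(cfg.model, cfg.params)
        G = build_topology(cfg.topology)
        manifest["stages"]["validate"] = "ok"
    except Exception as exc:
        manifest["stages"]["validate"] = f"failed: {exc}"
        dump_json(manifest, outdir / "manifest.json")
        raise
    steady = find_steady_state(model, G)
    manifest["stages"]["steady_state"] = {"residual": steady.residual, "stable": steady.stable}
    res = perturb_and_track(model, G, steady, cfg.source, epsilon=cfg.epsilon, eta=cfg.eta)
    manifest["stages"]["perturbation"] = "ok"

    dist = layers(G, cfg.source)
    tau_df = pd.DataFrame(
        {
            "node": sorted(G.nodes()),
            "layer": [dist[v] for v in sorted(G.nodes())],
            "delta_x_inf": res.delta_x_inf,
            "tau": res.tau,
            "overflow": res.overflow,
        }
    )
    tau_df.to_csv(outdir / "tau.tsv", sep="\t", index=False)
    traj = pd.DataFrame(res.delta_ratio, columns=[f"node_{v}" for v in sorted(G.nodes())])
    traj.insert(0, "time", res.times)
    traj.to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
    manifest["stages"]["serialise"] = "ok"
    dump_json(manifest, outdir / "manifest.json")
    return {"manifest": manifest, "tau": tau_df, "result": res}
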