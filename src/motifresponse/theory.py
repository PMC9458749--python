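"""Linear-response predictions for perturbation response times.

Local theory
------------
Linearising the clamped dynamics around the steady state gives, for each
node i, an intrinsic relaxation time ``J_i`` and an adjacent-dynamics term

    E_im(t) = J_i H1(x_i*) sum_{j != m} A_ij H2'(x_j*)
              * (Dx_j(t) - Dx_j(inf)) / (Dx_i(t) - Dx_i(inf)),

the correction to pure exponential relaxation contributed by neighbours
that have not themselves equilibrated.  Treating E as a constant yields
the closed-form response time ``tau_local``; when the source-target edge
sits inside triangles, the common neighbours feed the target in near
synchrony with it and the triangle form ``tau_triangle`` applies, with a
dynamics-dependent (degree-independent) synchrony constant f.

Asymptotic regimes in the target degree d:

    tau ~ d^theta_J              adjacent term negligible
    tau ~ d^(theta_J - theta_Q)  composite regime (theta_Q > 0, theta_J < 0)
    tau ~ d^(theta_J + 1)        triangle-dominated, f close to 1

Global theory
-------------
Along a propagation path m -> i_1 -> ... -> i_k, arrival times follow a
layer-by-layer Newton recursion on each node's response curve, and admit
a product form T(m -> i_k) ~ g^T D, where D carries the degree sequence
(with constants C1, C2 calibrated on a reference chain) and the weights
g accumulate adjacent-dynamics factors of the deeper layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import least_squares, minimize_scalar

from .dynamics import DynamicsModel, model_jacobian, scaling_exponents, self_time_J
from .errors import DomainError, RegimeValidityError
from .networks import adjacency
from .simulate import PerturbationResult, SteadyState

__all__ = [
    "linearized_rhs",
    "EimSeries",
    "E_im_from_trajectories",
    "adjacent_amplification",
    "tau_local",
    "tau_triangle",
    "ScalingPrediction",
    "predicted_scaling",
    "FEstimate",
    "estimate_f",
    "GlobalPathPrediction",
    "global_times_recursive",
    "build_g",
    "build_D",
    "global_times_product",
    "calibrate_constants",
]


# --- linearised system ----------------------------------------------------

def linearized_rhs(
    model: DynamicsModel,
    network: nx.Graph,
    steady: SteadyState,
    source: int,
    delta_source: float,
):
    """Linear response system of the clamped dynamics at the steady state.

    Returns ``(M, forcing, free)``: the (N-1)x(N-1) Jacobian of the clamped
    nonlinear system (source row/column removed), the constant forcing
    vector ``A_im H1(x_i*) H2'(x_m*) delta_source``, and the array of free
    node ids.  The linear response solves ``d(Dx)/dt = M Dx + forcing``.
    """
    A = adjacency(network)
    n = A.shape[0]
    xs = steady.x
    J_full = model_jacobian(model, xs, A)
    free = np.array([i for i in range(n) if i != source])
    M = J_full[free][:, free].tocsr()
    a_col = np.asarray(A[:, [source]].todense()).ravel()[free]
    forcing = a_col * model.H1(xs[free]) * float(model.H2prime(xs[source])) * delta_source
    lu = None
    try:
        lu = spla.splu(sp.csc_matrix(M))
    except RuntimeError as exc:  # exactly singular
        raise RegimeValidityError(f"linearised system is singular: {exc}") from exc
    return M, forcing, free


@dataclass
class EimSeries:
    """Time series of the adjacent-dynamics term with its scalar summary."""

    times: np.ndarray
    values: np.ndarray
    summary: float  # median over the mid-response window delta in [0.2, 0.8]
    n_window: int


def E_im_from_trajectories(
    result: PerturbationResult,
    model: DynamicsModel,
    network: nx.Graph,
    steady: SteadyState,
    target: int,
    window: tuple[float, float] = (0.2, 0.8),
) -> EimSeries:
    """Evaluate E_im(t) for a target node from stored trajectories.

    Points where the target's own residual underflows are masked.  The
    scalar summary is the median over the window where the target's
    response ratio lies in ``window`` — the regime over which the constant-E
    closed form is used.
    """
    xs = steady.x
    m = result.source
    nbrs = [j for j in network.neighbors(target) if j != m]
    Ji = self_time_J(model, xs[target])
    h1 = float(model.H1(xs[target]))
    w = np.array([float(model.H2prime(xs[j])) for j in nbrs])

    dx = result.delta_x
    dinf = result.delta_x_inf
    denom = dx[:, target] - dinf[target]
    floor = 1e-12 * abs(dinf[target]) + 1e-300
    mask = np.abs(denom) > floor
    vals = np.full(len(result.times), np.nan)
    if nbrs:
        resid = dx[:, nbrs] - dinf[nbrs]
        num = resid @ w
        vals[mask] = Ji * h1 * num[mask] / denom[mask]
    else:
        vals[mask] = 0.0
    delta = result.delta_ratio[:, target]
    sel = mask & (delta >= window[0]) & (delta <= window[1])
    summary = float(np.median(vals[sel])) if np.any(sel) else float("nan")
    return EimSeries(times=result.times, values=vals, summary=summary, n_window=int(sel.sum()))


def adjacent_amplification(
    model: DynamicsModel,
    network: nx.Graph,
    steady: SteadyState,
    delta_x_inf: np.ndarray,
    source: int,
    target: int,
) -> float:
    """Triangle/adjacent input of the target relative to the direct source input.

    C_im = [sum_{j != m} A_ij H2'(x_j*) Dx_j(inf)] / [H2'(x_m*) Dx_m]:
    the asymptotic neighbour contribution to the target's forcing divided
    by the source's direct contribution.  On a triangle-dominated local
    topology this grows linearly with the number of common neighbours,
    C_im ~ d_i * Qbar_im with a degree-independent mean-field factor
    Qbar_im.  Requires the target to be adjacent to the source.
    """
    if not network.has_edge(source, target):
        raise DomainError("adjacent_amplification needs target adjacent to source")
    xs = steady.x
    direct = float(model.H2prime(xs[source])) * delta_x_inf[source]
    if direct == 0:
        raise DomainError("zero direct forcing; C_im undefined")
    acc = 0.0
    for j in network.neighbors(target):
        if j == source:
            continue
        acc += float(model.H2prime(xs[j])) * delta_x_inf[j]
    return float(acc / direct)


# --- closed-form response times ------------------------------------------

def tau_local(J: float, eta: float, E: float) -> float:
    """Constant-E response time:
    tau = -J ln(1-eta) / (1 + [1/ln(1-eta)] [eta/(1-eta)] E)."""
    if not 0 < eta < 1:
        raise RegimeValidityError("eta must lie in (0, 1)")
    log1m = math.log(1 - eta)
    denom = 1.0 + (1.0 / log1m) * (eta / (1 - eta)) * E
    if denom <= 0:
        raise RegimeValidityError(
            f"adjacent term E={E} outside the validity region of the local formula"
        )
    return -J * log1m / denom


def tau_triangle(J: float, eta: float, C: float, f: float) -> float:
    """Triangle-dominated response time:
    tau = -ln(1-eta) J (1 + C) / (1 + (1-f) C)."""
    if not 0 < eta < 1:
        raise RegimeValidityError("eta must lie in (0, 1)")
    denom = 1.0 + (1.0 - f) * C
    if denom == 0:
        raise RegimeValidityError("zero denominator: (1-f) C = -1")
    return -math.log(1 - eta) * J * (1 + C) / denom


@dataclass(frozen=True)
class ScalingPrediction:
    exponent: float
    regime: str
    theta_J: float
    theta_Q: float
    alternative: float | None = None  # populated when the regime is ambiguous


def predicted_scaling(
    model: DynamicsModel,
    topology: str,
    f_regime: str | None = None,
    hbar: float = 1.0,
) -> ScalingPrediction:
    """Predicted large-degree exponent of tau(d) for a local topology.

    topology='independent_edges': theta_J when the adjacent term decays
    (theta_Q < 0) or when the self-dynamics does not (theta_J >= 0); the
    composite exponent theta_J - theta_Q when theta_Q > 0 and theta_J < 0.
    topology='triangles': theta_J for f well below 1, theta_J + 1 for
    f close to 1 (``f_regime`` in {'small', 'near_one'}).
    """
    est = scaling_exponents(model, hbar=hbar)
    tj, tq = est.theta_J, est.theta_Q
    if topology == "triangles":
        if f_regime == "near_one":
            return ScalingPrediction(tj + 1.0, "triangle_f_near_one", tj, tq)
        if f_regime == "small":
            return ScalingPrediction(tj, "triangle_f_small", tj, tq)
        raise RegimeValidityError("triangle topology needs f_regime 'small' or 'near_one'")
    if topology != "independent_edges":
        raise RegimeValidityError(f"unknown topology {topology!r}")
    if abs(tq) < 1e-9:
        raise RegimeValidityError(
            f"theta_Q = 0: regime ambiguous between {tj} and {tj - tq}"
        )
    if tq < 0:
        return ScalingPrediction(tj, "self_dynamics", tj, tq)
    if tj >= 0:
        return ScalingPrediction(tj, "degree_limited", tj, tq)
    return ScalingPrediction(tj - tq, "composite", tj, tq)


# --- triangle synchrony constant -----------------------------------------

@dataclass(frozen=True)
class FEstimate:
    f: float
    residual: float
    subset_values: tuple[float, ...]
    stable: bool


def estimate_f(
    samples: Sequence[tuple[float, float, float, float]],
    eta: float,
    stability_tol: float = 0.10,
) -> FEstimate:
    """Fit the synchrony constant f of the triangle response-time formula.

    ``samples`` holds (d, tau_sim, J, C_im) tuples from triangle-star
    simulations at distinct degrees.  f minimises the squared log-residuals
    of the triangle formula; stability across degree subsets (low half vs
    high half) checks the degree-independence the theory asserts.
    """
    if len(samples) < 4:
        raise RegimeValidityError("need at least 4 samples at distinct degrees")

    def fit(subset) -> tuple[float, float]:
        def loss(f: float) -> float:
            acc = 0.0
            for _, tau_sim, J, C in subset:
                pred = tau_triangle(J, eta, C, f)
                if pred <= 0:
                    return 1e12
                acc += (math.log(pred) - math.log(tau_sim)) ** 2
            return acc

        res = minimize_scalar(
            loss, bounds=(-5.0, 1.0 - 1e-9), method="bounded", options={"xatol": 1e-10}
        )
        return float(res.x), float(res.fun)

    ordered = sorted(samples)
    f_all, resid = fit(ordered)
    half = len(ordered) // 2
    f_lo, _ = fit(ordered[:half])
    f_hi, _ = fit(ordered[half:])
    ref = max(abs(f_all), 1e-6)
    stable = abs(f_lo - f_hi) <= 2 * stability_tol * ref
    return FEstimate(f=f_all, residual=resid, subset_values=(f_lo, f_hi), stable=stable)


# --- global propagation ---------------------------------------------------

@dataclass
class GlobalPathPrediction:
    """Per-layer propagation times along a path, with the product-form pieces."""

    path: list[int]
    T: np.ndarray  # recursive (Newton) layer times
    T_direct: np.ndarray  # direct eta-crossing times for cross-checking
    fallback: np.ndarray  # layers where Newton fell back to the direct crossing
    g: np.ndarray | None = None
    D: np.ndarray | None = None
    C1: float | None = None
    C2: float | None = None


def global_times_recursive(
    result: PerturbationResult,
    model: DynamicsModel,
    network: nx.Graph,
    path: Sequence[int],
    eta: float | None = None,
    max_iter: int = 60,
) -> GlobalPathPrediction:
    """Layer-by-layer Newton recursion for arrival times along a path.

    Starting from T_0 = 0 at the source, each layer's time updates by a
    Newton step on Dx_{i_k}(t) - eta Dx_{i_k}(inf), with the stationary
    limit D(dx)/dt(inf) = 0 substituted; the update is iterated to
    convergence, seeded at the previous layer's time.  Direct crossing
    times are reported alongside; a layer where the Newton iteration
    degenerates (flat trajectory) falls back to the direct crossing and is
    flagged.
    """
    eta = result.eta if eta is None else eta
    A = adjacency(network)
    path = list(path)
    if path[0] != result.source:
        raise RegimeValidityError("path must start at the perturbation source")
    t_end = result._segments[-1].t[-1] if result._segments else float(result.times[-1])
    T = np.zeros(len(path))
    direct = np.zeros(len(path))
    fallback = np.zeros(len(path), dtype=bool)
    for k in range(1, len(path)):
        node = path[k]
        dinf = result.delta_x_inf[node]
        direct[k] = result.tau[node]
        t = min(max(T[k - 1], 0.0), t_end)
        ok = False
        for _ in range(max_iter):
            x = result.state_at(t)
            dx = x[node] - result.steady.x[node]
            num = dx - eta * dinf
            dxdot = result.state_derivative_at(t, model, A)[node]
            if abs(dxdot) < 1e-300:
                break
            t_new = t - num / dxdot
            if not (0.0 <= t_new <= t_end * 1.5):
                break
            if abs(t_new - t) <= 1e-12 * max(t_new, 1.0):
                t = t_new
                ok = True
                break
            t = t_new
        if ok and np.isfinite(t):
            T[k] = t
        else:
            T[k] = direct[k]
            fallback[k] = True
    return GlobalPathPrediction(path=path, T=T, T_direct=direct, fallback=fallback)


def build_g(E_sequence: Sequence[float]) -> np.ndarray:
    """Layer weights g(h) = prod_{j=h+1..k} 1/(1 - E_j).

    ``E_sequence[j-1]`` is the adjacent-dynamics term of layer j; the first
    entry is not used (the product starts above the queried layer).  Raises
    when any factor has E >= 1, outside the validity of the geometric form.
    """
    E = np.asarray(E_sequence, dtype=float)
    if np.any(E >= 1):
        raise RegimeValidityError("every layer E must be < 1")
    k = len(E)
    g = np.empty(k)
    acc = 1.0
    for h in range(k - 1, -1, -1):
        g[h] = acc
        acc *= 1.0 / (1.0 - E[h])
    return g


def build_D(
    degrees_seq: Sequence[float],
    theta_J: float,
    theta_Q: float,
    C1: float,
    C2: float,
    eta: float,
) -> np.ndarray:
    """Degree-sequence vector D of the product-form propagation time.

    First component: -ln(1-eta) d_1^theta_J / (1 - C1 C2 d_1^theta_Q);
    subsequent components: d_k^theta_J / (1 - C2 d_k^theta_Q).
    """
    d = np.asarray(degrees_seq, dtype=float)
    if d.size == 0:
        return np.empty(0)
    denom = 1.0 - C2 * d**theta_Q
    denom[0] = 1.0 - C1 * C2 * d[0] ** theta_Q
    if np.any(denom <= 0):
        raise RegimeValidityError("non-positive denominator in D: constants outside the admissible region")
    out = d**theta_J / denom
    out[0] *= -math.log(1.0 - eta)
    return out


def global_times_product(E_sequence: Sequence[float], D: np.ndarray) -> np.ndarray:
    """Cumulative product-form predictions g(1:k)^T D(1:k) for every prefix k.

    The weight vector is rebuilt per prefix because g is defined relative
    to the last layer of the path considered.
    """
    D = np.asarray(D, dtype=float)
    E = np.asarray(E_sequence, dtype=float)
    if D.shape != E.shape:
        raise ValueError(f"shape mismatch: D {D.shape} vs E {E.shape}")
    out = np.empty(len(D))
    for k in range(1, len(D) + 1):
        g = build_g(E[:k])
        out[k - 1] = float(g @ D[:k])
    return out


def calibrate_constants(
    degrees_seq: Sequence[float],
    T_ref: Sequence[float],
    theta_J: float,
    theta_Q: float,
    eta: float,
    E_sequence: Sequence[float] | None = None,
) -> tuple[float, float, float]:
    """Least-squares calibration of the constants C1, C2 of the D vector.

    Fits (C1, C2) so that the product-form prefix predictions, scaled to
    match the first layer of ``T_ref`` (the proportionality of the product
    form is fixed there), reproduce the reference layer times of a
    calibration chain.  Returns (C1, C2, anchor), the anchor being the
    layer-1 reference time that fixes the proportionality.
    """
    d = np.asarray(degrees_seq, dtype=float)
    T_ref = np.asarray(T_ref, dtype=float)
    E = np.zeros_like(d) if E_sequence is None else np.asarray(E_sequence, dtype=float)
    # keep all denominators strictly positive across the chain's degrees
    cap = 0.95 / float(np.max(d**theta_Q))

    def predict(c1: float, c2: float) -> np.ndarray:
        D = build_D(d, theta_J, theta_Q, c1, c2, eta)
        pred = global_times_product(E, D)
        return pred / pred[0] * T_ref[0]

    def resid(p):
        c1, c2 = p
        try:
            pred = predict(c1, c2)
        except RegimeValidityError:
            return np.full(len(T_ref) - 1, 1e6)
        return (pred[1:] - T_ref[1:]) / T_ref[1:]

    fit = least_squares(resid, x0=[0.1, min(0.1, cap / 2)], bounds=([0, 0], [10.0, cap]))
    c1, c2 = fit.x
    return float(c1), float(c2), float(T_ref[0])
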