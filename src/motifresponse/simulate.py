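"""Steady states, permanent perturbations, and response-time measurement.

The protocol: integrate the coupled system to its stable equilibrium x*,
shift the source node m to x_m* (1 + epsilon) and hold it there (the
permanent perturbation enters the remaining equations as a constant
forcing), then track every node's response

    delta_i(t) = Dx_i(t) / Dx_i(inf),

where Dx_i(inf) is obtained from the clamped system's fixed point rather
than from a long integration.  The response time tau_im is the first
crossing delta_i(t) = eta, located by root-finding on the integrator's
dense output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .dynamics import DynamicsModel, model_jacobian, model_rhs, steady_state_meanfield
from .errors import ConvergenceError, ParameterError
from .networks import adjacency, degrees

__all__ = [
    "SteadyState",
    "PerturbationResult",
    "LinearPerturbationResult",
    "find_steady_state",
    "perturb_and_track",
    "perturb_linear_response",
    "layers",
    "layer_time_by_triangles",
]

# numeric floors / tolerances shared by the solvers
_RESPONSE_FLOOR = 1e-14


@dataclass
class SteadyState:
    """A stable equilibrium of the unperturbed system."""

    x: np.ndarray
    residual: float
    converged: bool
    stable: bool | None = None  # None when the stability check was skipped


@dataclass
class PerturbationResult:
    """Trajectories and response times of a single-source perturbation.

    ``tau`` holds NaN where the response time is undefined (asymptotic
    response below the noise floor, or no crossing before the integration
    horizon — the ``overflow`` flag marks the latter).
    """

    source: int
    delta_source: float
    eta: float
    epsilon: float
    times: np.ndarray
    delta_x: np.ndarray  # shape (n_times, N)
    delta_x_inf: np.ndarray
    delta_ratio: np.ndarray  # shape (n_times, N)
    tau: np.ndarray
    overflow: np.ndarray
    steady: SteadyState
    _segments: list = field(default_factory=list, repr=False)
    _free: np.ndarray | None = field(default=None, repr=False)

    def delta_at(self, t: float, node: int) -> float:
        """Response ratio delta_node(t) from the dense integrator output."""
        x = self.state_at(t)
        dinf = self.delta_x_inf[node]
        return float((x[node] - self.steady.x[node]) / dinf)

    def state_at(self, t: float) -> np.ndarray:
        """Full state vector at time t (dense output, clamped source)."""
        seg = None
        for s in self._segments:
            if s.t[0] <= t <= s.t[-1]:
                seg = s
                break
        if seg is None:
            seg = self._segments[-1]
            t = min(max(t, seg.t[0]), seg.t[-1])
        y = seg.sol(t)
        x = np.empty(self.steady.x.shape)
        x[self.source] = self.steady.x[self.source] + self.delta_source
        x[self._free] = y
        return x

    def state_derivative_at(self, t: float, model: DynamicsModel, A) -> np.ndarray:
        """Time derivative of the clamped system at time t."""
        x = self.state_at(t)
        dx = model_rhs(model, x, A)
        dx[self.source] = 0.0
        return dx


def _damped_newton(fun, jac, x0, *, positive: bool, tol_scale: float, max_iter: int = 80):
    """Newton iteration with residual backtracking and optional positivity."""
    x = np.asarray(x0, dtype=float).copy()
    res = np.max(np.abs(fun(x)))
    for _ in range(max_iter):
        if res < tol_scale:
            break
        J = sp.csc_matrix(jac(x))
        step = spla.spsolve(J, -fun(x))
        lam = 1.0
        if positive:
            while np.any(x + lam * step <= 0) and lam > 1e-12:
                lam /= 2.0
        for _ in range(40):
            cand = np.max(np.abs(fun(x + lam * step)))
            if cand < res:
                break
            lam /= 2.0
        else:
            break
        if lam * np.max(np.abs(step) / np.maximum(np.abs(x), 1e-12)) < 1e-15:
            x = x + lam * step
            res = np.max(np.abs(fun(x)))
            break
        x = x + lam * step
        res = np.max(np.abs(fun(x)))
    return x, res


def _tolerances(n: int, profile: str | None) -> tuple[float, float]:
    if profile == "strict" or (profile is None and n <= 500):
        return 1e-9, 1e-12
    return 1e-6, 1e-9


def _meanfield_seed(model: DynamicsModel, deg: np.ndarray, A) -> np.ndarray:
    """Self-consistent mean-field initial condition.

    Iterates x_i = R^{-1}(d_i * Hbar) with Hbar recomputed from the current
    state, which lands near the positive equilibrium even when the
    adjacent interaction makes node states strongly degree-amplified.
    """
    n = len(deg)
    x = np.ones(n)
    hbar = 1.0
    for _ in range(80):
        x_new = np.empty(n)
        for i in range(n):
            try:
                x_new[i] = steady_state_meanfield(model, max(deg[i], 1.0), hbar)
            except Exception:
                x_new[i] = x[i]
        hbar_new = float(np.mean((A @ model.H2(x_new)) / np.maximum(deg, 1.0)))
        if not np.isfinite(hbar_new) or hbar_new <= 0:
            break
        if abs(hbar_new - hbar) <= 1e-10 * abs(hbar):
            x = x_new
            break
        x, hbar = x_new, hbar_new
    return np.maximum(x, 1e-6)


def find_steady_state(
    model: DynamicsModel,
    network: nx.Graph,
    x0: np.ndarray | None = None,
    tol: float = 1e-10,
    check_stability: bool | None = None,
    t_burn: float = 50.0,
) -> SteadyState:
    """Integrate to the attracting equilibrium, then polish with Newton.

    The default initial condition is the self-consistent mean-field seed;
    the burn-in horizon doubles until the residual is small enough for the
    Newton polish to be safely inside the equilibrium's basin.  Convergence
    means max |rhs| below ``tol`` relative to the scale of F on the
    equilibrium.
    """
    A = adjacency(network)
    n = A.shape[0]
    deg = degrees(network)
    if x0 is None:
        x0 = _meanfield_seed(model, deg, A)

    def fun(x):
        return model_rhs(model, x, A)

    def jac(x):
        return model_jacobian(model, x, A)

    rtol, atol = _tolerances(n, None)
    lo, hi = model.domain
    clip_lo = lo + 1e-12 if math.isfinite(lo) else 1e-12

    x = np.maximum(np.asarray(x0, dtype=float), clip_lo)
    t0, horizon = 0.0, t_burn
    res = None
    for _ in range(14):
        sol = solve_ivp(
            lambda t, x: fun(np.maximum(x, clip_lo)),
            (t0, t0 + horizon),
            x,
            method="BDF",
            jac=lambda t, x: jac(np.maximum(x, clip_lo)),
            rtol=rtol,
            atol=atol,
        )
        x = np.maximum(sol.y[:, -1], clip_lo)
        t0 += horizon
        horizon *= 2.0
        scale = max(float(np.max(np.abs(model.F(x)))), 1.0)
        if np.max(np.abs(fun(x))) < 1e-6 * scale:
            break
    x_burn = x.copy()
    scale = max(float(np.max(np.abs(model.F(x)))), 1.0)
    x, res = _damped_newton(fun, jac, x, positive=True, tol_scale=tol * scale)
    if np.max(x) < 1e-8 * np.max(x_burn):
        # Newton collapsed onto the trivial branch; stay on the integrated state
        raise ConvergenceError(
            "Newton polish collapsed to the trivial equilibrium; "
            "increase t_burn or provide x0"
        )
    converged = res < tol * scale
    if not converged:
        raise ConvergenceError(f"steady state residual {res:.3g} above tolerance")

    stable: bool | None = None
    if check_stability or (check_stability is None and n <= 400):
        eigs = np.linalg.eigvals(jac(x).toarray())
        stable = bool(np.max(eigs.real) < 0)
    return SteadyState(x=x, residual=float(res), converged=converged, stable=stable)


def perturb_and_track(
    model: DynamicsModel,
    network: nx.Graph,
    steady: SteadyState,
    source: int,
    epsilon: float = 0.01,
    eta: float = 0.5,
    t_max: float = 1e6,
    n_grid: int = 400,
    converge_frac: float = 0.01,
    track: Sequence[int] | None = None,
) -> PerturbationResult:
    """Clamp the source at x_m*(1+epsilon) and track every node's response.

    The integration horizon grows geometrically until the tracked nodes'
    response ratios are within ``converge_frac`` of 1 (or ``t_max`` is
    reached, in which case unfinished nodes carry the overflow flag).
    ``track=None`` tracks all nodes; passing a subset (e.g. just the
    target) lets large sweeps stop integrating as soon as the nodes of
    interest have crossed eta.
    """
    if not steady.converged:
        raise ParameterError("steady state did not converge")
    if not 0 < eta < 1:
        raise ParameterError("eta must lie in (0, 1)")
    A = adjacency(network)
    n = A.shape[0]
    xs = steady.x
    dx_m = epsilon * xs[source]
    x_clamp = xs[source] + dx_m
    free = np.array([i for i in range(n) if i != source])

    def full_state(y):
        x = np.empty(n)
        x[source] = x_clamp
        x[free] = y
        return x

    def rhs_free(t, y):
        return model_rhs(model, full_state(y), A)[free]

    def jac_free(t, y):
        J = model_jacobian(model, full_state(y), A)
        return J[free][:, free]

    # asymptotic responses from the clamped fixed point (Newton)
    scale = max(float(np.max(np.abs(model.F(xs)))), 1.0)
    y_inf, res_inf = _damped_newton(
        lambda y: rhs_free(0.0, y),
        lambda y: jac_free(0.0, y),
        xs[free],
        positive=True,
        tol_scale=1e-12 * scale,
    )
    dx_inf = np.empty(n)
    dx_inf[source] = dx_m
    dx_inf[free] = y_inf - xs[free]

    watch = np.array(sorted(set(track))) if track is not None else np.arange(n)
    watch_free = np.array([i for i in watch if i != source])
    sizable = watch_free[np.abs(dx_inf[watch_free]) > _RESPONSE_FLOOR]

    rtol, atol = _tolerances(n, None)
    segments = []
    t0, horizon = 0.0, 1.0
    y = xs[free].copy()
    idx_free = {node: k for k, node in enumerate(free)}
    while t0 < t_max:
        seg = solve_ivp(
            rhs_free,
            (t0, min(t0 + horizon, t_max)),
            y,
            method="BDF",
            jac=jac_free,
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        segments.append(seg)
        y = seg.y[:, -1]
        t0 = seg.t[-1]
        if sizable.size == 0:
            break
        rel = np.abs(
            (y[[idx_free[i] for i in sizable]] - xs[sizable]) / dx_inf[sizable] - 1.0
        )
        if np.max(rel) < converge_frac:
            break
        horizon *= 2.0

    t_end = segments[-1].t[-1]
    result = PerturbationResult(
        source=source,
        delta_source=dx_m,
        eta=eta,
        epsilon=epsilon,
        times=np.empty(0),
        delta_x=np.empty((0, n)),
        delta_x_inf=dx_inf,
        delta_ratio=np.empty((0, n)),
        tau=np.full(n, np.nan),
        overflow=np.zeros(n, dtype=bool),
        steady=steady,
        _segments=segments,
        _free=free,
    )

    # dense evaluation grid: linear head, log-spaced tail
    n_head = max(n_grid // 8, 8)
    head = np.linspace(0.0, t_end * 1e-3, n_head, endpoint=False)
    tail = np.geomspace(t_end * 1e-3, t_end, n_grid - n_head)
    tgrid = np.concatenate([head, tail])
    states = np.array([result.state_at(t) for t in tgrid])
    delta_x = states - xs
    delta_x[:, source] = dx_m
    with np.errstate(invalid="ignore", divide="ignore"):
        delta_ratio = delta_x / dx_inf

    tau = np.full(n, np.nan)
    overflow = np.zeros(n, dtype=bool)
    tau[source] = 0.0
    for node in watch:
        if node == source:
            continue
        if abs(dx_inf[node]) <= _RESPONSE_FLOOR:
            continue  # response below noise floor: tau undefined
        dcurve = delta_ratio[:, node]
        above = np.nonzero(dcurve >= eta)[0]
        if above.size == 0:
            overflow[node] = True
            continue
        k = above[0]
        lo = tgrid[k - 1] if k > 0 else 0.0
        hi = tgrid[k]
        f = lambda t, node=node: result.delta_at(t, node) - eta
        if f(lo) >= 0:
            tau[node] = lo
        else:
            tau[node] = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)

    result.times = tgrid
    result.delta_x = delta_x
    result.delta_ratio = delta_ratio
    result.tau = tau
    result.overflow = overflow
    return result


class LinearPerturbationResult(PerturbationResult):
    """Perturbation response computed from the linearised dynamics.

    Used where asymptotic responses attenuate over many propagation layers
    to amplitudes far below the nonlinear integrator's noise floor
    (differences of O(1) states cannot resolve 1e-12 responses in double
    precision, while the linear system tracks the response itself).  The
    trajectory is the closed form Dx(t) = (e^{Mt} - I) M^{-1} f, evaluated
    by eigendecomposition.
    """

    def _delta_vec(self, t: float) -> np.ndarray:
        lam, V, Vinv_f = self._eig
        with np.errstate(over="ignore"):
            phi = np.where(
                np.abs(lam) > 1e-300, (np.exp(lam * t) - 1.0) / lam, t
            )
        return np.real(V @ (phi * Vinv_f))

    def state_at(self, t: float) -> np.ndarray:
        x = self.steady.x.copy()
        x[self.source] += self.delta_source
        x[self._free] += self._delta_vec(t)
        return x

    def state_derivative_at(self, t: float, model=None, A=None) -> np.ndarray:
        lam, V, Vinv_f = self._eig
        dvec = np.real(V @ (np.exp(lam * t) * Vinv_f))
        out = np.zeros_like(self.steady.x)
        out[self._free] = dvec
        return out

    def delta_at(self, t: float, node: int) -> float:
        if node == self.source:
            return 1.0
        k = self._free_index[node]
        return float(self._delta_vec(t)[k] / self.delta_x_inf[node])


def perturb_linear_response(
    model: DynamicsModel,
    network: nx.Graph,
    steady: SteadyState,
    source: int,
    epsilon: float = 0.01,
    eta: float = 0.5,
    n_grid: int = 400,
    track: Sequence[int] | None = None,
) -> LinearPerturbationResult:
    """Linear-response counterpart of :func:`perturb_and_track`.

    Solves the clamped system linearised at the steady state exactly (by
    eigendecomposition), so response ratios and crossing times are accurate
    even for nodes whose asymptotic response is many orders of magnitude
    below their state.  Valid in the same small-perturbation regime the
    response-time theory addresses.
    """
    if not steady.converged:
        raise ParameterError("steady state did not converge")
    if not 0 < eta < 1:
        raise ParameterError("eta must lie in (0, 1)")
    A = adjacency(network)
    n = A.shape[0]
    xs = steady.x
    dx_m = epsilon * xs[source]
    free = np.array([i for i in range(n) if i != source])
    J_full = model_jacobian(model, xs, A)
    M = J_full[free][:, free].toarray()
    a_col = np.asarray(A[:, [source]].todense()).ravel()[free]
    forcing = a_col * model.H1(xs[free]) * float(model.H2prime(xs[source])) * dx_m

    lam, V = np.linalg.eig(M)
    if np.max(lam.real) >= 0:
        raise ConvergenceError("clamped linear system is not stable")
    Vinv_f = np.linalg.solve(V, forcing.astype(complex))
    dx_inf_free = -np.linalg.solve(M, forcing)
    dx_inf = np.empty(n)
    dx_inf[source] = dx_m
    dx_inf[free] = dx_inf_free

    result = LinearPerturbationResult(
        source=source,
        delta_source=dx_m,
        eta=eta,
        epsilon=epsilon,
        times=np.empty(0),
        delta_x=np.empty((0, n)),
        delta_x_inf=dx_inf,
        delta_ratio=np.empty((0, n)),
        tau=np.full(n, np.nan),
        overflow=np.zeros(n, dtype=bool),
        steady=steady,
        _free=free,
    )
    result._eig = (lam, V, Vinv_f)
    result._free_index = {node: k for k, node in enumerate(free)}

    # time horizon: slowest decay mode sets the scale
    t_slow = 1.0 / np.min(np.abs(lam.real))
    t_end = 20.0 * t_slow

    watch = np.array(sorted(set(track))) if track is not None else np.arange(n)
    n_head = max(n_grid // 8, 8)
    head = np.linspace(0.0, t_end * 1e-4, n_head, endpoint=False)
    tail = np.geomspace(t_end * 1e-4, t_end, n_grid - n_head)
    tgrid = np.concatenate([head, tail])
    delta_x = np.zeros((len(tgrid), n))
    for k, t in enumerate(tgrid):
        delta_x[k, free] = result._delta_vec(t)
        delta_x[k, source] = dx_m
    with np.errstate(invalid="ignore", divide="ignore"):
        delta_ratio = delta_x / dx_inf

    tau = np.full(n, np.nan)
    tau[source] = 0.0
    for node in watch:
        if node == source:
            continue
        if abs(dx_inf[node]) <= 1e-280:
            continue
        dcurve = delta_ratio[:, node]
        above = np.nonzero(dcurve >= eta)[0]
        f = lambda t, node=node: result.delta_at(t, node) - eta
        if above.size == 0:
            hi = t_end
            ok = False
            for _ in range(60):
                hi *= 2.0
                if f(hi) >= 0:
                    ok = True
                    break
            if not ok:
                result.overflow[node] = True
                continue
            tau[node] = brentq(f, t_end, hi, xtol=1e-12, rtol=1e-12)
            continue
        k = above[0]
        lo = tgrid[k - 1] if k > 0 else 0.0
        if f(lo) >= 0:
            tau[node] = lo
        else:
            tau[node] = brentq(f, lo, tgrid[k], xtol=1e-12, rtol=1e-12)

    result.times = tgrid
    result.delta_x = delta_x
    result.delta_ratio = delta_ratio
    result.tau = tau
    return result


def layers(network: nx.Graph, source: int) -> dict[int, float]:
    """Shortest-path (BFS) distance of every node from the source;
    unreachable nodes get math.inf."""
    if source not in network:
        raise KeyError(f"source {source} not in network")
    dist = nx.single_source_shortest_path_length(network, source)
    return {v: float(dist.get(v, math.inf)) for v in network.nodes()}


def layer_time_by_triangles(
    result: PerturbationResult,
    network: nx.Graph,
    attribution: str = "bfs",
) -> pd.DataFrame:
    """Group response times by BFS layer and triangle count of the entry edge.

    ``attribution='bfs'`` counts triangles on each node's BFS-tree entry
    edge (a predecessor on a shortest path); ``attribution='direct'``
    restricts to layer-1 nodes and uses the direct source-node edge.
    Groups of size < 2 report the standard deviation as missing.
    """
    from .networks import triangles_through_edge

    src = result.source
    dist = layers(network, src)
    rows = []
    for node in network.nodes():
        if node == src or not math.isfinite(dist[node]):
            continue
        t = result.tau[node]
        if not np.isfinite(t):
            continue
        if attribution == "direct":
            if dist[node] != 1:
                continue
            entry = (src, node)
        else:
            preds = [u for u in network.neighbors(node) if dist[u] == dist[node] - 1]
            entry = (preds[0], node)
        rows.append(
            {
                "layer": int(dist[node]),
                "triangles": triangles_through_edge(network, entry),
                "tau": float(t),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["layer", "triangles", "mean_tau", "sd_tau", "n"])
    out = (
        df.groupby(["layer", "triangles"])["tau"]
        .agg(mean_tau="mean", sd_tau="std", n="count")
        .reset_index()
    )
    out.loc[out["n"] < 2, "sd_tau"] = np.nan
    return out
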