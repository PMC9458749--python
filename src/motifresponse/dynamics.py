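"""Prototypical dynamics on networks and their degree-scaling exponents.

Each model is a pairwise-coupled system

    dx_i/dt = F(x_i) + sum_j A_ij H1(x_i) H2(x_j),

captured by the triplet {F, H1, H2} of scalar functions.  Seven named models
are registered (gene regulation, human social activity, SIS epidemics,
mutualistic ecosystems, population flow, biochemical binding, inhibitory
neuronal dynamics).  From the triplet everything else follows:

* ``R(x) = -F(x)/H1(x)`` relates a node's state to the aggregate input of
  its neighbours; at a steady state ``R(x_i*) = sum_j A_ij H2(x_j*)``,
  which the mean field collapses to ``R(x_i*) = d_i * Hbar``.
* ``J_i`` is the intrinsic relaxation time of node i linearised around the
  steady state; ``Q_i = J_i H1(x_i*) H2'(x_i*)`` weights the feedback a
  node receives from its neighbours' transients.
* The leading powers of ``J`` and of ``d * Q`` in the node degree — the
  exponents ``theta_J`` and ``theta_Q`` — classify the large-degree
  response-time regimes.  They are extracted numerically by a log-log
  slope fit over a geometric degree grid and cross-checked against the
  registry's closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.stats import linregress

from .errors import (
    DegenerateEquilibriumError,
    DomainError,
    ModelRegistryError,
    NoSolutionError,
    ParameterError,
)

__all__ = [
    "DynamicsModel",
    "MeanFieldContext",
    "ExponentEstimate",
    "MODEL_NAMES",
    "make_model",
    "model_rhs",
    "model_jacobian",
    "R_of_x",
    "steady_state_meanfield",
    "compute_Hbar",
    "self_time_J",
    "Q_factor",
    "leading_exponent",
    "scaling_exponents",
    "default_degree_grid",
]

ArrayLike = np.ndarray | float


@dataclass(frozen=True)
class DynamicsModel:
    """A {F, H1, H2} triplet with analytic derivatives and metadata.

    ``domain`` is the open interval of physically meaningful states on
    which ``R`` is strictly monotone (the branch used for the mean-field
    steady state).  ``theta_closed_form`` maps the parameter record to the
    analytic (theta_J, theta_Q) pair and is used only as a cross-check of
    the numeric extractor.
    """

    name: str
    params: Mapping[str, float]
    F: Callable[[ArrayLike], ArrayLike]
    Fprime: Callable[[ArrayLike], ArrayLike]
    H1: Callable[[ArrayLike], ArrayLike]
    H1prime: Callable[[ArrayLike], ArrayLike]
    H2: Callable[[ArrayLike], ArrayLike]
    H2prime: Callable[[ArrayLike], ArrayLike]
    domain: tuple[float, float] = (0.0, math.inf)
    R_increasing: bool = True
    theta_closed_form: Callable[[Mapping[str, float]], tuple[float, float]] | None = None

    def rhs(self, x: np.ndarray, A) -> np.ndarray:
        return model_rhs(self, x, A)

    def jacobian(self, x: np.ndarray, A):
        return model_jacobian(self, x, A)


@dataclass(frozen=True)
class MeanFieldContext:
    """Mean-field constants entering the local response theory.

    hbar
        Network average of the adjacent interaction, ``Hbar`` — the mean of
        ``H2`` over each node's neighbours, averaged over nodes.
    qbar_im
        Degree-independent mean adjacent factor for a given source; the
        average of ``Q_j`` (weighted by the transient-shape factor) over the
        target's relevant neighbours.  Optional; only the theory module
        fills it in.
    source
        Node id of the perturbation source, when tied to one.
    """

    hbar: float = 1.0
    qbar_im: float | None = None
    source: int | None = None


@dataclass(frozen=True)
class ExponentEstimate:
    """Leading power of a degree-indexed positive quantity."""

    exponent: float
    r_squared: float
    fit_range: tuple[float, float]
    n_points: int
    flagged: bool = False

    def __float__(self) -> float:  # allows math on the estimate directly
        return self.exponent


def _as_pos(x: ArrayLike) -> np.ndarray:
    return np.asarray(x, dtype=float)


# --- model registry -------------------------------------------------------

_REQUIRED: dict[str, tuple[str, ...]] = {
    "regulatory": ("B", "alpha", "a", "b"),
    "human": ("B", "alpha", "a", "b", "c"),
    "epidemics": ("B", "alpha"),
    "mutualistic": ("B", "alpha", "a", "C"),
    "population": ("B", "alpha", "a", "b"),
    "biochemical": ("B", "C", "alpha"),
    "inhibitory": ("B", "C", "alpha"),
}

_POSITIVE: dict[str, tuple[str, ...]] = {
    "regulatory": ("B", "alpha", "a", "b"),
    "human": ("B", "alpha", "a", "c"),
    "epidemics": ("B", "alpha"),
    "mutualistic": ("B", "alpha", "a", "C"),
    "population": ("B", "alpha", "a", "b"),
    "biochemical": ("B", "C", "alpha"),
    "inhibitory": ("B", "C", "alpha"),
}

MODEL_NAMES: tuple[str, ...] = tuple(_REQUIRED)


def _check_params(name: str, params: Mapping[str, float]) -> dict[str, float]:
    required = _REQUIRED[name]
    out: dict[str, float] = {}
    for key in required:
        if key not in params:
            raise ParameterError(f"{name}: missing parameter {key!r}")
        out[key] = float(params[key])
    for key, value in params.items():
        out.setdefault(key, float(value))
    for key, value in out.items():
        if value < 0:
            raise ParameterError(f"{name}: parameter {key!r} must be non-negative, got {value}")
    for key in _POSITIVE[name]:
        if out[key] == 0:
            raise ParameterError(f"{name}: parameter {key!r} must be strictly positive")
    return out


def make_model(name: str, params: Mapping[str, float]) -> DynamicsModel:
    """Build a registered dynamics model from a parameter record.

    The triplet factorisation is fixed per model; multiplicative constants
    are absorbed into ``H1`` and the sign of the biochemical ``-alpha x_i x_j``
    coupling lives in ``H1``.  All derived quantities (``J``, ``Q``) are
    invariant to the particular split.
    """
    if name not in _REQUIRED:
        raise ModelRegistryError(
            f"unknown model {name!r}; registered models: {', '.join(MODEL_NAMES)}"
        )
    p = _check_params(name, params)

    if name == "regulatory":
        B, al, a, b = p["B"], p["alpha"], p["a"], p["b"]
        return DynamicsModel(
            name, p,
            F=lambda x: -B * _as_pos(x) ** a,
            Fprime=lambda x: -B * a * _as_pos(x) ** (a - 1),
            H1=lambda x: al * np.ones_like(_as_pos(x)),
            H1prime=lambda x: np.zeros_like(_as_pos(x)),
            H2=lambda x: _as_pos(x) ** b / (1 + _as_pos(x) ** b),
            H2prime=lambda x: b * _as_pos(x) ** (b - 1) / (1 + _as_pos(x) ** b) ** 2,
            theta_closed_form=lambda q: (1 / q["a"] - 1, -q["b"] / q["a"]),
        )
    if name == "human":
        B, al, a, b, c = p["B"], p["alpha"], p["a"], p["b"], p["c"]
        y0 = p.setdefault("y0", 2.0)
        return DynamicsModel(
            name, p,
            F=lambda x: -B * _as_pos(x) ** (a + b),
            Fprime=lambda x: -B * (a + b) * _as_pos(x) ** (a + b - 1),
            H1=lambda x: al * _as_pos(x) ** b,
            H1prime=lambda x: al * b * _as_pos(x) ** (b - 1),
            H2=lambda x: y0 - _as_pos(x) ** (-c),
            H2prime=lambda x: c * _as_pos(x) ** (-c - 1),
            theta_closed_form=lambda q: ((1 - q["b"]) / q["a"] - 1, -q["c"] / q["a"]),
        )
    if name == "epidemics":
        B, al = p["B"], p["alpha"]
        return DynamicsModel(
            name, p,
            F=lambda x: -B * _as_pos(x),
            Fprime=lambda x: -B * np.ones_like(_as_pos(x)),
            H1=lambda x: al * (1 - _as_pos(x)),
            H1prime=lambda x: -al * np.ones_like(_as_pos(x)),
            H2=lambda x: _as_pos(x),
            H2prime=lambda x: np.ones_like(_as_pos(x)),
            domain=(0.0, 1.0),
            theta_closed_form=lambda q: (-1.0, -1.0),
        )
    if name == "mutualistic":
        B, al, a, C = p["B"], p["alpha"], p["a"], p["C"]
        return DynamicsModel(
            name, p,
            F=lambda x: B * _as_pos(x) * (1 - _as_pos(x) ** a / C),
            Fprime=lambda x: B * (1 - (a + 1) * _as_pos(x) ** a / C),
            H1=lambda x: al * _as_pos(x),
            H1prime=lambda x: al * np.ones_like(_as_pos(x)),
            H2=lambda x: _as_pos(x) / (1 + _as_pos(x)),
            H2prime=lambda x: 1 / (1 + _as_pos(x)) ** 2,
            theta_closed_form=lambda q: (-1.0, -1 / q["a"]),
        )
    if name == "population":
        B, al, a, b = p["B"], p["alpha"], p["a"], p["b"]
        return DynamicsModel(
            name, p,
            F=lambda x: -B * _as_pos(x) ** a,
            Fprime=lambda x: -B * a * _as_pos(x) ** (a - 1),
            H1=lambda x: al * np.ones_like(_as_pos(x)),
            H1prime=lambda x: np.zeros_like(_as_pos(x)),
            H2=lambda x: _as_pos(x) ** b,
            H2prime=lambda x: b * _as_pos(x) ** (b - 1),
            theta_closed_form=lambda q: (1 / q["a"] - 1, q["b"] / q["a"]),
        )
    if name == "biochemical":
        B, C, al = p["B"], p["C"], p["alpha"]
        return DynamicsModel(
            name, p,
            F=lambda x: B - C * _as_pos(x),
            Fprime=lambda x: -C * np.ones_like(_as_pos(x)),
            H1=lambda x: -al * _as_pos(x),
            H1prime=lambda x: -al * np.ones_like(_as_pos(x)),
            H2=lambda x: _as_pos(x),
            H2prime=lambda x: np.ones_like(_as_pos(x)),
            R_increasing=False,
            theta_closed_form=lambda q: (-1.0, -1.0),
        )
    # inhibitory: R(x) = (B/alpha)(1 - x/C)^2 is monotone only past x = C;
    # the large-degree branch x > C is the one the scaling theory lives on.
    B, C, al = p["B"], p["C"], p["alpha"]
    return DynamicsModel(
        "inhibitory", p,
        F=lambda x: -B * _as_pos(x) * (1 - _as_pos(x) / C) ** 2,
        Fprime=lambda x: -B * (1 - _as_pos(x) / C) ** 2
        + 2 * B * _as_pos(x) / C * (1 - _as_pos(x) / C),
        H1=lambda x: al * _as_pos(x),
        H1prime=lambda x: al * np.ones_like(_as_pos(x)),
        H2=lambda x: _as_pos(x),
        H2prime=lambda x: np.ones_like(_as_pos(x)),
        domain=(C, math.inf),
        theta_closed_form=lambda q: (-1.0, 0.5),
    )


# --- evaluation on a network ---------------------------------------------

def model_rhs(model: DynamicsModel, x: np.ndarray, A) -> np.ndarray:
    """Right-hand side F(x_i) + H1(x_i) * sum_j A_ij H2(x_j)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("state vector contains non-finite entries")
    n = A.shape[0]
    if x.shape != (n,):
        raise ValueError(f"state has shape {x.shape}, adjacency is {A.shape}")
    return model.F(x) + model.H1(x) * (A @ model.H2(x))


def model_jacobian(model: DynamicsModel, x: np.ndarray, A) -> sp.csr_matrix:
    """Sparse Jacobian of :func:`model_rhs` at state ``x``.

    Diagonal: F'(x_i) + H1'(x_i) * sum_j A_ij H2(x_j);
    off-diagonal (i, j): H1(x_i) H2'(x_j) A_ij.
    """
    x = np.asarray(x, dtype=float)
    A = sp.csr_matrix(A)
    diag = model.Fprime(x) + model.H1prime(x) * (A @ model.H2(x))
    off = sp.diags(model.H1(x)) @ A @ sp.diags(model.H2prime(x))
    return (sp.diags(diag) + off).tocsr()


def R_of_x(model: DynamicsModel, x: float) -> float:
    """R(x) = -F(x)/H1(x), the steady-state input-output relation."""
    h1 = float(model.H1(x))
    if h1 == 0.0:
        raise DomainError(f"{model.name}: H1({x}) = 0, R undefined")
    return -float(model.F(x)) / h1


def steady_state_meanfield(
    model: DynamicsModel,
    degree: float,
    ctx: MeanFieldContext | float = 1.0,
) -> float:
    """Invert R: the mean-field steady state x* with R(x*) = degree * Hbar.

    ``degree`` may be non-integer; the sweep that extracts scaling
    exponents treats degree as a continuous variable.
    """
    hbar = ctx.hbar if isinstance(ctx, MeanFieldContext) else float(ctx)
    if degree <= 0:
        raise NoSolutionError("degree must be positive")
    target = degree * hbar
    lo, hi = model.domain
    sign = 1.0 if model.R_increasing else -1.0

    def g(x: float) -> float:
        return sign * (R_of_x(model, x) - target)

    # geometric bracket expansion inside the monotone domain
    span = hi - lo
    finite_hi = math.isfinite(hi)
    x_lo = lo + (1e-12 * span if finite_hi else max(1e-12, lo * 1e-9 + 1e-12))
    x_hi = hi - 1e-12 * span if finite_hi else max(1.0, 2 * x_lo)
    if not finite_hi:
        for _ in range(2000):
            if g(x_hi) > 0:
                break
            x_hi *= 2.0
        else:
            raise NoSolutionError(
                f"{model.name}: target {target} above attainable R range"
            )
    if g(x_lo) > 0:
        if finite_hi:
            raise NoSolutionError(
                f"{model.name}: target {target} outside attainable R range "
                f"({R_of_x(model, x_hi):.3g}, {R_of_x(model, x_lo):.3g})"
            )
        for _ in range(2000):
            x_lo = lo + (x_lo - lo) / 2.0
            if g(x_lo) < 0:
                break
        else:
            raise NoSolutionError(
                f"{model.name}: target {target} below attainable R range"
            )
    if finite_hi and g(x_hi) < 0:
        raise NoSolutionError(
            f"{model.name}: target {target} outside attainable R range"
        )
    xstar = brentq(g, x_lo, x_hi, xtol=1e-300, rtol=4 * np.finfo(float).eps)
    # Newton polish; near a finite endpoint where R diverges the bracketed
    # root is representation-limited, and one derivative step recovers what
    # float spacing allows
    for _ in range(3):
        rp = _R_prime(model, xstar)
        if rp == 0 or not math.isfinite(rp):
            break
        step = (R_of_x(model, xstar) - target) / rp
        cand = xstar - step
        if not (lo < cand < hi):
            break
        xstar = cand
        if abs(step) <= np.spacing(abs(xstar)):
            break
    if target != 0:
        # achievable precision is conditioned by |R'| * ulp(x)
        attainable = abs(_R_prime(model, xstar)) * np.spacing(abs(xstar)) / abs(target)
        tol = max(1e-10, 8.0 * attainable)
        if abs(R_of_x(model, xstar) - target) / abs(target) > tol:
            raise NoSolutionError(
                f"{model.name}: R inversion did not meet tolerance at degree {degree}"
            )
    return float(xstar)


def _R_prime(model: DynamicsModel, x: float) -> float:
    """d/dx of R = -F/H1 from the analytic derivatives."""
    h1 = float(model.H1(x))
    return -(float(model.Fprime(x)) * h1 - float(model.F(x)) * float(model.H1prime(x))) / h1**2


def compute_Hbar(model: DynamicsModel, network, xstar: np.ndarray) -> float:
    """Mean adjacent interaction: (1/N) sum_i (1/d_i) sum_j A_ij H2(x_j*)."""
    import networkx as nx

    A = nx.to_scipy_sparse_array(network, nodelist=sorted(network.nodes()), format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise DomainError("network has isolated nodes; Hbar undefined")
    xstar = np.asarray(xstar, dtype=float)
    return float(np.mean((A @ model.H2(xstar)) / deg))


def self_time_J(model: DynamicsModel, xstar: float) -> float:
    """Intrinsic relaxation time J = -1 / (H1(x*) [F/H1]'(x*))."""
    x = float(xstar)
    h1 = float(model.H1(x))
    if h1 == 0.0:
        raise DomainError(f"{model.name}: H1({x}) = 0, J undefined")
    # (F/H1)' = (F' H1 - F H1') / H1^2
    d_fh1 = (float(model.Fprime(x)) * h1 - float(model.F(x)) * float(model.H1prime(x))) / h1**2
    denom = h1 * d_fh1
    if denom == 0.0:
        raise DegenerateEquilibriumError(
            f"{model.name}: (F/H1)'({x}) = 0, degenerate equilibrium"
        )
    return -1.0 / denom


def Q_factor(model: DynamicsModel, xstar: float) -> float:
    """Adjacent-feedback weight Q = J(x*) H1(x*) H2'(x*)."""
    x = float(xstar)
    return self_time_J(model, x) * float(model.H1(x)) * float(model.H2prime(x))


# --- leading-power extraction --------------------------------------------

def default_degree_grid(dmin: float = 1e2, dmax: float = 1e6, num: int = 40) -> np.ndarray:
    """Geometric degree grid used for asymptotic exponent extraction."""
    return np.geomspace(dmin, dmax, num)


def leading_exponent(
    fn: Callable[[float], float],
    dgrid: Sequence[float] | None = None,
    *,
    r2_flag: float = 0.99,
) -> ExponentEstimate:
    """Numerically extract the leading power p of fn(d) ~ d^p as d grows.

    Fits the log-log slope over the top decade of the grid — the numeric
    stand-in for the analytic large-degree expansion.  An estimate with
    R^2 below ``r2_flag`` is returned flagged as non-power-law.
    """
    d = np.asarray(dgrid if dgrid is not None else default_degree_grid(), dtype=float)
    vals = np.array([float(fn(di)) for di in d])
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise DomainError("fn must be positive and finite on the whole grid")
    top = d >= d.max() / 10.0
    fit = linregress(np.log(d[top]), np.log(vals[top]))
    r2 = float(fit.rvalue**2)
    return ExponentEstimate(
        exponent=float(fit.slope),
        r_squared=r2,
        fit_range=(float(d[top].min()), float(d.max())),
        n_points=int(top.sum()),
        flagged=r2 < r2_flag,
    )


@dataclass(frozen=True)
class ScalingExponents:
    """Numeric (theta_J, theta_Q) with diagnostics and registry metadata."""

    theta_J: float
    theta_Q: float
    estimate_J: ExponentEstimate
    estimate_Q: ExponentEstimate
    closed_form: tuple[float, float] | None

    def as_record(self, model: DynamicsModel) -> dict:
        return {
            "model": model.name,
            "params": dict(model.params),
            "theta_J": self.theta_J,
            "theta_Q": self.theta_Q,
            "r2_J": self.estimate_J.r_squared,
            "r2_Q": self.estimate_Q.r_squared,
            "grid": [*self.estimate_J.fit_range, self.estimate_J.n_points],
        }


def scaling_exponents(
    model: DynamicsModel,
    hbar: float = 1.0,
    dgrid: Sequence[float] | None = None,
) -> ScalingExponents:
    """Extract theta_J and theta_Q for a model by the mean-field degree sweep.

    theta_J is the leading power of d -> J(x*(d)); theta_Q is the leading
    power of d -> d * |Q(x*(d))| (equivalently the power of Q plus one).
    The magnitude is used because the biochemical coupling carries its sign
    in H1, making Q negative while its scaling is unaffected.
    """
    ctx = MeanFieldContext(hbar=hbar)

    def J_of_d(d: float) -> float:
        return self_time_J(model, steady_state_meanfield(model, d, ctx))

    def Q_of_d(d: float) -> float:
        return abs(Q_factor(model, steady_state_meanfield(model, d, ctx)))

    est_J = leading_exponent(J_of_d, dgrid)
    est_Q = leading_exponent(Q_of_d, dgrid)
    closed = model.theta_closed_form(model.params) if model.theta_closed_form else None
    return ScalingExponents(
        theta_J=est_J.exponent,
        theta_Q=est_Q.exponent + 1.0,
        estimate_J=est_J,
        estimate_Q=est_Q,
        closed_form=closed,
    )
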