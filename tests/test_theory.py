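"""Unit tests for the linear-response theory module."""

import math

import networkx as nx
import numpy as np
import pytest

import motifresponse as mr
from motifresponse.errors import RegimeValidityError
from motifresponse.networks import adjacency


# --- linearised system ----------------------------------------------------

def _fd_jacobian(model, G, xs, source):
    """Finite-difference Jacobian of the clamped rhs (independent oracle)."""
    A = adjacency(G)
    n = A.shape[0]
    free = [i for i in range(n) if i != source]

    def rhs_free(y):
        x = xs.copy()
        x[free] = y
        return mr.model_rhs(model, x, A)[free]

    y0 = xs[free]
    J = np.zeros((len(free), len(free)))
    f0 = rhs_free(y0)
    for k in range(len(free)):
        h = 1e-7 * max(abs(y0[k]), 1e-3)
        yp = y0.copy()
        yp[k] += h
        J[:, k] = (rhs_free(yp) - f0) / h
    return J


@pytest.mark.parametrize(
    "name,params",
    [
        ("population", {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 1.1}),
        ("regulatory", {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 2.0}),
        ("epidemics", {"B": 1.0, "alpha": 1.0}),
    ],
)
def test_linearized_matrix_matches_fd_jacobian(name, params):
    model = mr.make_model(name, params)
    rng = np.random.default_rng(17)
    for _ in range(4):
        G = nx.gnp_random_graph(8, 0.45, seed=int(rng.integers(1e6)))
        if not nx.is_connected(G):
            continue
        ss = mr.find_steady_state(model, G)
        M, forcing, free = mr.linearized_rhs(model, G, ss, source=0, delta_source=0.01)
        fd = _fd_jacobian(model, G, ss.x, source=0)
        np.testing.assert_allclose(M.toarray(), fd, rtol=2e-5, atol=1e-10)


def test_forcing_supported_on_source_neighbours(motif4, population_reference):
    G, m, i, h, j = motif4
    ss = mr.find_steady_state(population_reference, G)
    M, forcing, free = mr.linearized_rhs(population_reference, G, ss, m, 0.01)
    by_node = dict(zip(free, forcing))
    assert by_node[j] == 0.0  # not adjacent to the source
    assert by_node[i] != 0.0 and by_node[h] != 0.0


def test_linear_fixed_point_matches_scalar_solve():
    """Two-node epidemics pair: the linear system reduces to a scalar solve.

    At x* = 1/2 (B=1, alpha=2) the follower diagonal is -1/J = -2 and the
    source forcing is alpha (1 - x*) H2'(x_m*) dx_m = dx_m, so
    Dx(inf) = dx_m / 2 exactly."""
    model = mr.make_model("epidemics", {"B": 1.0, "alpha": 2.0})
    G = nx.path_graph(2)
    ss = mr.find_steady_state(model, G)
    dxm = 0.01 * ss.x[0]
    M, forcing, free = mr.linearized_rhs(model, G, ss, 0, dxm)
    dx_inf = np.linalg.solve(M.toarray(), -forcing)
    assert M.toarray()[0, 0] == pytest.approx(-2.0, rel=1e-9)
    assert dx_inf[0] == pytest.approx(dxm / 2.0, rel=1e-9)


def test_nonlinear_matches_linearised_trajectories(motif4, population_reference):
    """Small-perturbation nonlinear response tracks the linear system."""
    from scipy.linalg import expm

    G, m, i, h, j = motif4
    ss = mr.find_steady_state(population_reference, G)
    res = mr.perturb_and_track(population_reference, G, ss, m, epsilon=0.001)
    M, forcing, free = mr.linearized_rhs(population_reference, G, ss, m, res.delta_source)
    Minv_f = np.linalg.solve(M.toarray(), forcing)
    for t in np.linspace(0.1, res.times[-1] / 2, 8):
        # Dx(t) = (e^{Mt} - I) M^{-1} forcing
        lin = (expm(M.toarray() * t) - np.eye(3)) @ Minv_f
        for k, node in enumerate(free):
            nonlin = res.state_at(t)[node] - ss.x[node]
            denom = abs(res.delta_x_inf[node])
            assert abs(nonlin - lin[k]) / denom < 0.02


# --- adjacent-dynamics term ----------------------------------------------

def test_E_zero_when_target_has_only_the_source():
    model = mr.make_model("population", {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 1.1})
    G = nx.path_graph(2)
    ss = mr.find_steady_state(model, G)
    res = mr.perturb_and_track(model, G, ss, 0)
    series = mr.E_im_from_trajectories(res, model, G, ss, target=1)
    assert series.summary == pytest.approx(0.0, abs=1e-12)


def test_E_nonzero_on_motif_network(motif4_run, population_reference):
    """The four-node motif network violates the 'neighbours equilibrate
    instantly' premise: E_im is clearly non-zero at the target."""
    G, ss, res = motif4_run
    series = mr.E_im_from_trajectories(res, population_reference, G, ss, target=1)
    assert abs(series.summary) > 0.1


# --- closed forms ---------------------------------------------------------

def test_tau_local_reduces_to_pure_exponential():
    assert mr.tau_local(2.0, 0.5, 0.0) == pytest.approx(-2.0 * math.log(0.5))
    assert mr.tau_local(1.0, 0.5, 0.0) == pytest.approx(math.log(2))


def test_tau_local_with_adjacent_term():
    # 0.693147 / (1 - 1.442695 * 0.3)
    assert mr.tau_local(1.0, 0.5, 0.3) == pytest.approx(0.6931472 / 0.5671914, rel=1e-5)


def test_tau_local_regime_violation():
    with pytest.raises(RegimeValidityError):
        mr.tau_local(1.0, 0.5, 0.8)  # denominator goes non-positive


def test_tau_triangle_limits():
    assert mr.tau_triangle(1.0, 0.5, 7.0, 0.0) == pytest.approx(math.log(2))
    assert mr.tau_triangle(1.0, 0.5, 4.0, 1.0) == pytest.approx(5 * math.log(2))
    assert mr.tau_triangle(2.0, 0.3, 3.0, 0.5) == pytest.approx(
        -math.log(0.7) * 2.0 * 4.0 / 2.5
    )


def test_predicted_scaling_regimes():
    composite = mr.predicted_scaling(
        mr.make_model("population", {"B": 1, "alpha": 1, "a": 1.2, "b": 0.6}),
        "independent_edges",
    )
    assert composite.regime == "composite"
    assert composite.exponent == pytest.approx(-1 / 6 - 0.5, abs=0.02)

    reg = mr.predicted_scaling(
        mr.make_model("regulatory", {"B": 1, "alpha": 1, "a": 1.2, "b": 2.0}),
        "independent_edges",
    )
    assert reg.regime == "self_dynamics"
    assert reg.exponent == pytest.approx(1 / 1.2 - 1, abs=0.02)

    tri = mr.predicted_scaling(
        mr.make_model("regulatory", {"B": 1, "alpha": 1, "a": 10.0, "b": 2.0}),
        "triangles",
        f_regime="near_one",
    )
    assert tri.exponent == pytest.approx(0.1, abs=0.02)

    deg = mr.predicted_scaling(
        mr.make_model("regulatory", {"B": 1, "alpha": 1, "a": 0.8, "b": 0.5}),
        "independent_edges",
    )
    assert deg.regime in ("self_dynamics", "degree_limited")
    assert deg.exponent == pytest.approx(0.25, abs=0.02)


# --- synchrony constant f -------------------------------------------------

def test_estimate_f_self_consistency():
    eta, f_true = 0.5, 0.8
    samples = []
    for d in (5, 10, 20, 40, 80):
        J = d**-0.2
        C = 0.3 * d
        samples.append((d, mr.tau_triangle(J, eta, C, f_true), J, C))
    est = mr.estimate_f(samples, eta)
    assert est.f == pytest.approx(f_true, abs=1e-6)
    assert est.stable


def test_estimate_f_needs_enough_samples():
    with pytest.raises(RegimeValidityError):
        mr.estimate_f([(1, 1, 1, 1)] * 3, 0.5)


# --- global propagation ---------------------------------------------------

def test_build_g_examples():
    np.testing.assert_allclose(mr.build_g([0.0, 0.0, 0.0]), [1, 1, 1])
    np.testing.assert_allclose(mr.build_g([0.1, 0.5, 0.5]), [4, 2, 1])
    g = mr.build_g([0.1, 0.5, 0.5, 0.0])
    np.testing.assert_allclose(g[:3], [4, 2, 1])  # appended E=0 layer is neutral
    with pytest.raises(RegimeValidityError):
        mr.build_g([0.5, 1.0])


def test_build_g_monotone_property():
    rng = np.random.default_rng(3)
    for _ in range(20):
        E = rng.uniform(0, 0.9, size=6)
        g = mr.build_g(E)
        assert np.all(np.diff(g) <= 0) and np.all(g >= 1)


def test_build_D_examples():
    D = mr.build_D([3.0, 4.0, 5.0], 0.5, -1.0, 0.0, 0.0, 0.5)
    np.testing.assert_allclose(
        D, [math.log(2) * 3**0.5, 2.0, 5**0.5]
    )
    D0 = mr.build_D([2, 2, 2], 0.0, -1.0, 0.0, 0.0, 0.5)
    np.testing.assert_allclose(D0, [math.log(2), 1.0, 1.0])


def test_build_D_regression_fixture():
    # hand evaluation: d=2, theta_J=0.25, theta_Q=-0.625, C1=0.5, C2=0.1
    d_tq = 2**-0.625
    D = mr.build_D([2, 2, 2], 0.25, -0.625, 0.5, 0.1, 0.5)
    first = math.log(2) * 2**0.25 / (1 - 0.05 * d_tq)
    rest = 2**0.25 / (1 - 0.1 * d_tq)
    np.testing.assert_allclose(D, [first, rest, rest], rtol=1e-12)


def test_build_D_invalid_constants():
    with pytest.raises(RegimeValidityError):
        mr.build_D([100.0], 0.0, 0.5, 1.0, 1.0, 0.5)


def test_global_times_product_prefix_sums():
    D = np.array([1.0, 2.0, 3.0])
    E = np.zeros(3)
    np.testing.assert_allclose(mr.global_times_product(E, D), [1.0, 3.0, 6.0])
    with pytest.raises(ValueError):
        mr.global_times_product(np.zeros(2), D)


def test_global_times_product_degree_permutation_sensitivity():
    """With non-trivial g, permuting the degree sequence changes the
    prediction: degree fluctuations do not average out."""
    E = np.array([0.1, 0.5, 0.5])
    D1 = mr.build_D([2, 8, 2], 0.25, 0.1, 0.0, 0.0, 0.5)
    D2 = mr.build_D([2, 2, 8], 0.25, 0.1, 0.0, 0.0, 0.5)
    p1 = mr.global_times_product(E, D1)[-1]
    p2 = mr.global_times_product(E, D2)[-1]
    assert p1 != pytest.approx(p2, rel=1e-6)


def test_recursion_on_exponential_response():
    """Exactly exponential follower: the Newton recursion lands on the
    closed-form crossing -ln(1-eta)/rate."""
    model = mr.make_model("epidemics", {"B": 1.0, "alpha": 2.0})
    G = nx.path_graph(2)
    ss = mr.find_steady_state(model, G)
    eps = 0.01
    res = mr.perturb_and_track(model, G, ss, 0, epsilon=eps)
    pred = mr.global_times_recursive(res, model, G, [0, 1])
    rate = 1.0 + 2 * 0.5 * (1 + eps)
    assert pred.T[1] == pytest.approx(math.log(2) / rate, rel=1e-4)
    assert pred.T[1] == pytest.approx(pred.T_direct[1], rel=1e-4)


def test_recursion_monotone_along_chain():
    model = mr.make_model("regulatory", {"B": 0.01, "alpha": 0.01, "a": 0.8, "b": 0.5})
    pred, res, G, path = mr.chain_response(model, [2, 3, 2, 4, 2, 3, 2, 2])
    assert np.all(np.diff(pred.T) >= 0)
    # recursion agrees with the direct crossings
    rel = np.abs(pred.T[1:] - pred.T_direct[1:]) / pred.T_direct[1:]
    assert np.max(rel) < 0.05


def test_calibrate_constants_recovers_reference():
    degrees = [3.0, 5.0, 2.0, 7.0]
    theta_J, theta_Q, eta = 0.25, -0.4, 0.5
    D_true = mr.build_D(degrees, theta_J, theta_Q, 0.4, 0.2, eta)
    T_ref = mr.global_times_product(np.zeros(4), D_true)
    c1, c2, scale = mr.calibrate_constants(degrees, T_ref, theta_J, theta_Q, eta)
    D_fit = mr.build_D(degrees, theta_J, theta_Q, c1, c2, eta)
    pred = mr.global_times_product(np.zeros(4), D_fit)
    pred = pred / pred[0] * T_ref[0]
    np.testing.assert_allclose(pred, T_ref, rtol=0.02)
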