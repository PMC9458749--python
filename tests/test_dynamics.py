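"""Unit tests for the dynamics models and the exponent machinery."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import motifresponse as mr
from motifresponse.dynamics import DynamicsModel, default_degree_grid
from motifresponse.errors import (
    DomainError,
    ModelRegistryError,
    NoSolutionError,
    ParameterError,
)

ALL_PARAMS = {
    "regulatory": {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 2.0},
    "human": {"B": 1.0, "alpha": 1.0, "a": 1.1, "b": 0.4, "c": 0.7, "y0": 2.0},
    "epidemics": {"B": 1.0, "alpha": 1.0},
    "mutualistic": {"B": 1.0, "alpha": 1.0, "a": 1.3, "C": 2.0},
    "population": {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 1.1},
    "biochemical": {"B": 1.0, "C": 1.0, "alpha": 1.0},
    "inhibitory": {"B": 1.0, "C": 1.0, "alpha": 1.0},
}


def test_registry_covers_all_models():
    for name, params in ALL_PARAMS.items():
        model = mr.make_model(name, params)
        assert model.name == name


def test_unknown_model_rejected():
    with pytest.raises(ModelRegistryError):
        mr.make_model("predator_prey", {"B": 1})


def test_missing_and_negative_parameters_rejected():
    with pytest.raises(ParameterError, match="alpha"):
        mr.make_model("population", {"B": 1, "a": 1, "b": 1})
    with pytest.raises(ParameterError, match="'a'"):
        mr.make_model("population", {"B": 1, "alpha": 1, "a": -1, "b": 1})


def test_epidemics_triplet_values():
    model = mr.make_model("epidemics", {"B": 1, "alpha": 1})
    assert model.F(0.5) == pytest.approx(-0.5)
    assert model.H1(0.5) == pytest.approx(0.5)
    assert model.H2(0.5) == pytest.approx(0.5)


def test_population_rhs_matches_equation():
    """rhs reproduces -B x^a + alpha sum_j A_ij x_j^b on a random graph."""
    model = mr.make_model("population", ALL_PARAMS["population"])
    G = nx.gnp_random_graph(8, 0.4, seed=3)
    from motifresponse.networks import adjacency

    A = adjacency(G)
    x = np.random.default_rng(0).uniform(0.5, 2.0, 8)
    got = mr.model_rhs(model, x, A)
    B, al, a, b = 0.01, 0.01, 1.2, 1.1
    want = -B * x**a + al * (A @ x**b)
    np.testing.assert_allclose(got, want, rtol=1e-12)


def test_rhs_trivial_cases():
    import scipy.sparse as sp

    pop = mr.make_model("population", {"B": 2, "alpha": 1, "a": 1.5, "b": 1})
    A0 = sp.csr_matrix((1, 1))
    x = np.array([1.7])
    np.testing.assert_allclose(mr.model_rhs(pop, x, A0), -2 * 1.7**1.5)

    epi = mr.make_model("epidemics", {"B": 1, "alpha": 1})
    A2 = sp.csr_matrix(np.array([[0, 1], [1, 0]], dtype=float))
    np.testing.assert_allclose(mr.model_rhs(epi, np.zeros(2), A2), 0.0)


def test_biochemical_rhs_on_triangle():
    """B - Cx - alpha x sum_j x_j at x=(1,1,1) on K3 gives -2 per node."""
    model = mr.make_model("biochemical", {"B": 1, "C": 1, "alpha": 1})
    from motifresponse.networks import adjacency

    A = adjacency(nx.complete_graph(3))
    got = mr.model_rhs(model, np.ones(3), A)
    np.testing.assert_allclose(got, [-2.0, -2.0, -2.0])


def test_R_of_x_and_domain_error():
    pop = mr.make_model("population", {"B": 1, "alpha": 1, "a": 2, "b": 1})
    assert mr.R_of_x(pop, 3.0) == pytest.approx(9.0)
    epi = mr.make_model("epidemics", {"B": 1, "alpha": 1})
    assert mr.R_of_x(epi, 0.5) == pytest.approx(1.0)
    with pytest.raises(DomainError):
        mr.R_of_x(epi, 1.0)


def test_steady_state_meanfield_inverts_R():
    pop = mr.make_model("population", {"B": 1, "alpha": 1, "a": 2, "b": 1})
    assert mr.steady_state_meanfield(pop, 9.0, 1.0) == pytest.approx(3.0, rel=1e-10)
    epi = mr.make_model("epidemics", {"B": 1, "alpha": 1})
    for d in (0.5, 1.0, 7.0, 300.0):
        assert mr.steady_state_meanfield(epi, d, 1.0) == pytest.approx(d / (1 + d), rel=1e-9)


def test_meanfield_depends_only_on_product():
    m = mr.make_model("regulatory", ALL_PARAMS["regulatory"])
    a = mr.steady_state_meanfield(m, 12.0, 0.5)
    b = mr.steady_state_meanfield(m, 6.0, 1.0)
    assert a == pytest.approx(b, rel=1e-12)


def test_meanfield_rejects_nonpositive_degree():
    m = mr.make_model("population", ALL_PARAMS["population"])
    with pytest.raises(NoSolutionError):
        mr.steady_state_meanfield(m, -1.0, 1.0)


@settings(max_examples=30, deadline=None)
@given(
    d=st.floats(min_value=0.5, max_value=1e5),
    hbar=st.floats(min_value=0.1, max_value=10.0),
)
def test_meanfield_R_roundtrip_property(d, hbar):
    """R(x*(d)) returns d * Hbar to relative error 1e-10, across models."""
    for name in ("population", "regulatory", "inhibitory", "biochemical"):
        m = mr.make_model(name, ALL_PARAMS[name])
        x = mr.steady_state_meanfield(m, d, hbar)
        assert mr.R_of_x(m, x) == pytest.approx(d * hbar, rel=1e-10)


def test_compute_Hbar_examples():
    epi = mr.make_model("epidemics", {"B": 1, "alpha": 1})
    # two-node path with states (0.2, 0.6): Hbar = (0.6 + 0.2)/2
    G2 = nx.path_graph(2)
    assert mr.compute_Hbar(epi, G2, np.array([0.2, 0.6])) == pytest.approx(0.4)
    # star with H2 = identity, centre 1 and leaves 0
    G = nx.star_graph(3)
    x = np.array([1.0, 0.0, 0.0, 0.0])
    assert mr.compute_Hbar(epi, G, x) == pytest.approx(0.75)
    # k-regular with uniform state: Hbar = H2(c)
    G4 = nx.cycle_graph(6)
    assert mr.compute_Hbar(epi, G4, np.full(6, 0.3)) == pytest.approx(0.3)


def test_compute_Hbar_rejects_isolated_nodes():
    G = nx.Graph()
    G.add_nodes_from([0, 1])
    G.add_edge(0, 1)
    G.add_node(2)
    epi = mr.make_model("epidemics", {"B": 1, "alpha": 1})
    with pytest.raises(DomainError):
        mr.compute_Hbar(epi, G, np.array([0.1, 0.1, 0.1]))


def test_self_time_J_closed_forms():
    pop1 = mr.make_model("population", {"B": 1, "alpha": 3, "a": 1, "b": 1})
    for x in (0.5, 2.0, 7.0):
        assert mr.self_time_J(pop1, x) == pytest.approx(1.0)
    epi = mr.make_model("epidemics", {"B": 1, "alpha": 1})
    assert mr.self_time_J(epi, 0.25) == pytest.approx(0.75)
    pop2 = mr.make_model("population", {"B": 1, "alpha": 1, "a": 2, "b": 1})
    assert mr.self_time_J(pop2, 3.0) == pytest.approx(1 / 6)


@pytest.mark.parametrize("name", sorted(ALL_PARAMS))
def test_J_matches_finite_difference(name):
    """Analytic J agrees with a central-difference evaluation of (F/H1)'."""
    model = mr.make_model(name, ALL_PARAMS[name])
    xs = [1.3, 2.4] if name != "epidemics" else [0.3, 0.7]
    for x in xs:
        h = 1e-6 * x

        def fh1(z):
            return float(model.F(z)) / float(model.H1(z))

        d = (fh1(x + h) - fh1(x - h)) / (2 * h)
        want = -1.0 / (float(model.H1(x)) * d)
        assert mr.self_time_J(model, x) == pytest.approx(want, rel=1e-6)


@pytest.mark.parametrize("name", sorted(ALL_PARAMS))
def test_H2prime_matches_finite_difference(name):
    model = mr.make_model(name, ALL_PARAMS[name])
    grid = np.linspace(0.2, 3.0, 9) if name != "epidemics" else np.linspace(0.05, 0.9, 9)
    h = 1e-6
    fd = (model.H2(grid + h) - model.H2(grid - h)) / (2 * h)
    np.testing.assert_allclose(model.H2prime(grid), fd, rtol=1e-6)


def test_Q_factor_closed_forms():
    pop = mr.make_model("population", {"B": 1, "alpha": 1, "a": 1, "b": 1})
    for x in (0.5, 1.0, 4.0):
        assert mr.Q_factor(pop, x) == pytest.approx(1.0)
    pop2 = mr.make_model("population", {"B": 0.01, "alpha": 0.01, "a": 1.2, "b": 0.6})
    for x in (0.7, 2.0):
        assert mr.Q_factor(pop2, x) == pytest.approx((0.6 / 1.2) * x ** (0.6 - 1.2))


def test_Q_factor_zero_for_constant_H2():
    base = mr.make_model("population", {"B": 1, "alpha": 1, "a": 1.5, "b": 1})
    import dataclasses

    flat = dataclasses.replace(
        base,
        H2=lambda x: np.ones_like(np.asarray(x, float)),
        H2prime=lambda x: np.zeros_like(np.asarray(x, float)),
    )
    assert mr.Q_factor(flat, 2.0) == 0.0


def test_triplet_split_invariance():
    """J and Q do not depend on how constants are split across the triplet."""
    import dataclasses

    B, al, a, b = 0.01, 0.01, 1.2, 0.6
    standard = mr.make_model("population", {"B": B, "alpha": al, "a": a, "b": b})
    # alternative split: H1 = 1, H2 = alpha x^b
    alt = dataclasses.replace(
        standard,
        H1=lambda x: np.ones_like(np.asarray(x, float)),
        H1prime=lambda x: np.zeros_like(np.asarray(x, float)),
        H2=lambda x: al * np.asarray(x, float) ** b,
        H2prime=lambda x: al * b * np.asarray(x, float) ** (b - 1),
    )
    for x in (0.5, 1.7, 9.0):
        assert mr.self_time_J(standard, x) == pytest.approx(mr.self_time_J(alt, x), rel=1e-12)
        assert mr.Q_factor(standard, x) == pytest.approx(mr.Q_factor(alt, x), rel=1e-12)


def test_leading_exponent_exact_power_law():
    est = mr.leading_exponent(lambda d: d**0.25)
    assert est.exponent == pytest.approx(0.25, abs=1e-12)
    assert est.r_squared == pytest.approx(1.0)
    est2 = mr.leading_exponent(lambda d: 7.3 * d**0.25)
    assert est2.exponent == pytest.approx(0.25, abs=1e-12)  # invariant to prefactor


def test_leading_exponent_flags_non_power_law():
    est = mr.leading_exponent(lambda d: math.exp(d / 1e5), default_degree_grid(1e2, 1e6, 30))
    assert est.flagged


def test_leading_exponent_rejects_nonpositive():
    with pytest.raises(DomainError):
        mr.leading_exponent(lambda d: d - 1e4)


def test_scaling_exponents_quick_registry_check():
    """Numeric extractor reproduces the closed forms (small spot check)."""
    cases = {
        "population": {"B": 1, "alpha": 1, "a": 1.2, "b": 0.6},
        "regulatory": {"B": 0.01, "alpha": 0.01, "a": 0.8, "b": 0.5},
        "epidemics": {"B": 1, "alpha": 1},
        "inhibitory": {"B": 1, "C": 1, "alpha": 1},
    }
    for name, params in cases.items():
        model = mr.make_model(name, params)
        est = mr.scaling_exponents(model)
        tj, tq = est.closed_form
        assert est.theta_J == pytest.approx(tj, abs=0.02)
        assert est.theta_Q == pytest.approx(tq, abs=0.02)


def test_population_a1_b1_exponents():
    est = mr.scaling_exponents(mr.make_model("population", {"B": 1, "alpha": 1, "a": 1, "b": 1}))
    assert est.theta_J == pytest.approx(0.0, abs=1e-8)
    assert est.theta_Q == pytest.approx(1.0, abs=1e-8)
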