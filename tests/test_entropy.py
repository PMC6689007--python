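"""Entropy-rate core against closed-form and brute-force oracles.

The dense oracle below recomputes every quantity from first principles
(explicit transition matrix, left Perron eigenvector, elementwise
entropy sum) independently of the sparse implementation paths.
"""

import numpy as np
import pandas as pd
import pytest

from scpotency.entropy import (
    dominant_eigenpair,
    entropy_rate,
    max_entropy_rate,
    normalized_sr,
    sr_profile,
    stationary_distribution,
    transition_matrix,
)
from scpotency.network import GeneNetwork, network_from_edges
from scpotency.simulate import simulate_network

from conftest import random_positive_expression


# ---------------------------------------------------------------- oracles

def dense_transition(x, net):
    A = net.adjacency.toarray()
    z = A @ x
    return A * x[None, :] / z[:, None]


def dense_entropy_rate(x, net):
    """Brute force: stationary measure as the left Perron eigenvector of
    the dense transition matrix, then the full entropy-rate sum."""
    P = dense_transition(x, net)
    w, V = np.linalg.eig(P.T)
    i = np.argmax(w.real)
    pi = np.abs(V[:, i].real)
    pi = pi / pi.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return -float(pi @ terms.sum(axis=1)), pi


# ------------------------------------------------------- worked examples

def test_dominant_eigenpair_path3(path3):
    lam, v = dominant_eigenpair(path3)
    assert lam == pytest.approx(np.sqrt(2), abs=1e-12)
    assert np.all(v > 0)
    assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)


def test_dominant_eigenpair_path4(path4):
    lam, _ = dominant_eigenpair(path4)
    assert lam == pytest.approx(2 * np.cos(np.pi / 5), abs=1e-12)


def test_dominant_eigenpair_triangle(triangle):
    lam, v = dominant_eigenpair(triangle)
    assert lam == pytest.approx(2.0, abs=1e-12)
    assert np.allclose(v, np.ones(3) / np.sqrt(3), atol=1e-10)


def test_dominant_eigenpair_rejects_disconnected():
    net = network_from_edges([("a", "b"), ("c", "d")])
    with pytest.raises(ValueError, match="largest connected component"):
        dominant_eigenpair(net)


@pytest.mark.parametrize(
    "fixture_name, expected",
    [
        ("triangle", np.log(2.0)),
        ("path3", np.log(np.sqrt(2.0))),
        ("star3", np.log(np.sqrt(3.0))),
    ],
)
def test_max_entropy_rate_worked_values(request, fixture_name, expected):
    net = request.getfixturevalue(fixture_name)
    max_sr, P = max_entropy_rate(net)
    assert max_sr == pytest.approx(expected, abs=1e-12)
    # entropy rate of the maximal-entropy walk under pi ~ v^2 equals maxSr
    _, v = dominant_eigenpair(net)
    pi = v**2 / np.sum(v**2)
    Pd = P.toarray()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(Pd > 0, Pd * np.log(Pd), 0.0)
    assert -float(pi @ terms.sum(axis=1)) == pytest.approx(max_sr, abs=1e-10)
    assert np.allclose(np.asarray(P.sum(axis=1)).ravel(), 1.0, atol=1e-12)


def test_transition_matrix_path3_hand_values(path3):
    P = transition_matrix(np.array([1.0, 1.0, 2.0]), path3).toarray()
    expected = np.array([[0, 1, 0], [1 / 3, 0, 2 / 3], [0, 1, 0]])
    assert np.allclose(P, expected, atol=1e-12)


def test_transition_matrix_uniform_is_degree_walk(small_random_net):
    net = small_random_net
    P = transition_matrix(np.ones(net.n_nodes), net).toarray()
    deg = net.degrees()
    assert np.allclose(P, net.adjacency.toarray() / deg[:, None], atol=1e-12)


def test_transition_matrix_scale_invariant(small_random_net):
    x = random_positive_expression(small_random_net, 0)
    P1 = transition_matrix(x, small_random_net)
    P2 = transition_matrix(10.0 * x, small_random_net)
    assert abs(P1 - P2).max() < 1e-12


def test_transition_matrix_rejects_bad_input(path3):
    with pytest.raises(ValueError, match="positive"):
        transition_matrix(np.array([1.0, 0.0, 1.0]), path3)
    with pytest.raises(ValueError, match="length"):
        transition_matrix(np.ones(5), path3)


def test_stationary_distribution_path3_weighted(path3):
    pi = stationary_distribution(np.array([1.0, 1.0, 2.0]), path3)
    assert np.allclose(pi, [1 / 6, 1 / 2, 1 / 3], atol=1e-12)


def test_stationary_distribution_path3_uniform(path3):
    pi = stationary_distribution(np.ones(3), path3)
    assert np.allclose(pi, [0.25, 0.5, 0.25], atol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_stationarity_and_detailed_balance(small_random_net, seed):
    net = small_random_net
    x = random_positive_expression(net, seed)
    P = transition_matrix(x, net)
    pi = stationary_distribution(x, net)
    assert pi.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.max(np.abs(pi @ P.toarray() - pi)) < 1e-10
    flux = P.toarray() * pi[:, None]
    assert np.max(np.abs(flux - flux.T)) < 1e-12


def test_entropy_rate_worked_values(path3, star3):
    assert entropy_rate(np.ones(3), path3) == pytest.approx(0.5 * np.log(2), abs=1e-12)
    x = np.array([1.0, 1.0, 2.0])
    h = -(np.log(1 / 3) / 3 + 2 * np.log(2 / 3) / 3)
    assert entropy_rate(x, path3) == pytest.approx(0.5 * h, abs=1e-12)
    assert entropy_rate(x, path3) == pytest.approx(0.318257, abs=1e-6)
    # star: hub entropy ln3, hub stationary mass 1/2
    assert entropy_rate(np.ones(4), star3) == pytest.approx(0.5 * np.log(3), abs=1e-12)


def test_normalized_sr_worked_values(path3, path4):
    max3, _ = max_entropy_rate(path3)
    assert normalized_sr(np.ones(3), path3, max3) == pytest.approx(1.0, abs=1e-12)
    assert normalized_sr(np.array([1.0, 1.0, 2.0]), path3, max3) == pytest.approx(
        0.91830, abs=1e-5
    )
    max4, _ = max_entropy_rate(path4)
    assert normalized_sr(np.ones(4), path4, max4) == pytest.approx(0.96028, abs=1e-5)


# ----------------------------------------------------------- properties

@pytest.mark.parametrize("seed", range(5))
def test_sparse_matches_dense_oracle(seed):
    net = simulate_network(n_genes=50, density=0.12, seed=seed + 100)
    x = random_positive_expression(net, seed)
    sr_sparse = entropy_rate(x, net)
    sr_dense, pi_dense = dense_entropy_rate(x, net)
    assert sr_sparse == pytest.approx(sr_dense, abs=1e-10)
    assert np.allclose(stationary_distribution(x, net), pi_dense, atol=1e-10)


def test_row_stochastic_on_random_fixtures():
    for seed in range(3):
        net = simulate_network(n_genes=60, density=0.1, seed=seed + 50)
        x = random_positive_expression(net, seed)
        rows = np.asarray(transition_matrix(x, net).sum(axis=1)).ravel()
        assert np.allclose(rows, 1.0, atol=1e-12)


def test_sr_equals_one_on_regular_graph_with_uniform_x():
    # cycle graphs are 2-regular
    edges = [(f"n{i}", f"n{(i + 1) % 8}") for i in range(8)]
    net = network_from_edges(edges)
    max_sr, _ = max_entropy_rate(net)
    assert normalized_sr(np.ones(8), net, max_sr) == pytest.approx(1.0, abs=1e-12)


def test_sr_bounds_on_random_inputs(small_random_net):
    max_sr, _ = max_entropy_rate(small_random_net)
    for seed in range(5):
        x = random_positive_expression(small_random_net, seed)
        srn = normalized_sr(x, small_random_net, max_sr)
        assert 0 < srn <= 1 + 1e-12


# ------------------------------------------------------------ sr_profile

def make_expr_frame(net, cells):
    return pd.DataFrame(
        np.column_stack(cells), index=net.gene_ids,
        columns=[f"c{i}" for i in range(len(cells))],
    )


def test_sr_profile_identical_cells_and_scale_invariance(small_random_net):
    net = small_random_net
    x = random_positive_expression(net, 3)
    expr = make_expr_frame(net, [x, x, 10 * x])
    prof = sr_profile(expr, net, align=False)
    assert prof.sr[0] == prof.sr[1]
    assert prof.sr[2] == pytest.approx(prof.sr[0], abs=1e-12)
    assert prof.max_sr == pytest.approx(np.log(dominant_eigenpair(net)[0]), abs=1e-12)


def test_sr_profile_order_independent(small_random_net):
    net = small_random_net
    cells = [random_positive_expression(net, s) for s in range(6)]
    prof = sr_profile(make_expr_frame(net, cells), net, align=False)
    rev = sr_profile(make_expr_frame(net, cells[::-1]), net, align=False)
    assert np.allclose(prof.sr, rev.sr[::-1], atol=0)


def test_sr_profile_aligns_to_network_genes(small_random_net):
    net = small_random_net
    x = random_positive_expression(net, 4)
    expr = make_expr_frame(net, [x])
    extra = pd.DataFrame(
        np.ones((2, 1)), index=["zzz1", "zzz2"], columns=expr.columns
    )
    prof = sr_profile(pd.concat([expr, extra]), net)
    ref = sr_profile(expr, net, align=False)
    assert prof.sr[0] == pytest.approx(ref.sr[0], abs=1e-12)
    assert prof.n_genes_used == net.n_nodes


def test_sr_profile_rejects_nonpositive_naming_cell_and_gene(small_random_net):
    net = small_random_net
    x = random_positive_expression(net, 5)
    expr = make_expr_frame(net, [x, x])
    expr.iloc[7, 1] = 0.0
    with pytest.raises(ValueError, match=str(expr.index[7])):
        sr_profile(expr, net, align=False)


def test_sr_profile_recovers_planted_potency_gradient():
    from scipy.stats import spearmanr
    from scpotency.simulate import simulate_potency_population

    net = simulate_network(n_genes=100, seed=1)
    bundle = simulate_potency_population(net, n_cells=200, seed=1)
    prof = sr_profile(bundle.expression, net, align=False)
    rho = spearmanr(prof.srn, bundle.ground_truth["t"]).statistic
    assert rho > 0.8
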