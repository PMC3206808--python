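"""Projection, stationary distribution, damping ratio, posterior summaries."""

import numpy as np
import pytest

from reefmarkov import (
    cover_from_distribution,
    damping_ratio,
    project_distribution,
    stationary_distribution,
    summarize_derived,
)
from reefmarkov.estimation import DirichletPosterior
from reefmarkov.surveys import CoverSummary

P2 = np.array([[0.9, 0.2], [0.1, 0.8]])


def test_projection_fixed_point():
    seq = project_distribution(np.eye(3), [0.2, 0.3, 0.5], 10)
    assert seq.shape == (11, 3)
    assert np.allclose(seq, seq[0])


def test_projection_step():
    seq = project_distribution(P2, [1.0, 0.0], 1)
    assert np.allclose(seq[1], [0.9, 0.1])


def test_projection_conserves_probability(caribbean_fit):
    seq = project_distribution(caribbean_fit.params, np.full(6, 1 / 6), 50)
    assert np.allclose(seq.sum(axis=1), 1.0, atol=1e-12)


def test_projection_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension|length"):
        project_distribution(P2, [0.5, 0.3, 0.2], 2)


def test_stationary_two_state():
    assert np.allclose(stationary_distribution(P2), [2 / 3, 1 / 3])
    sym = np.full((2, 2), 0.5)
    assert np.allclose(stationary_distribution(sym), [0.5, 0.5])


def test_stationary_power_iteration_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        P = rng.dirichlet(np.ones(6), size=6).T  # random positive columns
        pi = stationary_distribution(P)
        brute = np.linalg.matrix_power(P, 1000) @ np.full(6, 1 / 6)
        assert np.max(np.abs(pi - brute)) < 1e-8
        assert np.max(np.abs(P @ pi - pi)) < 1e-10


def test_stationary_reducible_rejected():
    with pytest.raises(ValueError, match="reducible|simple"):
        stationary_distribution(np.eye(4))


def test_damping_two_state():
    # 2x2 eigenvalues are 1 and trace - 1 = 0.7
    assert damping_ratio(P2) == pytest.approx(1 / 0.7)


def test_damping_rank_one_infinite():
    assert damping_ratio(np.full((6, 6), 1 / 6)) == np.inf


def test_damping_at_least_one():
    rng = np.random.default_rng(9)
    for _ in range(50):
        P = rng.dirichlet(np.ones(4), size=4).T
        assert damping_ratio(P) >= 1.0
    with pytest.raises(ValueError):
        damping_ratio(np.ones((1, 1)))


def test_cover_from_distribution(scheme):
    covers = CoverSummary(
        [10, 20, 30, 40, 50, 60], [5, 10, 15, 20, 25, 30], np.ones(6), scheme
    )
    qc, qa = cover_from_distribution(np.array([0.5, 0.5, 0, 0, 0, 0]), covers)
    assert qc == 15.0 and qa == 7.5
    qc, _ = cover_from_distribution(np.eye(6)[3], covers)
    assert qc == 40.0


def test_projection_converges_to_stationary(caribbean_fit):
    pi = stationary_distribution(caribbean_fit.params)
    seq = project_distribution(caribbean_fit.params, np.eye(6)[0], 200)
    assert np.max(np.abs(seq[-1] - pi)) < 1e-6
    # distance decreases beyond small t
    d = np.max(np.abs(seq - pi), axis=1)
    assert np.all(np.diff(d[5:]) <= 1e-15)


def test_equilibrium_cover_consistency(caribbean_fit):
    covers = caribbean_fit.covers
    pi = stationary_distribution(caribbean_fit.params)
    qc_eq, qa_eq = cover_from_distribution(pi, covers)
    seq = project_distribution(caribbean_fit.params, np.full(6, 1 / 6), 500)
    qc_t, qa_t = cover_from_distribution(seq[-1], covers)
    assert qc_t == pytest.approx(qc_eq, abs=1e-8)
    assert qa_t == pytest.approx(qa_eq, abs=1e-8)


def test_summarize_constant_statistic(caribbean_fit):
    s = summarize_derived(
        lambda P, p0: 7.0,
        caribbean_fit.posterior,
        n_rep=100,
        rng=np.random.default_rng(0),
    )
    assert s.mean == 7.0
    assert s.ci50 == (7.0, 7.0) and s.ci95 == (7.0, 7.0)


def test_summarize_initial_draw_marginal(caribbean_fit):
    """First entry of a uniform Dirichlet(1,...,1) draw has mean 1/6."""
    s = summarize_derived(
        lambda P, p0: p0[0],
        caribbean_fit.posterior,
        init_alpha=np.ones(6),
        n_rep=10000,
        rng=np.random.default_rng(1),
    )
    assert s.mean == pytest.approx(1 / 6, abs=0.01)
    assert s.ci95[0] <= s.ci50[0] <= s.ci50[1] <= s.ci95[1]


def test_summarize_nonfinite_policy(caribbean_fit):
    with pytest.raises(ValueError, match="non-finite"):
        summarize_derived(
            lambda P, p0: np.inf,
            caribbean_fit.posterior,
            n_rep=50,
            rng=np.random.default_rng(2),
        )


def test_monte_carlo_stability(caribbean_fit):
    """Damping-ratio posterior means agree across seeds within 3 MC errors."""
    s1 = caribbean_fit.damping_ratio_posterior(n_rep=10000, seed=101)
    s2 = caribbean_fit.damping_ratio_posterior(n_rep=10000, seed=202)
    # MC standard error from the sample spread (95% CI spans ~4 sd)
    sd = (s1.ci95[1] - s1.ci95[0]) / 4
    assert abs(s1.mean - s2.mean) < 3 * sd / np.sqrt(10000) * np.sqrt(2)
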