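"""Baseline-category logit scenario engine."""

import numpy as np
import pytest

from reefmarkov import (
    StateScheme,
    build_beta_matrix,
    scenario_curve,
    scenario_matrix,
)
from reefmarkov.surveys import CoverSummary


@pytest.fixture(scope="module")
def beta(scheme=None):
    return build_beta_matrix(StateScheme())


def test_beta_signs(beta):
    # A -> B (source col 0, dest row 1): coral overlap, algae up => -1
    assert beta[1, 0] == -1
    # D -> F (source col 3, dest row 5): coral up, algae overlap => +1
    assert beta[5, 3] == 1
    # F -> A: coral down, algae overlap => -1
    assert beta[0, 5] == -1
    # A -> D: coral up (dest (25,50] dominates [0,25]), algae overlap => +1
    assert beta[3, 0] == 1
    # B -> A: coral overlap, algae down => +1
    assert beta[0, 1] == 1
    assert np.all(np.diag(beta) == 0)
    assert set(np.unique(beta)) <= {-1.0, 0.0, 1.0}


def test_beta_magnitude_and_midpoint_rule():
    assert np.array_equal(build_beta_matrix(magnitude=2.5), 2.5 * build_beta_matrix())
    mid = build_beta_matrix(comparison="midpoint")
    # A -> C: coral intervals [0,25] vs [0,50] overlap (dominance: no coral
    # signal) but midpoints 12.5 vs 25 differ, so the rules disagree here
    dom = build_beta_matrix(comparison="dominance")
    assert not np.array_equal(mid, dom)
    assert np.all(np.diag(mid) == 0)
    with pytest.raises(ValueError):
        build_beta_matrix(comparison="nope")


def test_scenario_identity_at_origin(caribbean_fit, beta):
    P0 = caribbean_fit.params
    assert np.max(np.abs(scenario_matrix(P0, beta, 0.0) - P0)) < 1e-12


def test_scenario_two_state_toy():
    P0 = np.array([[0.8, 0.5], [0.2, 0.5]])
    b = np.array([[0.0, 0.0], [-1.0, 0.0]])
    P1 = scenario_matrix(P0, b, 1.0)
    expect = 0.25 * np.exp(-1) / (1 + 0.25 * np.exp(-1))
    assert P1[1, 0] == pytest.approx(expect)
    assert np.allclose(P1.sum(axis=0), 1.0, atol=1e-12)


def test_scenario_requires_positive_matrix(beta):
    P0 = np.eye(6)
    with pytest.raises(ValueError, match="positive"):
        scenario_matrix(P0, beta, 1.0)


def test_scenario_composability(caribbean_fit, beta):
    """Log-linearity: transforming by x then y equals transforming by x + y."""
    P0 = caribbean_fit.params
    for x, y in [(0.5, 0.7), (-1.0, 0.4), (2.0, -2.0)]:
        once = scenario_matrix(P0, beta, x + y)
        twice = scenario_matrix(scenario_matrix(P0, beta, x), beta, y)
        assert np.max(np.abs(once - twice)) < 1e-10


def test_sign_coherence_two_state():
    P0 = np.array([[0.8, 0.5], [0.2, 0.5]])
    b = np.array([[0.0, 0.0], [-1.0, 0.0]])
    xs = np.linspace(-2, 2, 21)
    p21 = np.array([scenario_matrix(P0, b, x)[1, 0] for x in xs])
    assert np.all(np.diff(p21) < 0)


def test_curve_zero_beta_constant(caribbean_fit):
    curve = caribbean_fit.scenario(
        beta=np.zeros((6, 6)), x_grid=[-2, 0, 2], n_rep=500, seed=7
    )
    assert np.ptp(curve.coral["mean"]) < 1e-10
    assert np.ptp(curve.algae["hi95"]) < 1e-10


def test_curve_matches_unperturbed_at_origin(caribbean_fit):
    """The x = 0 column equals the unperturbed posterior equilibrium summary
    when computed from the same seed (identical posterior draws)."""
    curve = caribbean_fit.scenario(x_grid=[0.0], n_rep=2000, seed=11)
    eq = caribbean_fit.equilibrium_cover_posterior(n_rep=2000, seed=11)
    assert curve.coral["mean"][0] == pytest.approx(eq.mean[0], abs=1e-9)
    assert curve.algae["lo95"][0] == pytest.approx(eq.ci95[0][1], abs=1e-9)


def test_caribbean_response_direction_and_uncertainty(caribbean_fit):
    curve = caribbean_fit.scenario(x_grid=np.linspace(0, 2, 9), n_rep=2000, seed=13)
    # favourable conditions raise equilibrium coral cover, monotonically on [0, 2]
    assert np.all(np.diff(curve.coral["mean"]) > 0)
    lo = caribbean_fit.scenario(x_grid=[-2.0], n_rep=2000, seed=13)
    assert lo.coral["mean"][0] < curve.coral["mean"][0]
    # uncertainty asymmetry: wider 95% coral band under favourable conditions
    w0 = curve.coral["hi95"][0] - curve.coral["lo95"][0]
    w2 = curve.coral["hi95"][-1] - curve.coral["lo95"][-1]
    assert w2 > w0


def test_curve_to_frame(caribbean_fit):
    curve = caribbean_fit.scenario(x_grid=[0, 1], n_rep=200, seed=3)
    frame = curve.to_frame()
    assert set(frame["statistic"]) == {"coral", "algae"} | {
        f"pi_{s}" for s in "ABCDEF"
    }
    assert len(frame) == 2 * (2 + 6)
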