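"""Synthetic survey generator: construction invariants and parameter recovery."""

import numpy as np
import pytest
from scipy.stats import chi2

from reefmarkov import (
    ReefMarkovModel,
    StateScheme,
    SurveyDesign,
    TransitionCounts,
    classify_surveys,
    count_transitions,
    lrt_homogeneity,
    make_true_model,
    pool_to_reef_year,
    simulate_surveys,
    stationary_distribution,
)


def test_preset_truths(caribbean):
    m = make_true_model("caribbean-like")
    assert m.P_true[0, 0] == pytest.approx(29 / 51)
    assert np.allclose(m.P_true.sum(axis=0), 1.0)
    assert np.isclose(m.init.sum(), 1.0)
    ident = make_true_model("custom", P=np.eye(6))
    assert np.array_equal(ident.P_true, np.eye(6))
    with pytest.raises(ValueError, match="column-stochastic"):
        make_true_model("custom", P=np.full((6, 6), 0.15))
    with pytest.raises(ValueError, match="preset"):
        make_true_model("nope")


def test_cover_sampling_round_trip(rng):
    """Generated covers always classify back to the generating state."""
    model = make_true_model("caribbean-like")
    scheme = StateScheme()
    r = np.random.default_rng(4)
    for state in range(6):
        for _ in range(200):
            c, a = model.sample_cover(state, r)
            assert int(scheme.classify_index(c, a)) == state
            assert c + a <= 100


def test_identity_truth_constant_sequences():
    model = make_true_model("custom", P=np.eye(6))
    design = SurveyDesign(n_reefs=30, obs_per_reef={5: 1.0}, dropout=0.0)
    df = classify_surveys(simulate_surveys(model, design, np.random.default_rng(8)))
    for _, g in df.groupby("reef"):
        assert g["state"].nunique() == 1


def test_design_shapes():
    d = SurveyDesign.caribbean_like()
    assert d.n_reefs == 69 and min(d.obs_per_reef) == 2 and max(d.obs_per_reef) == 7
    g = SurveyDesign.gbr_like()
    assert g.n_reefs == 55 and max(g.obs_per_reef) == 11
    with pytest.raises(ValueError, match="at least 2"):
        SurveyDesign(n_reefs=10, obs_per_reef={1: 1.0})
    with pytest.raises(ValueError, match="year range"):
        SurveyDesign(n_reefs=10, year_range=(2000, 2003), obs_per_reef={9: 1.0})


def test_simulated_design_properties():
    model = make_true_model("caribbean-like")
    design = SurveyDesign.caribbean_like(n_reefs=200)
    df = simulate_surveys(model, design, np.random.default_rng(12))
    per_reef = df.groupby("reef")["year"].count()
    assert per_reef.min() >= 2
    assert df["year"].between(*design.year_range).all()
    # mpa flags are reef-level and roughly at the design fraction
    mpa_by_reef = df.groupby("reef")["mpa"].nunique()
    assert (mpa_by_reef == 1).all()
    assert abs(df.groupby("reef")["mpa"].first().mean() - 0.65) < 0.12


def test_parameter_recovery_well_sampled_columns():
    """500 reefs x 10 annual surveys recover the truth closely where the
    source state was observed often."""
    truth = make_true_model("caribbean-like")
    design = SurveyDesign(
        n_reefs=500, year_range=(1996, 2006), obs_per_reef={10: 1.0}, dropout=0.0
    )
    df = simulate_surveys(truth, design, np.random.default_rng(20111102))
    res = ReefMarkovModel.from_surveys(df).fit()
    heavy = res.counts.column_totals >= 1000
    assert heavy.any()
    # heavily sampled columns: multinomial noise is well below 0.05 per cell
    assert np.abs(res.params - truth.P_true)[:, heavy].max() < 0.05
    assert np.abs(res.params - truth.P_true).mean() < 0.025


def test_recovery_sharpens_with_data():
    """Element-wise estimation error shrinks as the number of reefs grows."""
    truth = make_true_model("caribbean-like")
    errs = {}
    for n_reefs in (100, 1000):
        tot = []
        for seed in range(10):
            design = SurveyDesign(
                n_reefs=n_reefs, obs_per_reef={4: 1.0}, dropout=0.0
            )
            df = simulate_surveys(truth, design, np.random.default_rng(1000 + seed))
            res = ReefMarkovModel.from_surveys(df).fit()
            tot.append(np.abs(res.params - truth.P_true).mean())
        errs[n_reefs] = np.mean(tot)
    assert errs[1000] < errs[100]


def test_lrt_power_between_region_truths():
    """Transition data from the two regional truths are reliably distinguished
    at 300 pairs per subset."""
    rng = np.random.default_rng(99)
    crit = chi2.ppf(0.95, 30)
    truths = []
    for preset in ("caribbean-like", "gbr-like"):
        t = make_true_model(preset)
        truths.append((t.P_true, stationary_distribution(t.P_true)))
    rej = 0
    reps = 100
    for _ in range(reps):
        subs = []
        for P, pi in truths:
            src = rng.multinomial(300, pi)
            n = np.stack(
                [rng.multinomial(src[j], P[:, j]) for j in range(6)], axis=1
            )
            subs.append(TransitionCounts(n))
        rej += lrt_homogeneity(subs).statistic > crit
    assert rej / reps > 0.95


def test_simulated_surveys_feed_pipeline(rng):
    """End-to-end: generated tables pass validation and counting unchanged."""
    model = make_true_model("gbr-like")
    df = simulate_surveys(model, SurveyDesign.gbr_like(n_reefs=40), np.random.default_rng(5))
    pooled = classify_surveys(pool_to_reef_year(df))
    tc = count_transitions(pooled)
    n_pairs = sum(
        int(np.sum(np.diff(sorted(g["year"])) == 1)) for _, g in pooled.groupby("reef")
    )
    assert tc.total == n_pairs > 0
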