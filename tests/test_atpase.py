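"""ATP hydrolysis model suite: closed forms, reductions, fitting, occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from math import comb

from nsf20s import atpase as at
from nsf20s import synth

GRID = at.default_atp_grid(20, 0.5, 5000)


# -- poisoning curve --------------------------------------------------------

def test_poisoning_boundary_values():
    for j in range(1, 7):
        assert at.poisoning_curve(0.0, j) == pytest.approx(1.0)
        assert at.poisoning_curve(1.0, j) == pytest.approx(0.0)


def test_poisoning_pure_wt_fraction_at_sixty_percent_doping():
    """j=1: only pure WT hexamers stay active, (0.4)^6 ~ 0.4%."""
    assert at.poisoning_curve(0.6, 1) == pytest.approx(0.4**6)


def test_poisoning_monotone_decreasing():
    x = np.linspace(0, 1, 101)
    for j in (1, 2, 4, 6):
        y = at.poisoning_curve(x, j)
        assert np.all(np.diff(y) <= 1e-12)


def test_poisoning_matches_wt_weighted_monte_carlo():
    """The curve equals E[(n_WT/6) * 1{n_mut < j}] over random hexamers:
    active hexamers produce Pi only through their WT protomers."""
    rng = np.random.default_rng(17)
    draws = (rng.random((400_000, 6)) < 0.3).sum(axis=1)
    for j in (1, 2, 3):
        mc = np.mean((6 - draws) / 6 * (draws < j))
        assert at.poisoning_curve(0.3, j) == pytest.approx(mc, abs=3e-3)


# -- rate laws --------------------------------------------------------------

def test_hill_half_saturation_identity():
    assert at.hill_rate(40.0, 66.0, 40.0, 1.33) == pytest.approx(33.0)
    # n=1 reduces to Michaelis-Menten
    a = GRID
    assert np.allclose(at.hill_rate(a, 10, 5, 1.0), 10 * a / (a + 5))


def test_twomode_value_at_kd():
    """At A = K_d (half occupancy) the rate is (beta + 32 gamma)/64."""
    assert at.twomode_rate(4.8, 59, 7, 4.8) == pytest.approx((59 + 32 * 7) / 64)


def test_twomode_occupancy_identity_and_limits():
    """V = beta f^6 + gamma f equals the printed rational form."""
    p = GRID / 4.8
    rational = (59 * p**6 + 7 * p * (1 + p) ** 5) / (1 + p) ** 6
    assert np.allclose(at.twomode_rate(GRID, 59, 7, 4.8), rational, rtol=1e-12)
    assert at.twomode_rate(1e9, 59, 7, 4.8) == pytest.approx(66.0, rel=1e-6)
    assert at.twomode_rate(0.0, 59, 7, 4.8) == 0.0


@pytest.mark.parametrize(
    "reduce_fn, base_fn",
    [
        # concerted model with no tense state -> two-mode
        (lambda a: at.mwc_rate(a, 59, 7, 0.0, 4.8, 100.0),
         lambda a: at.twomode_rate(a, 59, 7, 4.8)),
        # equal R/T affinities -> two-mode with the coupled rate diluted
        # by the T-state population, beta -> beta/(1+L)
        (lambda a: at.mwc_rate(a, 59, 7, 3.7, 4.8, 4.8),
         lambda a: at.twomode_rate(a, 59 / 4.7, 7, 4.8)),
        # sequential model with alpha=1 -> two-mode
        (lambda a: at.knf_rate(a, 59, 7, 4.8, 1.0),
         lambda a: at.twomode_rate(a, 59, 7, 4.8)),
        # basal sequential with alpha=1 -> single-site Michaelis-Menten
        (lambda a: at.knf_rate(a, 0, 2.9, 11.0, 1.0, mode="basal"),
         lambda a: at.single_kd_rate(a, 2.9, 11.0)),
        # two-mode without the coupled term -> single-site Michaelis-Menten
        (lambda a: at.twomode_rate(a, 0.0, 7, 4.8),
         lambda a: at.single_kd_rate(a, 7, 4.8)),
    ],
)
def test_algebraic_model_reductions(reduce_fn, base_fn):
    a = GRID
    assert np.allclose(reduce_fn(a), base_fn(a), rtol=1e-10)


def test_knf_basal_equals_gamma_mean_occupancy():
    """Basal rate identity: V = gamma * <m>/6 with <m> from the
    sequential-binding occupancy distribution."""
    for a in (1.0, 30.0, 1000.0):
        occ = at.occupancy_distribution(a, 11.0, 1.6)
        v = at.knf_rate(a, 0.0, 2.9, 11.0, 1.6, mode="basal")
        assert v == pytest.approx(2.9 * occ.mean / 6, rel=1e-10)


def test_knf_basal_printed_parameter_evaluation():
    """Basal curve at the fitted parameters: ~2.65/min per protomer at 1 mM,
    saturating toward gamma."""
    v = at.knf_rate(1000.0, 0.0, 2.9, 11.0, 1.6, mode="basal")
    assert v == pytest.approx(2.644, abs=0.01)
    assert at.knf_rate(1e9, 0.0, 2.9, 11.0, 1.6, mode="basal") == pytest.approx(2.9, rel=1e-4)


@given(
    beta=st.floats(0.0, 200.0),
    gamma=st.floats(0.0, 50.0),
    k_d=st.floats(0.5, 500.0),
    alpha=st.floats(0.2, 5.0),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_rate_laws_nonnegative_and_monotone(beta, gamma, k_d, alpha):
    a = np.logspace(-2, 6, 120)
    for v in (
        at.twomode_rate(a, beta, gamma, k_d),
        at.knf_rate(a, beta, gamma, k_d, alpha),
        at.knf_rate(a, 0.0, gamma, k_d, alpha, mode="basal"),
    ):
        assert np.all(v >= -1e-12)
        assert np.all(np.diff(v) >= -1e-9 * max(beta + gamma, 1))


# -- occupancy --------------------------------------------------------------

def test_occupancy_binomial_case():
    occ = at.occupancy_distribution(4.8, 4.8, alpha=1.0)
    assert occ.p == pytest.approx([comb(6, m) / 64.0 for m in range(7)])
    assert occ.p[6] == pytest.approx(1 / 64)
    apo = at.occupancy_distribution(0.0, 4.8)
    assert apo.p[0] == 1.0


def test_occupancy_matches_partition_sum_enumeration():
    a, k_d, alpha = 100.0, 11.0, 1.6
    w = np.array([comb(6, m) * (a / k_d) ** m * alpha ** (-m * (m - 1) / 2)
                  for m in range(7)])
    occ = at.occupancy_distribution(a, k_d, alpha)
    assert np.allclose(occ.p, w / w.sum(), rtol=1e-12)


# -- fitting ----------------------------------------------------------------

def test_fit_recovers_noise_free_curve_exactly():
    data = synth.gen_titration(
        lambda a: at.twomode_rate(a, **synth.FIG6C_PARAMS), noise_cv=0.0
    )
    fit = at.fit_model(data, "twomode")
    assert fit.params["beta"] == pytest.approx(59.0, rel=1e-5)
    assert fit.params["gamma"] == pytest.approx(7.0, rel=1e-4)
    assert fit.params["k_d"] == pytest.approx(4.8, rel=1e-4)


def test_fit_recovers_twomode_parameters_within_two_se():
    """Stimulated-titration refit at the study conditions (5% CV, 6 reps)."""
    data = synth.fig6c_titration(seed=42)
    fit = at.fit_model(data, "twomode")
    for name, truth in [("beta", 59.0), ("k_d", 4.8)]:
        assert abs(fit.params[name] - truth) <= 2 * fit.stderr[name]


def test_fit_recovers_basal_alpha():
    """Basal-titration refit recovers the binding-penalty factor."""
    data = synth.fig6f_titration(seed=7)
    fit = at.fit_model(data, "knf_basal")
    assert fit.params["alpha"] == pytest.approx(1.6, rel=0.15)


def test_sequential_fit_to_independent_data_reduces_to_alpha_one():
    """Fitting the sequential model to two-mode data drives alpha -> 1."""
    data = synth.gen_titration(
        lambda a: at.twomode_rate(a, **synth.FIG6C_PARAMS),
        noise_cv=0.02, n_rep=6, seed=9,
    )
    fit = at.fit_model(data, "knf20s")
    assert fit.params["alpha"] == pytest.approx(1.0, abs=0.1)


def test_mwc_fit_to_twomode_data_collapses_to_twomode_curve():
    """The concerted model fitted to independent-binding data reduces to the
    simpler two-mode curve (degenerate L or K_t ~ K_r)."""
    data = synth.gen_titration(
        lambda a: at.twomode_rate(a, **synth.FIG6C_PARAMS),
        noise_cv=0.02, n_rep=6, seed=9,
    )
    fit = at.fit_model(data, "mwc")
    a = at.default_atp_grid(30)
    truth = at.twomode_rate(a, **synth.FIG6C_PARAMS)
    assert np.allclose(fit.predict(a), truth, rtol=0.05)


def test_fit_requires_enough_points():
    d = at.TitrationDataset(atp=np.array([1.0, 10, 100]), rate=np.array([1.0, 2, 3]))
    with pytest.raises(ValueError):
        at.fit_model(d, "mwc")


def test_confidence_interval_coverage():
    """95% intervals for beta/gamma/K_d cover truth in >= 90% of refits."""
    n_sim, hits = 100, np.zeros(3)
    for s in range(n_sim):
        data = synth.fig6c_titration(seed=1000 + s)
        fit = at.fit_model(data, "twomode")
        for i, (name, truth) in enumerate(
            [("beta", 59.0), ("gamma", 7.0), ("k_d", 4.8)]
        ):
            lo, hi = fit.ci(name)
            hits[i] += lo <= truth <= hi
    assert np.all(hits / n_sim >= 0.88)


# -- apparent Hill coefficients ---------------------------------------------

def test_apparent_hill_of_michaelis_menten_is_one():
    res = at.apparent_hill(lambda a: at.single_kd_rate(a, 7.0, 4.8))
    assert res["n"] == pytest.approx(1.0, abs=1e-4)


def test_apparent_hill_of_stimulated_model_is_modestly_cooperative():
    """Coupled all-or-none hydrolysis alone yields n ~ 1.3 without any
    cooperative binding."""
    res = at.apparent_hill(lambda a: at.twomode_rate(a, **synth.FIG6C_PARAMS))
    assert res["n"] == pytest.approx(1.33, abs=0.15)
    assert 1.0 < res["n"] < 6.0
    assert max(abs(n - res["n"]) for n in res["n_grid_sensitivity"]) < 0.05


def test_apparent_hill_of_basal_model_is_subunity():
    """Sequential binding penalty (alpha > 1) produces negative
    cooperativity, n ~ 0.58."""
    res = at.apparent_hill(
        lambda a: at.knf_rate(a, 0.0, mode="basal", **synth.FIG6F_PARAMS)
    )
    assert res["n"] == pytest.approx(0.58, abs=0.09)
    assert 0.0 < res["n"] < 1.0


# -- initial rates and stimulation -------------------------------------------

def test_initial_rate_linear_arithmetic():
    """1 μM Pi/min at 60 nM protomer is 16.7 per protomer per minute."""
    t, ab, std = synth.gen_progress_curve(1.0, noise_sd=0.0, seed=0)
    res = at.initial_rate(t, ab, std, enzyme_protomer_uM=0.06)
    assert res["rate"] == pytest.approx(1.0 / 0.06, rel=1e-9)


def test_initial_rate_from_saturating_progress_curve():
    t, ab, std = synth.gen_progress_curve(2.0, saturation_uM=150.0,
                                          duration_min=5.0, noise_sd=0.0003, seed=3)
    res = at.initial_rate(t, ab, std, enzyme_protomer_uM=0.06)
    assert res["rate"] == pytest.approx(2.0 / 0.06, rel=0.05)


def test_initial_rate_flat_series_is_zero():
    t, ab, std = synth.gen_progress_curve(0.0, noise_sd=0.0, seed=0)
    res = at.initial_rate(t, ab, std, enzyme_protomer_uM=0.06)
    assert res["rate"] == pytest.approx(0.0, abs=1e-9)


def test_fold_stimulation_identity_and_printed_value():
    same = {"beta": 0.0, "gamma": 5.0, "k_d": 10.0}
    basal = {"gamma": 5.0, "k_d": 10.0, "alpha": 1.0}
    assert at.fold_stimulation(same, basal, atp=1000.0) == pytest.approx(1.0)
    fold = at.fold_stimulation(synth.FIG6C_PARAMS, synth.FIG6F_PARAMS, atp=1000.0)
    assert fold == pytest.approx(24.0, rel=0.1)


# -- stochastic cross-check --------------------------------------------------

@pytest.mark.parametrize("atp", [2.0, 10.0, 100.0])
def test_gillespie_simulation_matches_closed_form(atp):
    """Continuous-time occupancy simulation reproduces the analytic
    two-mode rate — an oracle independent of the algebra."""
    sim = at.simulate_hydrolysis(atp, 59.0, 7.0, 4.8, t_end=3000.0, seed=int(atp))
    ana = at.twomode_rate(atp, 59.0, 7.0, 4.8)
    assert sim == pytest.approx(ana, rel=0.05)
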