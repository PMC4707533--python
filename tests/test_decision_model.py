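"""Decision model: observations, belief recursion, bounds, NDT, simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from dottrack import (
    BeliefState,
    ModelParams,
    belief_update,
    bound_value,
    make_observation,
    make_target_config,
    ndt_params_from_summary,
    ndt_summary,
    run_accumulation,
    sample_ndt,
    sample_trial,
    simulate_response,
    simulate_responses_batch,
)
from dottrack.decision_model import LEFT, RIGHT, TIMEOUT


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

def test_zero_noise_exact_observation_is_the_dot(d4_trial, rng):
    for t in (1, 13, 25):
        obs = make_observation(d4_trial, t, "exact", 0.0, rng)
        assert np.array_equal(obs, d4_trial.dots[t - 1])


def test_zero_noise_ddm_observation_is_the_target_mean(d4_trial, rng):
    mu = d4_trial.config.target_mean(d4_trial.true_target)
    for t in (1, 25):
        obs = make_observation(d4_trial, t, "ddm_equivalent", 0.0, rng)
        assert np.array_equal(obs, mu)


def test_observation_step_out_of_range(d4_trial, rng):
    for t in (0, 26):
        with pytest.raises(ValueError):
            make_observation(d4_trial, t, "exact", 10.0, rng)


def test_observation_noise_covariance_isotropic(d4_trial, rng):
    """Empirical covariance of repeated observations ≈ sigma_s² × identity."""
    sigma_s = 30.0
    obs = np.array(
        [make_observation(d4_trial, 5, "exact", sigma_s, rng) for _ in range(20000)]
    )
    cov = np.cov(obs, rowvar=False)
    se = sigma_s**2 * np.sqrt(2 / 20000)
    assert cov[0, 0] == pytest.approx(sigma_s**2, abs=5 * se)
    assert cov[1, 1] == pytest.approx(sigma_s**2, abs=5 * se)
    assert abs(cov[0, 1]) < 5 * se


# ---------------------------------------------------------------------------
# belief recursion
# ---------------------------------------------------------------------------

def test_equidistant_observation_leaves_beliefs_unchanged(d4_config):
    state = BeliefState(beliefs=(0.3, 0.7))
    new = belief_update(state, np.array([0.0, 40.0]), d4_config)
    assert new.belief_left == pytest.approx(0.3, abs=1e-12)
    assert new.t == 1


def test_no_accumulation_limit_uses_likelihood_only(d4_config, rng):
    """discount λ=0 erases history: beliefs depend on the current dot only."""
    obs = np.array([30.0, -12.0])
    for start in [(0.5, 0.5), (0.95, 0.05), (0.01, 0.99)]:
        new = belief_update(BeliefState(beliefs=start), obs, d4_config, discount=0.0)
        s2 = d4_config.sigma_stim**2
        ll = np.array(
            [
                -np.sum((obs - d4_config.mu_left) ** 2) / (2 * s2),
                -np.sum((obs - d4_config.mu_right) ** 2) / (2 * s2),
            ]
        )
        expected = np.exp(ll - ll.max())
        expected /= expected.sum()
        assert new.belief_left == pytest.approx(expected[0], abs=1e-10)


def test_recursive_equals_batch_posterior(d4_config, rng):
    """Lossless recursion matches the closed-form batch Bayes posterior."""
    prior_left = 0.37
    for _ in range(100):
        obs_seq = rng.normal(0.0, 80.0, size=(5, 2))
        state = BeliefState(beliefs=(prior_left, 1 - prior_left))
        for obs in obs_seq:
            state = belief_update(state, obs, d4_config)
        # batch: prior × product of likelihoods
        s2 = d4_config.sigma_stim**2
        ll_left = -np.sum((obs_seq - d4_config.mu_left) ** 2) / (2 * s2)
        ll_right = -np.sum((obs_seq - d4_config.mu_right) ** 2) / (2 * s2)
        log_post = np.array(
            [math.log(prior_left) + ll_left, math.log(1 - prior_left) + ll_right]
        )
        post = np.exp(log_post - log_post.max())
        post /= post.sum()
        assert state.belief_left == pytest.approx(post[0], abs=1e-10)


def test_beliefs_stay_normalized_under_extreme_observations(d4_config):
    state = BeliefState(beliefs=(0.5, 0.5))
    for x in (1e4, -1e4, 1e4, 3.0):
        state = belief_update(state, np.array([x, 0.0]), d4_config, discount=0.7)
        assert state.belief_left + state.belief_right == pytest.approx(1.0, abs=1e-12)
        assert 0.0 < state.belief_left < 1.0


@given(
    x=st.floats(-500, 500),
    y=st.floats(-500, 500),
    discount=st.floats(0.0, 1.0),
    b0=st.floats(0.01, 0.99),
)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_belief_update_preserves_normalization(x, y, discount, b0):
    """Property: any observation and leak keep beliefs a probability pair."""
    cfg = make_target_config("D3")
    state = belief_update(
        BeliefState(beliefs=(b0, 1 - b0)), np.array([x, y]), cfg,
        discount=discount,
    )
    assert state.belief_left + state.belief_right == pytest.approx(1.0, abs=1e-12)
    assert 0.0 < state.belief_left < 1.0


def test_non_finite_observation_rejected(d4_config):
    with pytest.raises(ValueError):
        belief_update(BeliefState(beliefs=(0.5, 0.5)), np.array([np.nan, 0.0]), d4_config)


# ---------------------------------------------------------------------------
# bound
# ---------------------------------------------------------------------------

def test_fixed_bound_is_constant():
    for t in (0, 5, 25):
        assert bound_value(t, 25, 0.83, s=0.0, k=1.7) == pytest.approx(0.83)


def test_full_collapse_reaches_half_at_deadline():
    assert bound_value(25, 25, 0.83, s=1.0, k=0.6) == pytest.approx(0.5, abs=1e-9)


def test_bound_starts_at_initial_value():
    assert bound_value(0, 25, 0.91, s=0.8, k=2.0) == pytest.approx(0.91)


def test_bound_monotone_nonincreasing_and_above_half():
    t = np.arange(26)
    for s in (0.0, 0.4, 1.0):
        for k in (0.3, 1.0, 3.0):
            b = bound_value(t, 25, 0.9, s=s, k=k)
            assert np.all(np.diff(b) <= 1e-15)
            assert np.all(b >= 0.5 - 1e-12)


def test_shape_controls_collapse_timing():
    """Small k drops the bound early; large k keeps it high until late."""
    mid_early = bound_value(8, 25, 0.9, s=1.0, k=0.4)
    mid_late = bound_value(8, 25, 0.9, s=1.0, k=3.0)
    assert mid_early < mid_late


def test_bound_parameter_validation():
    with pytest.raises(ValueError):
        bound_value(1, 25, 0.4)
    with pytest.raises(ValueError):
        bound_value(1, 25, 0.9, s=1.5)
    with pytest.raises(ValueError):
        bound_value(1, 25, 0.9, k=0.0)


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------

def test_minimal_bound_decides_at_first_dot(d4_trial, rng):
    params = ModelParams(sigma_s=0.0, ndt_mu=6.0, ndt_sigma=0.0,
                         bound=0.5 + 1e-9)
    out = run_accumulation(d4_trial, params, rng=rng)
    assert out.kind == "decided"
    assert out.t_d == 1


def test_overwhelming_prior_decides_immediately(d4_trial, rng):
    params = ModelParams(sigma_s=0.0, ndt_mu=6.0, ndt_sigma=0.0,
                         bound=0.9, prior_left=1 - 1e-9)
    out = run_accumulation(d4_trial, params, rng=rng)
    assert out.kind == "decided"
    assert out.choice == "left"
    assert out.t_d == 1


def test_decided_outcome_satisfies_bound(d4_trial, rng, easy_params):
    out = run_accumulation(d4_trial, easy_params, rng=rng, keep_trajectory=True)
    if out.kind == "decided":
        idx = 0 if out.choice == "left" else 1
        assert out.trajectory[out.t_d - 1][idx] >= easy_params.bound - 1e-12
        # no earlier crossing
        earlier = np.asarray(out.trajectory[: out.t_d - 1])
        if earlier.size:
            assert np.all(earlier.max(axis=1) < easy_params.bound)


def _mc_oracle_outcomes(trial, params, n, seed):
    """Independent accumulator: batch Bayes log-posterior per step via scipy
    normal densities, no shared code with the recursive implementation."""
    rng = np.random.default_rng(seed)
    cfg = trial.config
    out = []
    for _ in range(n):
        obs = trial.dots + rng.normal(0, params.sigma_s, size=trial.dots.shape)
        lp_left = np.log(params.prior_left) + np.cumsum(
            norm.logpdf(obs[:, 0], cfg.mu_left[0], cfg.sigma_stim)
            + norm.logpdf(obs[:, 1], cfg.mu_left[1], cfg.sigma_stim)
        )
        lp_right = np.log(1 - params.prior_left) + np.cumsum(
            norm.logpdf(obs[:, 0], cfg.mu_right[0], cfg.sigma_stim)
            + norm.logpdf(obs[:, 1], cfg.mu_right[1], cfg.sigma_stim)
        )
        p_left = 1.0 / (1.0 + np.exp(lp_right - lp_left))
        crossed = np.where((p_left >= params.bound) | (1 - p_left >= params.bound))[0]
        if crossed.size == 0:
            out.append((None, None))
        else:
            t = int(crossed[0])
            out.append(("left" if p_left[t] >= params.bound else "right", t + 1))
    return out


def test_accumulation_frequencies_match_independent_oracle(d4_trial, easy_params):
    """Choice/decision-step frequencies agree with an independently coded
    Monte-Carlo oracle within binomial error."""
    n = 4000
    mine = [
        run_accumulation(d4_trial, easy_params, rng=np.random.default_rng(1000))
        for _ in range(0)
    ]
    rng = np.random.default_rng(77)
    mine = [run_accumulation(d4_trial, easy_params, rng=rng) for _ in range(n)]
    theirs = _mc_oracle_outcomes(d4_trial, easy_params, n, seed=88)
    p_right_mine = np.mean([o.choice == "right" for o in mine])
    p_right_th = np.mean([c == "right" for c, _ in theirs])
    se = np.sqrt(0.25 / n)
    assert p_right_mine == pytest.approx(p_right_th, abs=6 * se)
    td_mine = np.mean([o.t_d for o in mine if o.t_d is not None])
    td_th = np.mean([t for _, t in theirs if t is not None])
    assert td_mine == pytest.approx(td_th, rel=0.05)


# ---------------------------------------------------------------------------
# non-decision time
# ---------------------------------------------------------------------------

def test_degenerate_ndt_is_deterministic(rng):
    assert sample_ndt(6.0, 0.0, rng) == pytest.approx(math.exp(6.0))
    mode, sd = ndt_summary(0.0, 0.0)
    assert (mode, sd) == (pytest.approx(1.0), pytest.approx(0.0))


def test_ndt_draws_positive_and_match_summary_moments(rng):
    mu, sigma = 6.0, 0.5
    draws = sample_ndt(mu, sigma, rng, size=1_000_000)
    assert np.all(draws > 0)
    _, sd = ndt_summary(mu, sigma)
    mean_expected = math.exp(mu + sigma**2 / 2)
    assert draws.mean() == pytest.approx(mean_expected, rel=0.005)
    assert draws.std() == pytest.approx(sd, rel=0.01)
    # empirical mode via histogram around the analytic mode
    mode_expected, _ = ndt_summary(mu, sigma)
    hist, edges = np.histogram(draws, bins=200, range=(0, 4 * mode_expected))
    mode_emp = 0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1])
    assert mode_emp == pytest.approx(mode_expected, rel=0.05)


def test_ndt_mode_closed_form():
    mode, _ = ndt_summary(0.0, 0.5)
    assert mode == pytest.approx(math.exp(-0.25), abs=1e-12)


@pytest.mark.parametrize("mu,sigma", [(0.0, 0.5), (6.0, 0.35), (5.5, 1.2)])
def test_ndt_summary_round_trip(mu, sigma):
    mode, sd = ndt_summary(mu, sigma)
    mu2, sigma2 = ndt_params_from_summary(mode, sd)
    assert mu2 == pytest.approx(mu, abs=1e-8)
    assert sigma2 == pytest.approx(sigma, abs=1e-8)


def test_ndt_params_from_summary_degenerate():
    mu, sigma = ndt_params_from_summary(250.0, 0.0)
    assert sigma == 0.0
    assert mu == pytest.approx(math.log(250.0))


def test_ndt_inversion_of_published_group_values():
    """Published D4 exact-input NDT mode/SD invert to a consistent log-normal."""
    mu, sigma = ndt_params_from_summary(399.35, 167.54)
    mode, sd = ndt_summary(mu, sigma)
    assert mode == pytest.approx(399.35, abs=1e-3)
    assert sd == pytest.approx(167.54, abs=1e-3)


# ---------------------------------------------------------------------------
# full response simulation
# ---------------------------------------------------------------------------

def test_forced_lapse_timeout(d4_trial, rng):
    params = ModelParams(sigma_s=10.0, ndt_mu=6.0, ndt_sigma=0.3, bound=0.9,
                         lapse_p=1.0, lapse_to_p=1.0)
    for _ in range(20):
        resp = simulate_response(d4_trial, params, rng=rng)
        assert resp.is_timeout
        assert resp.provenance == "lapse_timeout"


def test_deterministic_rt_decomposition(d4_trial, rng):
    """With no lapses and fixed NDT, rt = t_d × 93.2 + exp(ndt_mu) exactly."""
    params = ModelParams(sigma_s=0.0, ndt_mu=6.0, ndt_sigma=0.0, bound=0.85)
    out = run_accumulation(d4_trial, params, rng=rng)
    resp = simulate_response(d4_trial, params, rng=rng)
    assert out.kind == "decided"
    assert resp.choice == out.choice
    assert resp.rt_ms == pytest.approx(out.t_d * 93.2 + math.exp(6.0), abs=1e-9)


def test_response_distribution_matches_semianalytic_mixture(d4_trial):
    """Simulated choice/RT frequencies match a mixture assembled from the
    accumulator outcome frequencies, the NDT law and the lapse mixture."""
    params = ModelParams(sigma_s=40.0, ndt_mu=6.0, ndt_sigma=0.3, bound=0.8,
                         prior_left=0.45, lapse_p=0.1, lapse_to_p=0.3)
    n = 40000
    sim = simulate_responses_batch(
        d4_trial, params, n=n, rng=np.random.default_rng(5)
    )
    # accumulator-only outcome frequencies (independent run)
    acc = simulate_responses_batch(
        d4_trial, params.with_(lapse_p=0.0), n=n, rng=np.random.default_rng(6)
    )
    p_to_acc = np.mean(acc.choice == TIMEOUT)
    p_right_acc = np.mean(acc.choice == RIGHT)
    # analytic mixture
    p_timeout = params.lapse_p * params.lapse_to_p + (1 - params.lapse_p) * p_to_acc
    p_right = params.lapse_p * (1 - params.lapse_to_p) * 0.5 + (
        1 - params.lapse_p
    ) * p_right_acc
    se = np.sqrt(0.25 / n)
    assert np.mean(sim.choice == TIMEOUT) == pytest.approx(p_timeout, abs=6 * se)
    assert np.mean(sim.choice == RIGHT) == pytest.approx(p_right, abs=6 * se)
    # RT mean of evidence responses: E[t_d]·dt + E[NDT], lapse part uniform
    rt_mix = np.concatenate(
        [
            acc.rt_ms[acc.choice != TIMEOUT],
            np.random.default_rng(7).uniform(
                0, 2330.0, int(n * params.lapse_p * (1 - params.lapse_to_p))
            ),
        ]
    )
    sim_rts = sim.rt_ms[sim.choice != TIMEOUT]
    assert sim_rts.mean() == pytest.approx(rt_mix.mean(), rel=0.02)


def test_total_rt_deadline_rule_truncates(d4_trial):
    """Optional deadline on decision time + NDT converts slow responses."""
    params = ModelParams(sigma_s=0.0, ndt_mu=np.log(3000.0), ndt_sigma=0.0,
                         bound=0.85)
    on = simulate_response(
        d4_trial, params, rng=np.random.default_rng(0), deadline_on_total_rt=True
    )
    off = simulate_response(
        d4_trial, params, rng=np.random.default_rng(0), deadline_on_total_rt=False
    )
    assert on.is_timeout
    assert not off.is_timeout


# ---------------------------------------------------------------------------
# batch simulator consistency and DDM equivalence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mode", ["exact", "ddm_equivalent"])
@pytest.mark.parametrize("variant", ["standard", "leaky", "collapsing"])
def test_batch_equals_scalar_in_deterministic_limit(d4_trial, mode, variant):
    """With all noise sources off, the vectorized simulator reproduces the
    scalar reference path exactly, for every mode and variant."""
    params = ModelParams(
        sigma_s=0.0, ndt_mu=6.0, ndt_sigma=0.0, bound=0.8,
        prior_left=0.45, discount=0.8, stretch=0.6, shape=1.4,
    )
    scalar = simulate_response(
        d4_trial, params, mode=mode, variant=variant, rng=np.random.default_rng(0)
    )
    batch = simulate_responses_batch(
        d4_trial, params, n=3, mode=mode, variant=variant,
        rng=np.random.default_rng(0),
    )
    labels = {LEFT: "left", RIGHT: "right", TIMEOUT: "timeout"}
    assert labels[int(batch.choice[0])] == scalar.choice
    if not scalar.is_timeout:
        assert batch.rt_ms[0] == pytest.approx(scalar.rt_ms, abs=1e-9)
        assert np.all(batch.rt_ms == batch.rt_ms[0])


def test_batch_matches_scalar_distribution(d4_trial, easy_params):
    """Stochastic batch and scalar paths agree in outcome frequencies."""
    n = 6000
    batch = simulate_responses_batch(
        d4_trial, easy_params, n=n, rng=np.random.default_rng(21)
    )
    rng = np.random.default_rng(22)
    scalar = [simulate_response(d4_trial, easy_params, rng=rng) for _ in range(n)]
    se = np.sqrt(0.25 / n)
    for code, label in [(LEFT, "left"), (RIGHT, "right"), (TIMEOUT, "timeout")]:
        pb = np.mean(batch.choice == code)
        ps = np.mean([r.choice == label for r in scalar])
        assert pb == pytest.approx(ps, abs=6 * se)
    rb = batch.rt_ms[batch.choice != TIMEOUT]
    rs = [r.rt_ms for r in scalar if not r.is_timeout]
    assert rb.mean() == pytest.approx(np.mean(rs), rel=0.02)


def test_ddm_equivalent_increment_moments(d1_config, rng):
    """In DDM-equivalent mode the per-step log-odds increments are i.i.d.
    Gaussian with closed-form mean and variance."""
    sigma_s = 95.0
    tr = sample_trial(d1_config, "right", rng)
    n = 100_000
    mu_l, mu_r = d1_config.mu_left, d1_config.mu_right
    mu_true = d1_config.mu_right
    s2 = d1_config.sigma_stim**2
    mean_expected = (mu_r - mu_l) @ (mu_true - (mu_l + mu_r) / 2) / s2
    var_expected = np.sum((mu_r - mu_l) ** 2) * sigma_s**2 / s2**2
    obs_x = mu_true[0] + sigma_s * rng.standard_normal(n)
    # increment toward the true (right) target is the negative left log-odds
    inc = 2.0 * d1_config.offset * obs_x / s2
    se_mean = np.sqrt(var_expected / n)
    se_var = var_expected * np.sqrt(2.0 / n)
    assert inc.mean() == pytest.approx(mean_expected, abs=3 * se_mean)
    assert inc.var() == pytest.approx(var_expected, abs=3 * se_var)


def test_raising_bound_slows_and_improves(d4_config):
    """Higher confidence bound: longer decision times, fewer errors."""
    rng = np.random.default_rng(3)
    trials = [sample_trial(d4_config, "right", rng, f"t{i}") for i in range(40)]
    stats = {}
    for bound in (0.6, 0.95):
        params = ModelParams(sigma_s=60.0, ndt_mu=6.0, ndt_sigma=0.0, bound=bound)
        tds, errs = [], []
        for tr in trials:
            sim = simulate_responses_batch(
                tr, params, n=300, rng=np.random.default_rng(9)
            )
            resp = sim.choice != TIMEOUT
            tds.append(np.mean((sim.rt_ms[resp] - math.exp(6.0)) / 93.2))
            errs.append(np.mean(sim.choice[resp] == LEFT))
        stats[bound] = (np.mean(tds), np.mean(errs))
    assert stats[0.95][0] > stats[0.6][0]
    assert stats[0.95][1] < stats[0.6][1]
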