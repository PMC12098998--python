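import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avoidprior import models as M
from avoidprior import simulate_subject
from avoidprior.simulate import default_group_params
from avoidprior.task_design import build_block_design

from oracles import brute_force_nll


class TestTransforms:
    def test_reference_points(self):
        p = M.transform_parameters("bayes", np.zeros(3))
        assert p["tau"] == pytest.approx(0.01)
        assert p["mu0"] == pytest.approx(0.5)
        assert p["sigma0_sq"] == pytest.approx(0.5)
        p = M.transform_parameters("bayes_bias", np.zeros(4))
        assert p["phi"] == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            M.transform_parameters("wsls", np.zeros(2))

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-6, max_value=6),
            min_size=7,
            max_size=7,
        )
    )
    def test_round_trip_to_machine_precision(self, raw):
        theta = np.asarray(raw)
        spec = M.get_model("joint_2prior")
        back = M.inverse_transform_parameters(
            spec, M.transform_parameters(spec, theta).constrained
        )
        assert np.allclose(back, theta, atol=1e-9)


class TestSoftmax:
    def test_indifference_gives_half(self):
        assert M.softmax_p_go(10.0, 10.0, 3.7) == pytest.approx(0.5)

    def test_one_temperature_unit_advantage(self):
        # Q(go) - Q(ng) = tau -> 1 / (1 + e^-1)
        assert M.softmax_p_go(7.0, 2.0, 5.0) == pytest.approx(0.7310586, abs=1e-6)

    def test_high_temperature_limit(self):
        assert M.softmax_p_go(100.0, 0.0, 1e12) == pytest.approx(0.5, abs=1e-9)

    def test_monotone_in_value_difference(self):
        dq = np.linspace(-50, 50, 101)
        p = M.softmax_p_go(dq, 0.0, 10.0)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            M.softmax_p_go(1.0, 0.0, 0.0)


class TestUtilities:
    def test_softmax_only_robber(self):
        q = M.trial_utilities("softmax_only", "robber", 100, 30, {"tau": 1.0})
        assert q == (70.0, 0.0)

    def test_softmax_only_factory(self):
        q = M.trial_utilities("softmax_only", "factory", 100, 30, {"tau": 1.0})
        assert q == (-30.0, -100.0)

    def test_static_factory(self):
        q = M.trial_utilities(
            "static_prob", "factory", 100, 20, {"tau": 1.0, "p": 0.5}
        )
        assert q == (-70.0, -100.0)

    def test_wsls_success_bonus(self):
        q = M.trial_utilities(
            "wsls",
            "robber",
            100,
            30,
            {"tau": 1.0, "gamma_plus": 5.0, "gamma_minus": 2.0},
            prev_success=True,
        )
        assert q == (75.0, 0.0)

    def test_bayes_uses_posterior_mean(self):
        q = M.trial_utilities(
            "bayes",
            "robber",
            100,
            10,
            {"tau": 1.0, "mu0": 0.3, "sigma0_sq": 0.5},
            p_success=0.75,
        )
        assert q == (-10.0 + 75.0, 0.0)


class TestBetaPrior:
    def test_uniform_prior(self):
        assert M.beta_prior_from_moments(0.5, 1 / 3) == pytest.approx((1.0, 1.0))

    def test_asymmetric_prior(self):
        assert M.beta_prior_from_moments(0.8, 0.2) == pytest.approx((3.2, 0.8))

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.01, max_value=0.99),
    )
    def test_moment_round_trip(self, mu, s2):
        a, b = M.beta_prior_from_moments(mu, s2)
        assert a > 0 and b > 0
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(mu)
        assert var / (mean * (1 - mean)) == pytest.approx(s2)

    @pytest.mark.parametrize("mu,s2", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)])
    def test_domain_errors(self, mu, s2):
        with pytest.raises(ValueError):
            M.beta_prior_from_moments(mu, s2)


class TestBeliefUpdate:
    def test_success_increments_alpha(self):
        s = M.BeliefState(alpha0=1.0, beta0=1.0)
        s2 = M.update_belief(s, 3, "go", "success")
        assert s2.posterior(3) == (2.0, 1.0)
        assert s2.posterior_mean(3) == pytest.approx(2 / 3)

    def test_loss_increments_beta_other_stimuli_untouched(self):
        s = M.BeliefState(alpha0=2.0, beta0=1.0)
        s2 = M.update_belief(s, "a", "go", "loss")
        assert s2.posterior("a") == (2.0, 2.0)
        assert s2.posterior("b") == (2.0, 1.0)

    def test_posterior_mean(self):
        s = M.BeliefState(alpha0=3.0, beta0=1.0)
        assert s.posterior_mean("x") == pytest.approx(0.75)

    def test_passive_is_identity(self):
        s = M.update_belief(M.BeliefState(1.0, 1.0), 1, "go", "success")
        assert M.update_belief(s, 1, "ng", None).counts == s.counts

    def test_inconsistent_action_outcome(self):
        s = M.BeliefState(1.0, 1.0)
        with pytest.raises(ValueError):
            M.update_belief(s, 1, "ng", "success")
        with pytest.raises(ValueError):
            M.update_belief(s, 1, "go", None)


class TestLapse:
    @pytest.mark.parametrize(
        "phi,p,expected",
        [(0.0, 0.6, 0.6), (-0.5, 0.6, 0.3), (0.5, 0.6, 0.8)],
    )
    def test_rectifier_worked_values(self, phi, p, expected):
        assert M.biased_choice_prob(phi, p) == pytest.approx(expected)

    def test_softplus_close_to_rectifier_everywhere(self):
        phi = np.linspace(-0.99, 0.99, 397)
        for p in (0.05, 0.5, 0.95):
            gap = np.abs(
                M.biased_choice_prob(phi, p, "softplus")
                - M.biased_choice_prob(phi, p, "rectifier")
            )
            assert gap.max() < 0.007

    def test_softplus_converges_to_rectifier(self):
        phi, p = 0.3, 0.6
        exact = M.biased_choice_prob(phi, p, "rectifier")
        gaps = [
            abs(float(M.biased_choice_prob(phi, p, "softplus", alpha=a)) - exact)
            for a in (2, 5, 10, 20, 50)
        ]
        assert all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))
        assert abs(
            float(M.biased_choice_prob(phi, p, "softplus", alpha=100)) - exact
        ) < 1e-8

    def test_phi_out_of_range(self):
        with pytest.raises(ValueError):
            M.biased_choice_prob(1.5, 0.5)


@pytest.fixture(scope="module")
def ten_trial_subjects():
    """Short two-task datasets for oracle comparison."""
    rob = build_block_design("robber", seed=7)
    fac = build_block_design("factory", seed=8)
    out = {}
    for name in M.MODELS:
        spec = M.get_model(name)
        mean, _ = default_group_params(spec)
        theta = mean + 0.3 * np.arange(spec.n_params)
        designs = [rob, fac] if spec.joint else [rob]
        data = simulate_subject(spec, theta, designs, seed=13)
        frame = (
            data.frame
            if spec.joint
            else data.frame.iloc[:10].reset_index(drop=True)
        )
        out[name] = (frame, theta)
    return out


@pytest.mark.parametrize("name", sorted(M.MODELS))
@pytest.mark.parametrize("smoothing", ["rectifier", "softplus"])
def test_nll_matches_brute_force_enumeration(ten_trial_subjects, name, smoothing):
    """The vectorised likelihood equals an explicit trial-by-trial
    enumeration of the belief trajectory."""
    frame, theta = ten_trial_subjects[name]
    spec = M.get_model(name)
    fast = M.negative_log_likelihood(spec, frame, theta, smoothing=smoothing)
    slow = brute_force_nll(
        name,
        frame,
        M.transform_parameters(spec, theta).constrained,
        smoothing=smoothing,
    )
    assert fast == pytest.approx(slow, abs=1e-10)


def test_chance_likelihood(robber_design, bayes_subject):
    # an effectively infinite temperature forces P(go) = 0.5 on all trials
    theta = np.array([np.log(1e15)])
    frame = bayes_subject.frame
    nll = M.negative_log_likelihood("softmax_only", frame, theta)
    assert nll == pytest.approx(len(frame) * np.log(2), rel=1e-9)


def test_static_prob_is_zero_variance_limit_of_bayes(bayes_subject):
    frame = bayes_subject.frame
    theta_b = np.array([6.0, 0.4, -25.0])  # sigma0_sq = logistic(-25) ~ 1e-11
    theta_s = np.array([6.0, 0.4])
    nll_b = M.negative_log_likelihood("bayes", frame, theta_b)
    nll_s = M.negative_log_likelihood("static_prob", frame, theta_s)
    assert nll_b == pytest.approx(nll_s, abs=1e-6)


def test_flat_prior_limit_first_outcome_dominates():
    # sigma0_sq -> 1 means alpha0, beta0 -> 0: one observation swamps the prior
    a0, b0 = M.beta_prior_from_moments(0.3, 1 - 1e-9)
    s = M.update_belief(M.BeliefState(a0, b0), 1, "go", "success")
    assert s.posterior_mean(1) == pytest.approx(1.0, abs=1e-6)
    s = M.update_belief(M.BeliefState(a0, b0), 1, "go", "loss")
    assert s.posterior_mean(1) == pytest.approx(0.0, abs=1e-6)


def test_peaked_prior_limit_never_learns():
    a0, b0 = M.beta_prior_from_moments(0.3, 1e-9)
    s = M.BeliefState(a0, b0)
    for _ in range(20):
        s = M.update_belief(s, 1, "go", "loss")
    assert s.posterior_mean(1) == pytest.approx(0.3, abs=1e-6)


def test_choice_probabilities_proper(bayes_subject, bayes_theta):
    arrays = M.prepare_trial_arrays(bayes_subject.frame)
    p = M.predict_p_go("bayes", arrays, M.transform_parameters("bayes", bayes_theta))
    assert np.all((p > 0) & (p < 1))


def test_nll_rejects_bad_inputs(bayes_subject):
    with pytest.raises(ValueError):
        M.negative_log_likelihood("bayes", bayes_subject.frame, np.array([np.nan, 0, 0]))
    bad = bayes_subject.frame.copy()
    bad.loc[0, "choice"] = 2
    with pytest.raises(ValueError):
        M.negative_log_likelihood("bayes", bad, np.zeros(3))


def test_joint_model_requires_both_tasks(bayes_subject):
    robber_only = bayes_subject.frame[bayes_subject.frame["task"] == "robber"]
    with pytest.raises(ValueError):
        M.negative_log_likelihood("joint_1prior", robber_only, np.zeros(5))
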