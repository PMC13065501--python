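"""EM engine: exact Bayes E-step against brute-force enumeration, ascent
of the observed log-likelihood, label-orientation guarding, and parameter
recovery on simulated cohorts."""

import numpy as np
import pytest
from scipy.special import expit, logit

import misclassem as me
from misclassem.em import (
    Theta,
    align_labels,
    e_step,
    init_theta,
    m_step,
    observed_loglik,
    run_em,
)


def _brute_force_xi(cohort, theta, spec):
    """Independent oracle: per-subject two-term Bayes enumeration using
    plain density arithmetic (no log-space tricks)."""
    X1, X2, X3 = spec.x1(cohort.X), spec.x2(cohort.X), spec.x3(cohort.X)
    out = []
    for i in range(cohort.n):
        terms = {}
        for t in (0, 1):
            fy = me.outcome_density(
                cohort.Y[i], t, X1[i : i + 1], theta.outcome, spec.outcome_family
            )[0]
            pm = me.me_predict(theta.me, t, X2[i : i + 1])[0]
            pm = pm if cohort.Tobs[i] == 1 else 1 - pm
            pt = theta.ps.prob(X3[i : i + 1])[0]
            pt = pt if t == 1 else 1 - pt
            terms[t] = fy * pm * pt
        out.append(terms[1] / (terms[0] + terms[1]))
    return np.clip(np.array(out), 1e-10, 1 - 1e-10)


def _mirror(theta):
    """Swap the latent labels analytically: t -> 1-t in all three models."""
    o = theta.outcome
    outcome = me.OutcomeParams(o.gamma0 + o.psi, -o.psi, o.gamma, o.sigma2)
    m = theta.me
    memod = me.MEParams("glm", alpha0=m.alpha0 + m.alpha1, alpha1=-m.alpha1, eta=m.eta)
    p = theta.ps
    ps = me.PSParams(-p.beta0, -p.beta)
    return Theta(outcome, memod, ps)


class TestInit:
    def test_m2_init_matches_closed_form(self, s1_cohort, s1_spec):
        th = init_theta(s1_cohort, s1_spec, 0.8, 0.8)
        assert th.me.alpha0 == pytest.approx(logit(0.2), abs=1e-12)
        assert th.me.alpha1 == pytest.approx(logit(0.8) - logit(0.2), abs=1e-12)
        assert np.all(th.me.eta == 0)
        assert th.outcome.sigma2 > 0

    def test_no_misclassification_init_equals_oracle_fit(self, s1_spec):
        c = me.generate_scenario(me.scenario_config("S1", n=500, seed=31))
        clean = me.Cohort(Y=c.Y, Tobs=c.T_true.copy(), X=c.X, T_true=c.T_true)
        th = init_theta(clean, s1_spec, 0.999, 0.999)
        oracle = me.fit_weighted_outcome(
            clean.Y, clean.T_true.astype(float), clean.X, np.ones(clean.n), "gaussian"
        )
        assert th.outcome.psi == pytest.approx(oracle.psi, abs=1e-10)

    @pytest.mark.parametrize("s", [0.4, 0.5, 1.0, 1.2])
    def test_initialization_outside_half_one_rejected(self, s1_cohort, s1_spec, s):
        with pytest.raises(ValueError):
            init_theta(s1_cohort, s1_spec, s, 0.8)


class TestEStep:
    def test_equals_brute_force_enumeration(self, s1_cohort, s1_spec):
        th = init_theta(s1_cohort, s1_spec)
        xi = e_step(s1_cohort, th, s1_spec)
        np.testing.assert_allclose(xi, _brute_force_xi(s1_cohort, th, s1_spec), rtol=1e-9)

    def test_single_subject_hand_computation(self):
        """One subject, every factor written out by hand."""
        cohort = me.Cohort(Y=np.array([3.0]), Tobs=np.array([1]), X=np.zeros((1, 1)))
        spec = me.ModelSpec()
        theta = Theta(
            me.OutcomeParams(1.0, 2.0, np.zeros(1), 1.0),
            me.MEParams("glm", alpha0=-1.386, alpha1=2.773, eta=np.zeros(1)),
            me.PSParams(0.0, np.zeros(1)),
        )
        num = (
            np.exp(-0.5 * (3 - 3) ** 2) * expit(-1.386 + 2.773) * 0.5
        )
        den = num + np.exp(-0.5 * (3 - 1) ** 2) * expit(-1.386) * 0.5
        xi = e_step(cohort, theta, spec)
        assert xi[0] == pytest.approx(num / den, abs=1e-12)

    def test_uninformative_y_and_tobs_give_ps(self, rng):
        """With psi=0 and a surrogate independent of T, the posterior is
        exactly the propensity score."""
        n = 50
        X = rng.normal(size=(n, 2))
        cohort = me.Cohort(
            Y=rng.normal(size=n), Tobs=rng.integers(0, 2, n), X=X
        )
        spec = me.ModelSpec()
        theta = Theta(
            me.OutcomeParams(0.0, 0.0, np.zeros(2), 1.0),
            me.MEParams("glm", alpha0=0.3, alpha1=0.0, eta=np.zeros(2)),
            me.PSParams(0.5, np.array([1.0, -1.0])),
        )
        xi = e_step(cohort, theta, spec)
        np.testing.assert_allclose(xi, theta.ps.prob(X), rtol=1e-10)

    def test_total_symmetry_gives_half(self):
        cohort = me.Cohort(Y=np.array([0.7]), Tobs=np.array([1]), X=np.zeros((1, 1)))
        theta = Theta(
            me.OutcomeParams(0.0, 0.0, np.zeros(1), 1.0),
            me.MEParams("glm", alpha0=0.0, alpha1=0.0, eta=np.zeros(1)),
            me.PSParams(0.0, np.zeros(1)),
        )
        assert e_step(cohort, theta, me.ModelSpec())[0] == pytest.approx(0.5)


class TestObservedLoglik:
    def test_single_subject_brute_force(self):
        cohort = me.Cohort(Y=np.array([1.2]), Tobs=np.array([0]), X=np.array([[0.5]]))
        spec = me.ModelSpec()
        theta = Theta(
            me.OutcomeParams(1.0, 2.0, np.array([0.3]), 1.5),
            me.MEParams("glm", alpha0=-1.0, alpha1=2.0, eta=np.array([0.2])),
            me.PSParams(0.1, np.array([-0.4])),
        )
        total = 0.0
        for t in (0, 1):
            fy = me.outcome_density(1.2, t, np.array([[0.5]]), theta.outcome, "gaussian")[0]
            pm = me.me_predict(theta.me, t, np.array([[0.5]]))[0]
            pm = 1 - pm  # Tobs = 0
            pt = theta.ps.prob(np.array([[0.5]]))[0]
            pt = pt if t == 1 else 1 - pt
            total += fy * pm * pt
        assert observed_loglik(cohort, theta, spec) == pytest.approx(np.log(total), abs=1e-10)

    def test_label_swap_symmetry(self, s1_cohort, s1_spec):
        th = init_theta(s1_cohort, s1_spec)
        assert observed_loglik(s1_cohort, th, s1_spec) == pytest.approx(
            observed_loglik(s1_cohort, _mirror(th), s1_spec), abs=1e-8
        )

    def test_additivity_under_duplication(self, s1_spec):
        c = me.generate_scenario(me.scenario_config("S1", n=40, seed=32))
        th = init_theta(c, s1_spec)
        dup = me.Cohort(
            Y=np.append(c.Y, c.Y[0]),
            Tobs=np.append(c.Tobs, c.Tobs[0]),
            X=np.vstack([c.X, c.X[:1]]),
        )
        single = me.Cohort(Y=c.Y[:1], Tobs=c.Tobs[:1], X=c.X[:1])
        assert observed_loglik(dup, th, s1_spec) == pytest.approx(
            observed_loglik(c, th, s1_spec) + observed_loglik(single, th, s1_spec),
            abs=1e-8,
        )


class TestMStep:
    def test_degenerate_posteriors_equal_oracle_fits(self, s1_cohort, s1_spec):
        c = s1_cohort
        xi = np.clip(c.T_true.astype(float), 1e-10, 1 - 1e-10)
        th = m_step(c, xi, s1_spec)
        direct = me.fit_weighted_outcome(
            c.Y, c.T_true.astype(float), c.X, np.ones(c.n), "gaussian"
        )
        np.testing.assert_allclose(th.outcome.flat(), direct.flat(), atol=1e-6)

    def test_q_function_improves(self, s1_cohort, s1_spec):
        """The M-step maximizes the expected complete-data log-likelihood:
        Q at the update is >= Q at the previous parameters."""
        th0 = init_theta(s1_cohort, s1_spec)
        xi = e_step(s1_cohort, th0, s1_spec)
        th1 = m_step(s1_cohort, xi, s1_spec, theta_prev=th0)

        def q(theta):
            from misclassem.em import _log_factors

            l1, l0 = _log_factors(s1_cohort, theta, s1_spec)
            return float((xi * l1 + (1 - xi) * l0).sum())

        assert q(th1) >= q(th0) - 1e-8

    def test_vd_me_component_frozen(self):
        cfg = me.scenario_config("S4", n=400, seed=33)
        c = me.generate_scenario(cfg)
        spec = me.ModelSpec(me_backend="vd")
        th0 = init_theta(c, spec)
        xi = e_step(c, th0, spec)
        th1 = m_step(c, xi, spec, theta_prev=th0)
        assert th1.me is th0.me


class TestRunEM:
    def test_clean_cohort_converges_fast_to_oracle(self, s1_spec):
        """With a perfect surrogate and near-certain initial sens/spec the
        EM reduces to the oracle estimator in a couple of iterations."""
        c = me.generate_scenario(me.scenario_config("S1", n=600, seed=34))
        clean = me.Cohort(Y=c.Y, Tobs=c.T_true.copy(), X=c.X, T_true=c.T_true)
        state = run_em(clean, s1_spec, init_sens=0.999999, init_spec=0.999999)
        oracle = me.fit_weighted_outcome(
            clean.Y, clean.T_true.astype(float), clean.X, np.ones(clean.n), "gaussian"
        )
        assert state.converged
        assert state.n_iter <= 3
        assert state.theta.outcome.psi == pytest.approx(oracle.psi, abs=1e-4)

    def test_loglik_nondecreasing_glm(self, s1_spec):
        for seed in range(5):
            c = me.generate_scenario(me.scenario_config("S1", n=300, seed=40 + seed))
            state = run_em(c, s1_spec)
            diffs = np.diff(state.loglik_trace)
            assert diffs.min() > -1e-8

    def test_scenario1_recovers_effect(self, s1_spec):
        c = me.generate_scenario(me.scenario_config("S1", n=1000, seed=35))
        state = run_em(c, s1_spec)
        assert state.converged
        assert state.theta.outcome.psi == pytest.approx(2.0, abs=0.35)

    def test_parameter_recovery_large_cohort(self, s1_spec):
        """All generating parameters recovered within +-0.15 on one large
        Scenario-1 cohort."""
        c = me.generate_scenario(me.scenario_config("S1", n=5000, seed=36))
        th = run_em(c, s1_spec).theta
        assert th.outcome.gamma0 == pytest.approx(1.0, abs=0.15)
        assert th.outcome.psi == pytest.approx(2.0, abs=0.15)
        np.testing.assert_allclose(th.outcome.gamma, [-0.8, 0.8, -0.8, 0.8, -0.8], atol=0.15)
        assert th.outcome.sigma2 == pytest.approx(1.0, abs=0.15)
        assert th.me.alpha0 == pytest.approx(-1.386, abs=0.15)
        assert th.me.alpha1 == pytest.approx(2.773, abs=0.3)
        np.testing.assert_allclose(th.me.eta, np.zeros(5), atol=0.15)
        np.testing.assert_allclose(th.ps.beta, [-2.0, 3.0, 1.0, 0.5, 0.5], atol=0.3)

    def test_nonconvergence_warns_not_raises(self, s1_spec):
        c = me.generate_scenario(me.scenario_config("S1", n=300, seed=37))
        with pytest.warns(UserWarning, match="did not converge"):
            state = run_em(c, s1_spec, max_iter=2)
        assert not state.converged

    def test_vd_backend_pins_validated_posteriors(self):
        cfg = me.scenario_config("S4", n=500, seed=38)
        c = me.generate_scenario(cfg)
        state = run_em(c, me.ModelSpec(me_backend="vd"))
        mask = c.validated.astype(bool)
        np.testing.assert_allclose(
            state.xi[mask], np.clip(c.T_true[mask], 1e-10, 1 - 1e-10), atol=1e-12
        )


class TestAlignLabels:
    def test_well_separated_fit_unchanged(self, s1_spec):
        c = me.generate_scenario(me.scenario_config("S1", n=500, seed=39))
        state = run_em(c, s1_spec)
        aligned = align_labels(c, state, s1_spec)
        assert not aligned.label_flipped
        assert aligned.theta is state.theta

    def test_mirrored_state_restored(self, s1_spec):
        c = me.generate_scenario(me.scenario_config("S1", n=500, seed=39))
        state = run_em(c, s1_spec)
        mirrored = me.EMState(
            theta=_mirror(state.theta),
            xi=1 - state.xi,
            loglik_trace=state.loglik_trace,
            n_iter=state.n_iter,
            converged=state.converged,
        )
        fixed = align_labels(c, mirrored, s1_spec)
        assert fixed.label_flipped
        # orientation restored: implied sens + spec > 1, psi back near +2
        assert fixed.theta.outcome.psi == pytest.approx(state.theta.outcome.psi, abs=0.05)
        # mirror solution has the same observed likelihood
        assert observed_loglik(c, mirrored.theta, s1_spec) == pytest.approx(
            observed_loglik(c, state.theta, s1_spec), abs=1e-6
        )

    def test_idempotent(self, s1_spec):
        c = me.generate_scenario(me.scenario_config("S1", n=500, seed=39))
        state = run_em(c, s1_spec)
        once = align_labels(c, state, s1_spec)
        twice = align_labels(c, once, s1_spec)
        assert twice.theta is once.theta
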