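"""EM estimation of the joint outcome / measurement-error / propensity model
with the true treatment as a latent binary variable.

The observed-data likelihood for subject i sums the product of the three
model factors over the two latent states:

    L_i(theta) = sum_{t in {0,1}} f(Y_i | t, X1_i) P(Tobs_i | t, X2_i) P(t | X3_i)

E-step: the posterior xi_i = P(T_i = 1 | Y_i, Tobs_i, X_i; theta) is an
exact two-term Bayes computation. M-step: each subject is expanded into a
t=1 row with weight xi_i and a t=0 row with weight 1 - xi_i, and the three
component models are refit by weighted maximum likelihood. With the
parametric (glm) measurement-error backend every M-step is an exact
maximizer, so the observed log-likelihood is non-decreasing; the neural
backend performs a conditional-improvement (generalized EM) step instead.

The latent labels are identified only up to a swap; initializing the
surrogate's sensitivity and specificity above 0.5 breaks the symmetry, and
a post-fit orientation guard flips the labels back if a run nevertheless
converges to the mirror solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .models import (
    MEParams,
    ModelSpec,
    OutcomeParams,
    PSParams,
    SEPARATION_WARN,
    fit_me_on_validation,
    fit_weighted_me_glm,
    fit_weighted_outcome,
    fit_weighted_ps,
    me_predict,
)
from .nn import fit_weighted_me_nn, tune_nn
from .simdata import Cohort, sens_spec_to_alpha

__all__ = ["Theta", "EMState", "init_theta", "e_step", "observed_loglik", "m_step", "run_em", "align_labels"]

#: posterior clipping bound: keeps weights strictly positive and logs finite
XI_EPS = 1e-10

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Theta:
    outcome: OutcomeParams
    me: MEParams
    ps: PSParams

    def flat(self) -> np.ndarray:
        return np.concatenate([self.outcome.flat(), self.me.flat(), self.ps.flat()])


@dataclass
class EMState:
    theta: Theta
    xi: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    label_flipped: bool = False


def init_theta(
    cohort: Cohort,
    spec: ModelSpec,
    sens0: float = 0.8,
    spec0: float = 0.8,
) -> Theta:
    """Starting parameters for the EM.

    The outcome and propensity models are fit with the observed treatment
    standing in for the latent one; the measurement-error model starts from
    an assumed (sensitivity, specificity) of the surrogate, with covariate
    coefficients zero. Initial sensitivity and specificity must exceed 0.5:
    that choice orients the latent labels (the likelihood is invariant to
    swapping them).
    """
    if not 0.5 < sens0 < 1.0 or not 0.5 < spec0 < 1.0:
        raise ValueError(
            "initial sensitivity and specificity must lie in (0.5, 1) to "
            "orient the latent labels"
        )
    n = cohort.n
    ones = np.ones(n)
    tobs = cohort.Tobs.astype(float)
    outcome = fit_weighted_outcome(
        cohort.Y, tobs, spec.x1(cohort.X), ones, spec.outcome_family
    )
    ps = fit_weighted_ps(tobs, spec.x3(cohort.X), ones)
    if spec.me_backend == "vd":
        me = fit_me_on_validation(cohort, spec)
    else:
        alpha0, alpha1 = sens_spec_to_alpha(sens0, spec0)
        p2 = spec.x2(cohort.X).shape[1]
        me = MEParams(backend="glm", alpha0=alpha0, alpha1=alpha1, eta=np.zeros(p2))
    return Theta(outcome=outcome, me=me, ps=ps)


def _log_factors(cohort: Cohort, theta: Theta, spec: ModelSpec):
    """Per-subject log of the three-factor product at t=1 and t=0."""
    X1 = spec.x1(cohort.X)
    X2 = spec.x2(cohort.X)
    X3 = spec.x3(cohort.X)
    Y = cohort.Y
    out = theta.outcome

    if spec.outcome_family == "gaussian":
        s2 = out.sigma2
        l_y1 = -0.5 * ((Y - out.linpred(1, X1)) ** 2 / s2 + _LOG2PI + np.log(s2))
        l_y0 = -0.5 * ((Y - out.linpred(0, X1)) ** 2 / s2 + _LOG2PI + np.log(s2))
    else:
        mu1 = expit(out.linpred(1, X1))
        mu0 = expit(out.linpred(0, X1))
        yb = Y.astype(bool)
        l_y1 = np.log(np.clip(np.where(yb, mu1, 1 - mu1), XI_EPS, None))
        l_y0 = np.log(np.clip(np.where(yb, mu0, 1 - mu0), XI_EPS, None))

    tobs1 = cohort.Tobs == 1
    p_t1 = np.clip(me_predict(theta.me, 1, X2), XI_EPS, 1 - XI_EPS)
    p_t0 = np.clip(me_predict(theta.me, 0, X2), XI_EPS, 1 - XI_EPS)
    l_m1 = np.log(np.where(tobs1, p_t1, 1 - p_t1))
    l_m0 = np.log(np.where(tobs1, p_t0, 1 - p_t0))

    pi = np.clip(theta.ps.prob(X3), XI_EPS, 1 - XI_EPS)
    l_p1 = np.log(pi)
    l_p0 = np.log1p(-pi)

    l1 = l_y1 + l_m1 + l_p1
    l0 = l_y0 + l_m0 + l_p0
    if not (np.isfinite(l1).all() and np.isfinite(l0).all()):
        bad = int(np.flatnonzero(~(np.isfinite(l1) & np.isfinite(l0)))[0])
        raise ValueError(f"non-finite likelihood factor for subject {bad}")
    return l1, l0


def e_step(cohort: Cohort, theta: Theta, spec: ModelSpec) -> np.ndarray:
    """Posterior probability of true treatment for every subject.

    A two-term Bayes computation per subject, done in log space for
    stability and clipped to [XI_EPS, 1 - XI_EPS]. Under the
    validation-data backend, validated subjects' labels are data: their
    posteriors are pinned to the observed true treatment.
    """
    l1, l0 = _log_factors(cohort, theta, spec)
    xi = expit(l1 - l0)
    xi = np.clip(xi, XI_EPS, 1.0 - XI_EPS)
    if spec.me_backend == "vd" and cohort.validated is not None:
        mask = cohort.validated.astype(bool)
        xi[mask] = np.clip(cohort.T_true[mask].astype(float), XI_EPS, 1.0 - XI_EPS)
    return xi


def observed_loglik(cohort: Cohort, theta: Theta, spec: ModelSpec) -> float:
    """Observed-data log-likelihood, via a log-sum-exp over the two latent
    states (the covariate density factor, parameter-free, is dropped)."""
    l1, l0 = _log_factors(cohort, theta, spec)
    return float(np.logaddexp(l1, l0).sum())


def _expand(cohort: Cohort, xi: np.ndarray, spec: ModelSpec):
    """Two-row-per-subject expansion: (t=1, weight xi), (t=0, weight 1-xi)."""
    n = cohort.n
    Tdup = np.concatenate([np.ones(n), np.zeros(n)])
    w = np.concatenate([xi, 1.0 - xi])
    Ydup = np.concatenate([cohort.Y, cohort.Y])
    Xdup = np.vstack([cohort.X, cohort.X])
    Tobsdup = np.concatenate([cohort.Tobs, cohort.Tobs]).astype(float)
    return Ydup, Tdup, Tobsdup, Xdup, w


def m_step(
    cohort: Cohort,
    xi: np.ndarray,
    spec: ModelSpec,
    theta_prev: Optional[Theta] = None,
    nn_hyper: Optional[tuple] = None,
) -> Theta:
    """Refit the three component models by weighted maximum likelihood on
    the posterior-weighted expansion. A frozen (validation-fitted)
    measurement-error model is carried over unchanged."""
    Ydup, Tdup, Tobsdup, Xdup, w = _expand(cohort, xi, spec)
    outcome = fit_weighted_outcome(
        Ydup, Tdup, spec.x1(Xdup), w, spec.outcome_family
    )
    ps = fit_weighted_ps(
        Tdup, spec.x3(Xdup), w,
        start=theta_prev.ps if theta_prev is not None else None,
    )
    prev_me = theta_prev.me if theta_prev is not None else None
    if spec.me_backend == "vd":
        if prev_me is None or not prev_me.frozen:
            raise ValueError("vd backend requires a frozen measurement-error model")
        me = prev_me
    elif spec.me_backend == "nn":
        me = fit_weighted_me_nn(
            Tobsdup, Tdup, spec.x2(Xdup), w,
            config=spec.nn_config, hyper=nn_hyper, warm_start=prev_me,
        )
    else:
        me = fit_weighted_me_glm(
            Tobsdup, Tdup, spec.x2(Xdup), w,
            start=prev_me if (prev_me is not None and prev_me.backend == "glm") else None,
        )
    return Theta(outcome=outcome, me=me, ps=ps)


def _orientation_stat(cohort: Cohort, state: EMState, spec: ModelSpec) -> float:
    """Median conditional log-odds shift of the surrogate under the
    fitted error model: the per-subject logit P(Tobs=1|T=1,x) - logit
    P(Tobs=1|T=0,x), summarized by its median. Equals the treatment
    coefficient alpha1 for the logistic backend. Positive in the
    canonical orientation (initializing sensitivity and specificity
    above 0.5 makes the surrogate positively informative) and exactly
    antisymmetric under the label swap. The median, unlike the mean or
    marginal sensitivity + specificity, is insensitive to a neural
    error model's wild extrapolation in covariate regions where one arm
    has no effective data."""
    X2 = spec.x2(cohort.X)
    me = state.theta.me
    p1 = np.clip(me_predict(me, 1, X2), XI_EPS, 1 - XI_EPS)
    p0 = np.clip(me_predict(me, 0, X2), XI_EPS, 1 - XI_EPS)
    return float(np.median(np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))))


def align_labels(cohort: Cohort, state: EMState, spec: ModelSpec) -> EMState:
    """Restore the canonical latent-label orientation if the fit converged
    to the mirror solution (negative mean conditional log-odds shift of
    the surrogate): flip the posteriors, refit from them, let the EM
    re-converge, and flag the state. For the glm backend the mirror image is an exact one-step
    reparameterization; a neural error model cannot be mirrored in
    parameter space, so its network is retrained from scratch on the
    flipped posteriors and a few EM iterations restore the fixed point.
    The flip is kept only if the observed log-likelihood is preserved
    (the two orientations of a genuine mirror mode are likelihood-
    equivalent); otherwise the original state is returned. Idempotent; a
    frozen validation-fitted error model is never flipped."""
    if state.theta.me.frozen:
        return state
    if _orientation_stat(cohort, state, spec) >= 0.0:
        return state
    hyper = None
    prev = state.theta
    if state.theta.me.backend == "nn":
        hyper = (state.theta.me.nn.n_hidden, state.theta.me.nn.decay)
        prev = None  # fresh network fit on the flipped weights
    xi = 1.0 - state.xi
    theta = m_step(cohort, xi, spec, theta_prev=prev, nn_hyper=hyper)
    extra = 1
    prev_flat = theta.flat()
    for _ in range(50):
        xi = e_step(cohort, theta, spec)
        theta = m_step(cohort, xi, spec, theta_prev=theta, nn_hyper=hyper)
        extra += 1
        flat = theta.flat()
        if flat.shape == prev_flat.shape and np.abs(flat - prev_flat).max() < 1e-6:
            break
        prev_flat = flat
    xi = e_step(cohort, theta, spec)
    ll = observed_loglik(cohort, theta, spec)
    repaired = EMState(
        theta=theta, xi=xi, loglik_trace=state.loglik_trace, n_iter=0, converged=True
    )
    # the orientations of a genuine mirror mode agree to within network
    # training noise (a nat or two); a flip that loses much more than
    # that, or that re-converged to a still-mirrored state, did not land
    # in the mirror image and is rolled back
    if ll < state.loglik_trace[-1] - 5.0 or _orientation_stat(cohort, repaired, spec) < 0:
        return state
    return EMState(
        theta=theta,
        xi=xi,
        loglik_trace=np.append(state.loglik_trace, ll),
        n_iter=state.n_iter + extra,
        converged=state.converged,
        label_flipped=True,
    )


def run_em(
    cohort: Cohort,
    spec: ModelSpec,
    init_sens: float = 0.8,
    init_spec: float = 0.8,
    tol: float = 1e-6,
    max_iter: int = 500,
    loglik_tol: float = 0.0,
    anneal_start: Optional[float] = None,
    anneal_cool: float = 0.85,
    n_starts: Optional[int] = None,
    nn_hyper: Optional[tuple] = None,
) -> EMState:
    """Run the EM to convergence.

    ``n_starts`` controls a multi-start for the neural backend, whose
    training landscape occasionally plants a run in a clearly inferior
    mode (tens of nats below the dominant one): the EM is run once per
    start and the state with the highest final observed log-likelihood
    is kept. The first two starts use independently cross-validated
    hyperparameters (distinct folds and network seeds); if they both
    converge to the same mode (final log-likelihoods within a few nats)
    the search stops, otherwise a last start fixes the hidden layer at
    the top of the grid with the best decay seen so far, because the CV
    criterion — held-out surrogate prediction under the rough initial
    weights — occasionally under-selects capacity that the joint
    likelihood clearly supports. Defaults: 3 for the neural backend, 1
    for the parametric backends (deterministic M-steps).

    Convergence is declared when the maximum absolute parameter change
    drops below ``tol``; a positive ``loglik_tol`` additionally stops when
    the relative observed log-likelihood change falls below it, but is
    disabled by default because EM trajectories routinely cross long
    likelihood plateaus (tiny likelihood gain, parameters still moving)
    well before the maximizer. Non-convergence returns a state flagged
    ``converged=False`` with a warning, never an exception. For the neural
    backend the hyperparameters are tuned once, on the weights implied by
    the initial parameters, and held fixed; each subsequent M-step
    warm-starts the network (a generalized-EM scheme).

    ``anneal_start`` sets the initial temperature of a deterministic
    annealing schedule on the E-step: posteriors are tempered as
    expit((l1 - l0) / temperature) and the temperature decays by
    ``anneal_cool`` per iteration down to 1. Annealing flattens early
    posteriors and avoids the collapsed-latent-class local maxima that the
    flexible neural backend is prone to; it defaults on (temperature 4)
    for that backend and off (temperature 1, i.e. standard EM) for the
    parametric ones. The monotone-ascent guarantee applies only to the
    un-annealed glm iterations.
    """
    if n_starts is None:
        n_starts = 3 if spec.me_backend == "nn" else 1
    if n_starts > 1:
        best = None
        runs = []
        for k in range(n_starts):
            spec_k = replace(
                spec, nn_config=replace(spec.nn_config, seed=spec.nn_config.seed + 7919 * k)
            )
            hyper_k = nn_hyper
            if k == n_starts - 1 and best is not None and best.theta.me.backend == "nn":
                hyper_k = (max(spec.nn_config.hidden_grid), best.theta.me.nn.decay)
            state = run_em(
                cohort, spec_k,
                init_sens=init_sens, init_spec=init_spec, tol=tol,
                max_iter=max_iter, loglik_tol=loglik_tol,
                anneal_start=anneal_start, anneal_cool=anneal_cool, n_starts=1,
                nn_hyper=hyper_k,
            )
            runs.append(state)
            if best is None or state.loglik_trace[-1] > best.loglik_trace[-1]:
                best = state
            if (
                k == 1
                and runs[0].converged
                and runs[1].converged
                and abs(runs[0].loglik_trace[-1] - runs[1].loglik_trace[-1]) < 5.0
            ):
                break
        return best

    theta = init_theta(cohort, spec, sens0=init_sens, spec0=init_spec)
    trace = [observed_loglik(cohort, theta, spec)]
    if spec.me_backend == "nn" and nn_hyper is None:
        # tuned once per start, on the weights implied by the initial
        # parameters, then held fixed across M-steps; each start draws its
        # own cross-validation folds
        xi0 = e_step(cohort, theta, spec)
        Ydup, Tdup, Tobsdup, Xdup, w = _expand(cohort, xi0, spec)
        nn_hyper = tune_nn(Tobsdup, Tdup, spec.x2(Xdup), w, spec.nn_config)

    if anneal_start is None:
        anneal_start = 4.0 if spec.me_backend == "nn" else 1.0
    temp = max(1.0, float(anneal_start))

    converged = False
    n_iter = 0
    prev_flat = None
    prev_xi = None
    for n_iter in range(1, max_iter + 1):
        if temp > 1.0:
            l1, l0 = _log_factors(cohort, theta, spec)
            xi = np.clip(expit((l1 - l0) / temp), XI_EPS, 1.0 - XI_EPS)
            if spec.me_backend == "vd" and cohort.validated is not None:
                mask = cohort.validated.astype(bool)
                xi[mask] = np.clip(
                    cohort.T_true[mask].astype(float), XI_EPS, 1.0 - XI_EPS
                )
        else:
            xi = e_step(cohort, theta, spec)
        theta = m_step(cohort, xi, spec, theta_prev=theta, nn_hyper=nn_hyper)
        ll = observed_loglik(cohort, theta, spec)
        trace.append(ll)
        flat = theta.flat()
        if temp == 1.0 and prev_flat is not None and flat.shape == prev_flat.shape:
            # coordinates past the separation threshold sit on a flat
            # likelihood ridge (effectively infinite); their wandering is
            # not evidence against convergence of the model fit
            finite = (np.abs(flat) < SEPARATION_WARN) | (np.abs(prev_flat) < SEPARATION_WARN)
            dpar = float(np.abs(flat - prev_flat)[finite].max()) if finite.any() else 0.0
            dll = abs(trace[-1] - trace[-2]) / (1.0 + abs(trace[-2]))
            # exactly stationary posteriors imply a stationary (exact)
            # M-step even when a separated component wanders its ridge
            dxi = float(np.abs(xi - prev_xi).max()) if prev_xi is not None else np.inf
            if dpar < tol or dxi < 1e-12 or (loglik_tol > 0 and dll < loglik_tol):
                converged = True
                break
        prev_flat = flat
        prev_xi = xi
        temp = max(1.0, temp * anneal_cool)
    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations", UserWarning
        )
    xi = e_step(cohort, theta, spec)
    state = EMState(
        theta=theta,
        xi=xi,
        loglik_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
    )
    return align_labels(cohort, state, spec)
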