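"""The three component models of the latent-treatment likelihood.

M1 — outcome model  E[Y | T, X1] (Gaussian/identity or Bernoulli/logit),
M2 — measurement-error model  P(Tobs | T, X2) (logistic, neural-network,
     or validation-data-fitted), and
M3 — propensity-score model  P(T = 1 | X3),

each fit by weighted maximum likelihood with per-observation fractional
weights, which is what the EM M-step requires: every subject contributes a
row with t=1 and weight xi and a row with t=0 and weight 1-xi, turning the
expected complete-data log-likelihood into three ordinary weighted GLM
log-likelihoods.

The weighted logistic solver is a compact IRLS written on numpy: the M-step
is executed on the order of 10^5 times across a Monte-Carlo experiment, so
the solver is kept allocation-light. Its output agrees with statsmodels'
frequency-weighted GLM to optimizer tolerance (asserted in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "NNConfig",
    "OutcomeParams",
    "MEParams",
    "PSParams",
    "SeparationWarning",
    "outcome_density",
    "fit_weighted_outcome",
    "fit_weighted_ps",
    "fit_weighted_me_glm",
    "fit_me_on_validation",
    "me_predict",
    "weighted_logistic",
]

#: hard cap on |coefficient|; set above the ridge-penalized optimum of a
#: separated fit so it only guards pathological escapes
COEF_CAP = 40.0
#: |coefficient| beyond which a separation warning is emitted
SEPARATION_WARN = 15.0
#: ridge strength making separated logistic MLEs finite and deterministic;
#: small enough that the EM ascent property holds to well below 1e-8
RIDGE = 1e-11


class SeparationWarning(UserWarning):
    """Raised (as a warning) when a logistic fit drifts toward perfect
    separation and its coefficients are capped."""


@dataclass(frozen=True)
class NNConfig:
    """Hyperparameters for the neural-network measurement-error backend.

    The network has one hidden ReLU layer and a sigmoid output; training
    minimizes weighted binary cross-entropy plus an L2 penalty (``decay``)
    via L-BFGS. ``hidden_grid`` and ``decay_grid`` span the cross-validated
    grid search; fold count and optimizer iteration caps are fixed here.
    """

    hidden_grid: tuple = (1, 2, 3)
    decay_grid: tuple = (0.0, 0.001, 0.01, 0.05, 0.1)
    cv_folds: int = 3
    maxiter_init: int = 400
    maxiter_warm: int = 40
    maxiter_cv: int = 100
    seed: int = 0


@dataclass(frozen=True)
class ModelSpec:
    """Which covariate columns enter each component model, the outcome
    family, and the measurement-error backend.

    ``None`` column lists mean "all available covariates" — the recommended
    default when the error mechanism is unknown.
    """

    x1_cols: Optional[tuple] = None
    x2_cols: Optional[tuple] = None
    x3_cols: Optional[tuple] = None
    outcome_family: str = "gaussian"
    me_backend: str = "glm"
    nn_config: NNConfig = field(default_factory=NNConfig)

    def __post_init__(self):
        if self.outcome_family not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown outcome_family {self.outcome_family!r}")
        if self.me_backend not in ("glm", "nn", "vd"):
            raise ValueError(f"unknown me_backend {self.me_backend!r}")

    @property
    def link(self) -> str:
        return "identity" if self.outcome_family == "gaussian" else "logit"

    def x1(self, X: np.ndarray) -> np.ndarray:
        return X if self.x1_cols is None else X[:, list(self.x1_cols)]

    def x2(self, X: np.ndarray) -> np.ndarray:
        return X if self.x2_cols is None else X[:, list(self.x2_cols)]

    def x3(self, X: np.ndarray) -> np.ndarray:
        return X if self.x3_cols is None else X[:, list(self.x3_cols)]


@dataclass(frozen=True)
class OutcomeParams:
    gamma0: float
    psi: float
    gamma: np.ndarray
    sigma2: Optional[float] = None  # gaussian only

    def __post_init__(self):
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def linpred(self, t, X1: np.ndarray) -> np.ndarray:
        return self.gamma0 + self.psi * np.asarray(t, dtype=float) + X1 @ self.gamma

    def flat(self) -> np.ndarray:
        extra = [] if self.sigma2 is None else [self.sigma2]
        return np.concatenate([[self.gamma0, self.psi], self.gamma, extra])


@dataclass(frozen=True)
class MEParams:
    """Measurement-error model parameters.

    ``backend`` is 'glm', 'nn' or 'vd'. glm/vd store the logistic
    coefficients; nn stores the fitted network. ``frozen`` marks a
    validation-fitted model that the M-step must not update.
    """

    backend: str
    alpha0: Optional[float] = None
    alpha1: Optional[float] = None
    eta: Optional[np.ndarray] = None
    nn: Optional[object] = None  # MLP instance
    frozen: bool = False

    def flat(self) -> np.ndarray:
        if self.backend in ("glm", "vd"):
            return np.concatenate([[self.alpha0, self.alpha1], self.eta])
        return self.nn.flat()


@dataclass(frozen=True)
class PSParams:
    beta0: float
    beta: np.ndarray

    def prob(self, X3: np.ndarray) -> np.ndarray:
        return expit(self.beta0 + X3 @ self.beta)

    def flat(self) -> np.ndarray:
        return np.concatenate([[self.beta0], self.beta])


# ---------------------------------------------------------------------------
# weighted fitting primitives
# ---------------------------------------------------------------------------

def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if not np.isfinite(w).all():
        raise ValueError("weights must be finite")
    if w.sum() <= 0:
        raise ValueError("weights are all zero: nothing to fit")
    return w


def weighted_logistic(
    Z: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    start: Optional[np.ndarray] = None,
    max_iter: int = 60,
    tol: float = 1e-10,
    fallback: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Weighted logistic MLE by iteratively reweighted least squares.

    ``Z`` is the full design matrix (intercept included by the caller),
    ``y`` the 0/1 response and ``w`` nonnegative fractional weights. A
    minute ridge penalty (``RIDGE``) keeps the optimum finite and the
    iteration deterministic when the weighted data are (near-)separated —
    common in intermediate EM iterations — at a coefficient perturbation
    far below optimizer tolerance for regular problems. Coefficients
    drifting past ``SEPARATION_WARN`` trigger a
    :class:`SeparationWarning`; ``COEF_CAP`` is a final hard bound. When
    ``fallback`` parameters are supplied, a separated fit returns them
    instead: a weighted MLE at infinity carries no usable update, and the
    previous finite parameters saturate the same probabilities without
    wandering the flat ridge.
    """
    w = _check_weights(w)
    n, k = Z.shape
    b = np.zeros(k) if start is None else np.asarray(start, dtype=float).copy()

    def obj(bb):
        lp = Z @ bb
        return float((w * (y * lp - np.logaddexp(0.0, lp))).sum()) - 0.5 * RIDGE * float(bb @ bb)

    cur = obj(b)
    for _ in range(max_iter):
        p = expit(Z @ b)
        grad = Z.T @ (w * (y - p)) - RIDGE * b
        wpq = w * p * (1.0 - p)
        H = (Z * wpq[:, None]).T @ Z
        H[np.diag_indices_from(H)] += RIDGE
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "degenerate weighted logistic design (collinear columns or "
                "degenerate weights)"
            ) from exc
        # dampen huge Newton steps from near-flat likelihoods
        snorm = np.abs(step).max()
        if snorm > 10.0:
            step *= 10.0 / snorm
        # step-halving keeps the (concave) objective monotone, so the
        # iteration converges from any start, including antipodal ones
        t = 1.0
        nxt = cur
        for _ in range(40):
            cand = obj(b + t * step)
            if cand >= cur - 1e-12:
                nxt = cand
                break
            t *= 0.5
        b = b + t * step
        cur = nxt
        if np.abs(step).max() * t < tol:
            break
    if np.abs(b).max() > SEPARATION_WARN:
        warnings.warn(
            "large logistic coefficients: data look separated for this "
            "weighting",
            SeparationWarning,
            stacklevel=2,
        )
        if fallback is not None:
            return np.asarray(fallback, dtype=float).copy()
        b = np.clip(b, -COEF_CAP, COEF_CAP)
    return b


def _weighted_ols(Z: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    A = (Z * w[:, None]).T @ Z
    A[np.diag_indices_from(A)] += 1e-12
    try:
        return np.linalg.solve(A, Z.T @ (w * y))
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate weighted least-squares design") from exc


def fit_weighted_outcome(
    Y: np.ndarray,
    T: np.ndarray,
    X1: np.ndarray,
    weights: np.ndarray,
    family: str = "gaussian",
) -> OutcomeParams:
    """Weighted MLE of the outcome model on the two-row expansion.

    For the Gaussian family the variance estimate is the weighted mean
    squared residual with the weight total (the subject count, when weights
    come from posteriors) as denominator — the closed-form maximizer of the
    weighted Gaussian log-likelihood.
    """
    w = _check_weights(weights)
    Z = np.column_stack([np.ones(len(Y)), np.asarray(T, dtype=float), X1])
    if family == "gaussian":
        b = _weighted_ols(Z, Y, w)
        resid = Y - Z @ b
        sigma2 = float((w * resid**2).sum() / w.sum())
        sigma2 = max(sigma2, 1e-12)
        return OutcomeParams(gamma0=b[0], psi=b[1], gamma=b[2:], sigma2=sigma2)
    if family == "bernoulli":
        b = weighted_logistic(Z, Y, w)
        return OutcomeParams(gamma0=b[0], psi=b[1], gamma=b[2:], sigma2=None)
    raise ValueError(f"unknown family {family!r}")


def fit_weighted_ps(
    T: np.ndarray,
    X3: np.ndarray,
    weights: np.ndarray,
    start: Optional[PSParams] = None,
) -> PSParams:
    """Weighted logistic regression of the (latent) treatment on X3.

    Warm-startable (and sticky once separated) for the same reason as the
    measurement-error fit: near-degenerate EM weightings otherwise make
    successive updates wander a flat likelihood ridge.
    """
    w = _check_weights(weights)
    Z = np.column_stack([np.ones(len(T)), X3])
    b0 = None
    if start is not None:
        b0 = np.concatenate([[start.beta0], start.beta])
    sticky = b0 if (b0 is not None and np.abs(b0).max() > SEPARATION_WARN) else None
    b = weighted_logistic(Z, np.asarray(T, dtype=float), w, start=b0, fallback=sticky)
    return PSParams(beta0=b[0], beta=b[1:])


def fit_weighted_me_glm(
    Tobs: np.ndarray,
    T: np.ndarray,
    X2: np.ndarray,
    weights: np.ndarray,
    start: Optional[MEParams] = None,
) -> MEParams:
    """Weighted logistic regression of Tobs on (t, X2): the parametric
    measurement-error backend's M-step."""
    w = _check_weights(weights)
    Z = np.column_stack([np.ones(len(Tobs)), np.asarray(T, dtype=float), X2])
    b0 = None
    if start is not None and start.backend in ("glm", "vd"):
        b0 = np.concatenate([[start.alpha0, start.alpha1], start.eta])
    # once a previous update was declared separated its parameters already
    # saturate the predicted probabilities; stop chasing the flat ridge
    sticky = b0 if (b0 is not None and np.abs(b0).max() > SEPARATION_WARN) else None
    b = weighted_logistic(Z, np.asarray(Tobs, dtype=float), w, start=b0, fallback=sticky)
    return MEParams(backend="glm", alpha0=b[0], alpha1=b[1], eta=b[2:])


def fit_me_on_validation(cohort, spec: ModelSpec) -> MEParams:
    """Fit the logistic measurement-error model on the validated subsample
    (where the true treatment is observed) and freeze it."""
    if cohort.validated is None or cohort.T_true is None:
        raise ValueError("validation fitting requires a validated mask and T_true")
    mask = cohort.validated.astype(bool)
    if mask.sum() == 0:
        raise ValueError("validation set is empty")
    if mask.sum() < 2:
        raise ValueError("validation set too small to fit the error model")
    X2 = spec.x2(cohort.X)[mask]
    Z = np.column_stack(
        [np.ones(mask.sum()), cohort.T_true[mask].astype(float), X2]
    )
    b = weighted_logistic(Z, cohort.Tobs[mask].astype(float), np.ones(mask.sum()))
    return MEParams(backend="vd", alpha0=b[0], alpha1=b[1], eta=b[2:], frozen=True)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

_LOG2PI = np.log(2.0 * np.pi)


def outcome_density(y, t, X1: np.ndarray, params: OutcomeParams, family: str):
    """Density/probability mass f(y | T=t, X1) under the outcome model.

    Vectorized over subjects; ``t`` may be a scalar or a vector.
    """
    mu = params.linpred(t, X1)
    if family == "gaussian":
        if params.sigma2 is None or params.sigma2 <= 0:
            raise ValueError("gaussian outcome density requires sigma2 > 0")
        z2 = (np.asarray(y) - mu) ** 2 / params.sigma2
        return np.exp(-0.5 * (z2 + _LOG2PI + np.log(params.sigma2)))
    if family == "bernoulli":
        p = expit(mu)
        y = np.asarray(y)
        return np.where(y == 1, p, 1.0 - p)
    raise ValueError(f"unknown family {family!r}")


def me_predict(params: MEParams, t, X2: np.ndarray) -> np.ndarray:
    """P(Tobs = 1 | T = t, X2) under the fitted measurement-error model."""
    if params.backend in ("glm", "vd"):
        return expit(params.alpha0 + params.alpha1 * np.asarray(t, dtype=float) + X2 @ params.eta)
    if params.backend == "nn":
        t = np.broadcast_to(np.asarray(t, dtype=float), (X2.shape[0],))
        return params.nn.predict(t, X2)
    raise ValueError(f"unknown backend {params.backend!r}")
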