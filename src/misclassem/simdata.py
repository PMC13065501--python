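"""Synthetic cohort generation for treatment-misclassification studies.

Cohorts consist of an outcome ``Y`` (Gaussian or Bernoulli), a true binary
treatment ``T`` generated from a logistic propensity model, an observed
(possibly misclassified) treatment ``Tobs`` generated from a logistic (or
nonlinear) surrogate model, and five confounders: three jointly Gaussian
with an AR1 correlation structure and two independent Bernoulli(0.5).

All generators are pure functions of (parameters, seed): each stochastic
stage (covariates, treatment, misclassification, outcome, validation mask)
consumes an independent sub-stream derived from the seed and a stage tag,
so two scenarios differing only in the misclassification model share
identical covariates, treatment, and outcome draws at the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "ScenarioConfig",
    "Cohort",
    "gen_covariates",
    "gen_treatment",
    "gen_tobs",
    "gen_outcome",
    "sens_spec_to_alpha",
    "make_validation_mask",
    "generate_scenario",
    "scenario3_predictor",
    "SCENARIO_PRESETS",
]

# stage tags for independent sub-streams
_STAGE_COVARIATES = 0
_STAGE_TREATMENT = 1
_STAGE_MISCLASS = 2
_STAGE_OUTCOME = 3
_STAGE_VALIDATION = 4


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Independent generator for one stochastic stage of one cohort."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stage,)))


@dataclass(frozen=True)
class Cohort:
    """An analysis cohort: outcome, observed treatment, covariates, and
    (for simulated data) the latent truth.

    ``validated`` marks subjects whose ``T_true`` may be used as data by the
    validation-data estimator; it requires ``T_true`` to be present.
    """

    Y: np.ndarray
    Tobs: np.ndarray
    X: np.ndarray
    T_true: Optional[np.ndarray] = None
    validated: Optional[np.ndarray] = None

    def __post_init__(self):
        n = len(self.Y)
        if len(self.Tobs) != n or self.X.shape[0] != n:
            raise ValueError("Y, Tobs, X must have equal length")
        if not np.isin(self.Tobs, [0, 1]).all():
            raise ValueError("Tobs must be binary")
        if self.T_true is not None:
            if len(self.T_true) != n or not np.isin(self.T_true, [0, 1]).all():
                raise ValueError("T_true must be a binary vector of length n")
        if self.validated is not None:
            if self.T_true is None:
                raise ValueError("validated mask requires T_true")
            if len(self.validated) != n or not np.isin(self.validated, [0, 1]).all():
                raise ValueError("validated must be a binary vector of length n")

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"Y": self.Y, "Tobs": self.Tobs.astype(int)}
        for j in range(self.p):
            cols[f"X{j + 1}"] = self.X[:, j]
        if self.T_true is not None:
            cols["T_true"] = self.T_true.astype(int)
        if self.validated is not None:
            cols["validated"] = self.validated.astype(int)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full generative specification for one simulated cohort.

    Presets (``S1``, ``S2_weak``, ``S2_strong``, ``S3``, ``S4``) carry the
    published coefficient settings; ``custom`` uses the fields verbatim.
    """

    scenario_id: str = "custom"
    n: int = 1000
    outcome_family: str = "gaussian"
    rho: float = 0.3
    sigma2: float = 1.0
    me_alpha0: float = -1.4
    me_alpha1: float = 2.8
    me_eta: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    me_nonlinear: bool = False
    ps_beta0: float = 0.0
    ps_beta: tuple = (-2.0, 3.0, 1.0, 0.5, 0.5)
    outcome_gamma0: float = 1.0
    outcome_psi: float = 2.0
    outcome_gamma: tuple = (-0.8, 0.8, -0.8, 0.8, -0.8)
    validation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not 0.0 <= self.validation_fraction <= 1.0:
            raise ValueError("validation_fraction must lie in [0, 1]")
        if self.outcome_family not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown outcome_family {self.outcome_family!r}")
        if self.outcome_family == "gaussian" and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive for a gaussian outcome")


# Published generative settings. The propensity and outcome models are shared
# across scenarios; scenarios differ in the misclassification model (its
# covariate dependence and functional form) and, for S2_binary, the outcome.
_BASE = dict(
    rho=0.3,
    sigma2=1.0,
    ps_beta0=0.0,
    ps_beta=(-2.0, 3.0, 1.0, 0.5, 0.5),
    outcome_gamma0=1.0,
    outcome_psi=2.0,
    outcome_gamma=(-0.8, 0.8, -0.8, 0.8, -0.8),
)

SCENARIO_PRESETS: dict[str, dict] = {
    # misclassification independent of covariates: sens = spec = 0.8
    "S1": dict(_BASE, me_alpha0=-1.4, me_alpha1=2.8, me_eta=(0.0,) * 5),
    # covariate-dependent misclassification, weak and strong
    "S2_weak": dict(_BASE, me_alpha0=-1.4, me_alpha1=2.8, me_eta=(-0.4, 0.0, 0.4, 0.0, -0.4)),
    "S2_strong": dict(_BASE, me_alpha0=-1.4, me_alpha1=2.8, me_eta=(-2.0, 0.0, 2.0, 0.0, -2.0)),
    # binary outcome variant of S2 (logit link, intercept -1)
    "S2_weak_binary": dict(
        _BASE,
        me_alpha0=-1.4, me_alpha1=2.8, me_eta=(-0.4, 0.0, 0.4, 0.0, -0.4),
        outcome_family="bernoulli", outcome_gamma0=-1.0,
    ),
    "S2_strong_binary": dict(
        _BASE,
        me_alpha0=-1.4, me_alpha1=2.8, me_eta=(-2.0, 0.0, 2.0, 0.0, -2.0),
        outcome_family="bernoulli", outcome_gamma0=-1.0,
    ),
    # nonlinear, interaction-bearing misclassification
    "S3": dict(_BASE, me_alpha0=-1.4, me_alpha1=2.8, me_nonlinear=True),
    # S2_strong with an internal validation subsample (fraction set by caller;
    # 0.2 is the published default)
    "S4": dict(
        _BASE,
        me_alpha0=-1.4, me_alpha1=2.8, me_eta=(-2.0, 0.0, 2.0, 0.0, -2.0),
        validation_fraction=0.2,
    ),
}


def scenario_config(scenario_id: str, n: int = 1000, seed: int = 0, **overrides) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a preset id, with overrides."""
    if scenario_id == "custom":
        return ScenarioConfig(scenario_id="custom", n=n, seed=seed, **overrides)
    if scenario_id not in SCENARIO_PRESETS:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; expected one of "
            f"{sorted(SCENARIO_PRESETS)} or 'custom'"
        )
    params = dict(SCENARIO_PRESETS[scenario_id])
    params.update(overrides)
    return ScenarioConfig(scenario_id=scenario_id, n=n, seed=seed, **params)


def gen_covariates(n: int, rho: float = 0.3, seed: int = 0) -> np.ndarray:
    """Draw the n x 5 covariate matrix.

    Columns 1-3 are jointly Gaussian with mean zero, unit variance and
    corr(Xj, Xk) = rho^|j-k| (AR1); columns 4-5 are independent
    Bernoulli(0.5).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    rng = _rng(seed, _STAGE_COVARIATES)
    idx = np.arange(3)
    cov = rho ** np.abs(idx[:, None] - idx[None, :])
    xg = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    xb = rng.binomial(1, 0.5, size=(n, 2)).astype(float)
    return np.column_stack([xg, xb])


def gen_treatment(
    X: np.ndarray, beta0: float, beta: Sequence[float], seed: int = 0
) -> np.ndarray:
    """Draw true treatment T ~ Bernoulli(expit(beta0 + X @ beta))."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != X.shape[1]:
        raise ValueError(f"beta has length {beta.shape[0]} but X has {X.shape[1]} columns")
    p = expit(beta0 + X @ beta)
    rng = _rng(seed, _STAGE_TREATMENT)
    return (rng.random(X.shape[0]) < p).astype(int)


def scenario3_predictor(X: np.ndarray) -> np.ndarray:
    """Nonlinear covariate contribution to the Scenario-3 surrogate model:
    -2*exp(X1/2) + 2*(X1*X3/25 + 0.6)^3 - 2*X5.
    """
    x1, x3, x5 = X[:, 0], X[:, 2], X[:, 4]
    return -2.0 * np.exp(x1 / 2.0) + 2.0 * (x1 * x3 / 25.0 + 0.6) ** 3 - 2.0 * x5


def gen_tobs(
    T: np.ndarray,
    X: np.ndarray,
    alpha0: float,
    alpha1: float,
    eta: Sequence[float] = (),
    nonlinear: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Draw the observed surrogate treatment Tobs.

    P(Tobs=1 | T, X) = expit(alpha0 + alpha1*T + g(X)) where g is either the
    linear form eta . X or the Scenario-3 nonlinear transform of (X1, X3, X5).
    """
    if nonlinear:
        g = scenario3_predictor(X)
    else:
        eta = np.asarray(eta, dtype=float)
        if eta.size == 0:
            g = 0.0
        elif eta.shape[0] != X.shape[1]:
            raise ValueError(f"eta has length {eta.shape[0]} but X has {X.shape[1]} columns")
        else:
            g = X @ eta
    p = expit(alpha0 + alpha1 * np.asarray(T, dtype=float) + g)
    rng = _rng(seed, _STAGE_MISCLASS)
    return (rng.random(len(T)) < p).astype(int)


def gen_outcome(
    T: np.ndarray,
    X: np.ndarray,
    gamma0: float,
    psi: float,
    gamma: Sequence[float],
    family: str = "gaussian",
    sigma2: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw the outcome given true treatment and covariates.

    gaussian: Y = gamma0 + psi*T + X @ gamma + N(0, sigma2)
    bernoulli: Y ~ Bernoulli(expit(gamma0 + psi*T + X @ gamma))
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape[0] != X.shape[1]:
        raise ValueError(f"gamma has length {gamma.shape[0]} but X has {X.shape[1]} columns")
    lin = gamma0 + psi * np.asarray(T, dtype=float) + X @ gamma
    rng = _rng(seed, _STAGE_OUTCOME)
    if family == "gaussian":
        if sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        return lin + rng.normal(0.0, np.sqrt(sigma2), size=len(lin))
    if family == "bernoulli":
        return (rng.random(len(lin)) < expit(lin)).astype(float)
    raise ValueError(f"unknown family {family!r}")


def sens_spec_to_alpha(sens: float, spec: float) -> tuple[float, float]:
    """Map (sensitivity, specificity) of the surrogate to the logistic
    intercept and treatment coefficient of the covariate-free model:
    alpha0 = logit(1 - spec), alpha1 = logit(sens) - alpha0.
    """
    if not 0.0 < sens < 1.0 or not 0.0 < spec < 1.0:
        raise ValueError("sens and spec must lie strictly inside (0, 1)")
    alpha0 = float(logit(1.0 - spec))
    alpha1 = float(logit(sens)) - alpha0
    return alpha0, alpha1


def make_validation_mask(n: int, fraction: float, seed: int = 0) -> np.ndarray:
    """Uniformly random mask flagging exactly round(n * fraction) subjects."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    k = int(round(n * fraction))
    rng = _rng(seed, _STAGE_VALIDATION)
    mask = np.zeros(n, dtype=int)
    if k > 0:
        mask[rng.choice(n, size=k, replace=False)] = 1
    return mask


def generate_rhc_like(n: int = 5734, seed: int = 0) -> Cohort:
    """Synthetic high-dimensional stress cohort loosely shaped like an ICU
    observational study: 33 standardized covariates, a linear outcome, and a
    covariate-dependent misclassification model (alpha0=-1.1, alpha1=-2.8,
    eta=(0.5, -0.5, 0.7, -0.7) on four designated columns).

    Purely a synthetic fixture for exercising the estimators at p >> 5; it
    reproduces no published analysis.
    """
    rng = _rng(seed, _STAGE_COVARIATES)
    p = 33
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:8] = [0.4, -0.4, 0.3, -0.3, 0.2, 0.2, -0.2, 0.2]
    T = gen_treatment(X, -0.5, beta, seed)
    eta = np.zeros(p)
    eta[[0, 1, 2, 3]] = [0.5, -0.5, 0.7, -0.7]
    Tobs = gen_tobs(T, X, -1.1, -2.8, eta, seed=seed)
    gamma = np.zeros(p)
    gamma[:8] = [-1.0, 1.0, -0.5, 0.5, 0.8, -0.8, 0.3, -0.3]
    Y = gen_outcome(T, X, 10.0, -3.3, gamma, family="gaussian", sigma2=4.0, seed=seed)
    return Cohort(Y=Y, Tobs=Tobs, X=X, T_true=T)


def generate_scenario(config: ScenarioConfig) -> Cohort:
    """Generate a fully truth-tagged cohort from a scenario configuration."""
    X = gen_covariates(config.n, config.rho, config.seed)
    T = gen_treatment(X, config.ps_beta0, config.ps_beta, config.seed)
    Tobs = gen_tobs(
        T, X, config.me_alpha0, config.me_alpha1, config.me_eta,
        nonlinear=config.me_nonlinear, seed=config.seed,
    )
    Y = gen_outcome(
        T, X, config.outcome_gamma0, config.outcome_psi, config.outcome_gamma,
        family=config.outcome_family, sigma2=config.sigma2, seed=config.seed,
    )
    validated = None
    if config.validation_fraction > 0:
        validated = make_validation_mask(config.n, config.validation_fraction, config.seed)
    return Cohort(Y=Y, Tobs=Tobs, X=X, T_true=T, validated=validated)
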