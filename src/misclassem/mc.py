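"""Monte-Carlo evaluation harness: replicate generation, estimator
application, and bias/RMSE summarization.

Replicate r of an experiment draws its cohort with seed ``base_seed + r``,
so disjoint replicate ranges are independent and their summaries pool
exactly. Replicates whose estimator raises or returns a non-finite value
are excluded from bias/RMSE; replicates whose EM merely exhausts its
iteration budget keep their (stable, slowly-converging) estimate in the
summary. Both kinds are counted in ``n_failed``, and a summary with more
than 20% such replicates is flagged unreliable. Dropping slow-converging
replicates instead would selectively censor the hardest cohorts and
understate the error of a misspecified model.

For Gaussian outcomes the estimand is the ATE (truth: the generating
treatment coefficient); for Bernoulli outcomes it is the log marginal odds
ratio (truth: computed from the generative model by standardizing both
potential-outcome risks over a large simulated covariate draw).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .effects import METHODS, naive_estimate, oracle_estimate, proposed_estimate
from .models import ModelSpec, NNConfig
from .simdata import ScenarioConfig, gen_covariates, generate_scenario, sens_spec_to_alpha

__all__ = [
    "ExperimentConfig",
    "MethodSummary",
    "MCSummary",
    "true_marginal_log_or",
    "run_replicates",
    "sens_spec_grid",
    "run_validation_experiment",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """One Monte-Carlo experiment: a scenario template, the estimators to
    compare, and the replicate budget."""

    scenario: ScenarioConfig
    methods: tuple = ("naive", "oracle", "proposed_glm")
    n_reps: int = 200
    base_seed: int = 0
    spec: Optional[ModelSpec] = None
    em_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; expected one of {METHODS}")

    def model_spec(self) -> ModelSpec:
        if self.spec is not None:
            return self.spec
        return ModelSpec(
            outcome_family=self.scenario.outcome_family,
            nn_config=NNConfig(seed=self.base_seed),
        )


@dataclass
class MethodSummary:
    method: str
    estimates: np.ndarray  # finite estimates (incl. slow-converging EM runs)
    truth: float
    n_failed: int  # exceptions, non-finite values, and non-converged EMs

    @property
    def bias(self) -> float:
        return float(np.mean(self.estimates - self.truth))

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean((self.estimates - self.truth) ** 2)))

    @property
    def variance(self) -> float:
        return float(np.mean((self.estimates - np.mean(self.estimates)) ** 2))


@dataclass
class MCSummary:
    truth: float
    n: int
    n_reps: int
    per_method: dict

    @property
    def unreliable(self) -> bool:
        return any(m.n_failed > 0.2 * self.n_reps for m in self.per_method.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": m.method,
                "bias": m.bias,
                "rmse": m.rmse,
                "n_failed": m.n_failed,
                "truth": m.truth,
                "n": self.n,
                "n_reps": self.n_reps,
            }
            for m in self.per_method.values()
        ]
        return pd.DataFrame(rows)

    @staticmethod
    def pool(a: "MCSummary", b: "MCSummary") -> "MCSummary":
        """Pool two summaries over disjoint replicate ranges."""
        if a.truth != b.truth or a.n != b.n:
            raise ValueError("summaries are not poolable")
        merged = {}
        for k in a.per_method:
            ma, mb = a.per_method[k], b.per_method[k]
            merged[k] = MethodSummary(
                method=k,
                estimates=np.concatenate([ma.estimates, mb.estimates]),
                truth=ma.truth,
                n_failed=ma.n_failed + mb.n_failed,
            )
        return MCSummary(a.truth, a.n, a.n_reps + b.n_reps, merged)


def true_marginal_log_or(scenario: ScenarioConfig, n: int = 1_000_000, seed: int = 0) -> float:
    """Log marginal causal odds ratio implied by a Bernoulli-outcome
    generative model: standardize both potential-outcome risks over a large
    covariate draw and form the odds ratio."""
    X = gen_covariates(n, scenario.rho, seed)
    gamma = np.asarray(scenario.outcome_gamma)
    lin = scenario.outcome_gamma0 + X @ gamma
    r1 = float(np.mean(expit(lin + scenario.outcome_psi)))
    r0 = float(np.mean(expit(lin)))
    return float(np.log((r1 / (1 - r1)) / (r0 / (1 - r0))))


def estimand_truth(scenario: ScenarioConfig, seed: int = 0) -> float:
    """True value of the summarized estimand for a generative scenario."""
    if scenario.outcome_family == "gaussian":
        return float(scenario.outcome_psi)
    return true_marginal_log_or(scenario, seed=seed)


def _apply_method(cohort, spec: ModelSpec, method: str, em_kwargs: dict):
    """Returns (estimate-on-summary-scale, succeeded)."""
    if method == "naive":
        return naive_estimate(cohort, spec).log_value, True
    if method == "oracle":
        return oracle_estimate(cohort, spec).log_value, True
    backend = method.split("_")[1]
    mspec = replace(spec, me_backend=backend)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est, state = proposed_estimate(cohort, mspec, method_tag=method, **em_kwargs)
    return est.log_value, bool(state.converged)


def run_replicates(config: ExperimentConfig) -> MCSummary:
    """Generate ``n_reps`` cohorts, apply every estimator, and summarize
    bias and RMSE against the scenario's true estimand."""
    spec = config.model_spec()
    truth = estimand_truth(config.scenario, seed=config.base_seed)
    collected: dict[str, list] = {m: [] for m in config.methods}
    failed = {m: 0 for m in config.methods}
    for r in range(config.n_reps):
        scen = replace(config.scenario, seed=config.base_seed + r)
        cohort = generate_scenario(scen)
        for m in config.methods:
            try:
                value, ok = _apply_method(cohort, spec, m, config.em_kwargs)
            except Exception:
                failed[m] += 1
                continue
            if np.isfinite(value):
                collected[m].append(value)
                if not ok:
                    failed[m] += 1
            else:
                failed[m] += 1
    per_method = {
        m: MethodSummary(
            method=m,
            estimates=np.asarray(collected[m]),
            truth=truth,
            n_failed=failed[m],
        )
        for m in config.methods
    }
    summary = MCSummary(truth, config.scenario.n, config.n_reps, per_method)
    if summary.unreliable:
        warnings.warn("more than 20% of replicates failed: summary unreliable")
    return summary


def sens_spec_grid(
    config: ExperimentConfig,
    sens_grid: Sequence[float] = (0.55, 0.65, 0.75, 0.85, 0.95),
    spec_grid: Sequence[float] = (0.55, 0.65, 0.75, 0.85, 0.95),
) -> pd.DataFrame:
    """Sweep the generating sensitivity/specificity of the covariate-free
    misclassification model and summarize every estimator at each grid
    point. Returns a long-format table (sens, spec, method, bias, rmse,
    n_failed)."""
    rows = []
    for sens in sens_grid:
        for spc in spec_grid:
            a0, a1 = sens_spec_to_alpha(sens, spc)
            scen = replace(
                config.scenario,
                me_alpha0=a0,
                me_alpha1=a1,
                me_eta=(0.0,) * len(config.scenario.me_eta),
                me_nonlinear=False,
            )
            summary = run_replicates(replace(config, scenario=scen))
            for m, ms in summary.per_method.items():
                rows.append(
                    {
                        "sens": sens,
                        "spec": spc,
                        "method": m,
                        "bias": ms.bias,
                        "rmse": ms.rmse,
                        "n_failed": ms.n_failed,
                    }
                )
    return pd.DataFrame(rows)


def run_validation_experiment(
    config: ExperimentConfig, fractions: Sequence[float] = (0.2, 0.4)
) -> dict[float, MCSummary]:
    """Re-run the experiment with an internal validation subsample of each
    given fraction, so the validation-data estimator can be compared with
    the latent-variable ones on identical cohorts."""
    out = {}
    for f in fractions:
        scen = replace(config.scenario, validation_fraction=f)
        out[f] = run_replicates(replace(config, scenario=scen))
    return out
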