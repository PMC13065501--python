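"""Correct the misclassification with the latent-variable EM.

Fits the joint outcome x measurement-error x propensity model by EM on a
single Scenario-1 cohort and compares the g-computed ATE with the Naive
(label-as-is) and Oracle (true-label) references.
"""

import warnings

import misclassem as me

warnings.simplefilter("ignore")

cohort = me.generate_scenario(me.scenario_config("S1", n=1000, seed=3))
spec = me.ModelSpec()  # gaussian outcome, glm error model, all covariates

naive = me.naive_estimate(cohort, spec)
oracle = me.oracle_estimate(cohort, spec)
em_est, state = me.proposed_estimate(cohort, spec)

print(f"true ATE              : 2.000")
print(f"naive ATE             : {naive.value:.3f}   (ignores the misclassification)")
print(f"oracle ATE            : {oracle.value:.3f}   (uses the true labels)")
print(f"EM-corrected ATE      : {em_est.value:.3f}")
print()
print(f"EM iterations         : {state.n_iter} (converged: {state.converged})")
print(f"final log-likelihood  : {state.loglik_trace[-1]:.2f}")
a0, a1 = state.theta.me.alpha0, state.theta.me.alpha1
print(f"fitted error model    : alpha0 = {a0:.3f}, alpha1 = {a1:.3f}")
print()
print("The naive estimate collapses toward zero; the EM recovers the")
print("effect to within sampling error of the oracle, and its fitted")
print("error-model coefficients sit near the generating (-1.386, 2.773).")
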