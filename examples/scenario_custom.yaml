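# Example configuration for `misclassem simulate/fit/mc --config ...`
# Field names mirror ScenarioConfig / ModelSpec.
scenario:
  scenario_id: custom
  n: 1000
  outcome_family: gaussian
  rho: 0.3
  sigma2: 1.0
  me_alpha0: -1.4          # logit(1 - specificity) at the covariate mean
  me_alpha1: 2.8           # logit(sens) - logit(1 - spec)
  me_eta: [-0.4, 0.0, 0.4, 0.0, -0.4]
  ps_beta0: 0.0
  ps_beta: [-2.0, 3.0, 1.0, 0.5, 0.5]
  outcome_gamma0: 1.0
  outcome_psi: 2.0         # the true ATE
  outcome_gamma: [-0.8, 0.8, -0.8, 0.8, -0.8]
  validation_fraction: 0.0
  seed: 1

model:
  me_backend: glm          # glm | nn | vd
  outcome_family: gaussian
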