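# Methods

## Model and estimand

Each subject carries an outcome `Y` (Gaussian or Bernoulli), covariates
`X`, a latent true binary treatment `T`, and an observed surrogate label
`Tobs`. Identification rests on the usual counterfactual assumptions
(exchangeability given `X`, consistency, positivity, SUTVA) plus
*non-differential misclassification*: `Y ⟂ Tobs | (T, X)` — once the true
treatment and confounders are known, the error-laden label carries no
further information about the outcome. Under these assumptions the
marginal effect is identified by g-computation over the outcome model,
standardizing over the analysis cohort's empirical covariate distribution
(all n subjects; no reweighting to an external population).

Estimands: for a continuous outcome with identity link the ATE equals the
treatment coefficient ψ, and `estimate_ate` returns ψ directly rather
than recomputing the average of per-subject differences (they are equal
by linearity; returning ψ keeps the identity exact in floating point).
For a binary outcome the marginal causal odds ratio is formed from the
two standardized risks. Monte-Carlo summaries for binary designs are on
the log-OR scale; the conditional log-OR of 2 used in the binary
benchmark implies a marginal log-OR near 1.5 (non-collapsibility), which
the harness computes from the generative model by standardizing both
potential-outcome risks over a 10⁶-subject covariate draw rather than
taking the conditional coefficient as the truth.

## Likelihood and EM

The observed-data log-likelihood drops the parameter-free covariate
density and sums, per subject, the log of a two-term mixture (t = 0, 1) of
the outcome density, the measurement-error probability, and the
propensity. All evaluation is in log space with log-sum-exp; posteriors
are computed as `expit(l₁ − l₀)` and clipped to `[1e−10, 1 − 1e−10]` so
M-step weights stay strictly positive.

The M-step uses the two-row expansion: subject i contributes a `t=1` row
with weight ξᵢ and a `t=0` row with weight 1 − ξᵢ, making the expected
complete-data log-likelihood an ordinary weighted GLM (or network)
log-likelihood for each component separately. The Gaussian variance
update is the closed-form maximizer σ̂² = Σ w·(y − μ̂)²/Σ w.

Initialization: M1 and M3 are fit with `Tobs` standing in for `T`; M2
starts from an assumed sensitivity/specificity of the surrogate via
`α₀ = logit(1 − spec)`, `α₁ = logit(sens) − α₀`, with covariate
coefficients zero. Both initial values must exceed 0.5: the likelihood is
invariant to swapping the latent labels (mirroring all three models), and
starting above 0.5 selects the orientation in which the surrogate is
positively informative. A post-fit guard (`align_labels`) flips the
posteriors and reruns one M-step if a run nevertheless lands in the
mirror mode (implied sensitivity + specificity < 1 averaged over the
cohort). Default initialization is (0.8, 0.8); results are insensitive to
this choice away from the 0.5 boundary.

Convergence is declared when the maximum absolute parameter change falls
below `tol` (default 1e−6, 500 iterations maximum), or when the posterior
vector is exactly stationary (sup-norm < 1e−12, which happens when a
separated error model saturates all posteriors at the clip bounds). A
relative log-likelihood criterion is available but disabled by default:
EM trajectories routinely cross long likelihood plateaus — likelihood
gains below 1e−8 per iteration while parameters are still far from the
maximizer — so stopping on likelihood change truncates exactly the slow,
hard fits. Non-convergence returns a flagged state with a warning, never
an exception.

Separation: intermediate weightings can make a weighted logistic fit
separable. The IRLS solver uses damped Newton steps with objective-based
step halving (monotone on the concave penalized log-likelihood, hence
convergent from any start, including the antipodal starts the
label-orientation repair produces), carries a minute ridge (1e−11) so
separated fits are finite and deterministic, warns when coefficients
pass 15, and — for the measurement-error and propensity models, once a
previous update was already separated — retains the previous parameters
rather than chasing the flat ridge, since any point on it saturates the
same predicted probabilities. A separated surrogate model is the
expected behavior when `Tobs` is error-free; in that limit the EM
reduces to the oracle analysis.

## The neural measurement-error backend

The network maps `(t, X₂)` (features standardized by their weighted
moments, `t` appended as an input rather than training one network per
arm) through one ReLU hidden layer to a sigmoid output. Training
minimizes weighted binary cross-entropy plus an L2 penalty ("decay") with
L-BFGS on the full batch; with a few dozen parameters this is fast and
deterministic given the initialization seed. Hidden-layer size (1–3) and
decay (0, 0.001, 0.01, 0.05, 0.1) are chosen by 3-fold cross-validation
on the weighted rows, minimizing held-out weighted cross-entropy; tuning
happens once per EM run, on the weights implied by the initial
parameters, and the chosen point is held fixed while each M-step
warm-starts the previous network (capped at 40 L-BFGS iterations — a
conditional-improvement, generalized-EM step, so the monotone-ascent
guarantee is documented for the glm backend only).

Two stabilizers address the rougher likelihood surface this backend
induces; both were adopted after plain EM was observed to land in a
collapsed-latent-class mode — mean posterior far below the treated
fraction, a separated propensity fit propping it up, tens of nats below
the dominant mode — on an appreciable fraction of nonlinear-mechanism
cohorts:

1. **Deterministic annealing** of the E-step: posteriors are tempered as
   `expit((l₁ − l₀)/temperature)`, starting at temperature 4 and cooling
   by 0.85 per iteration to 1. Flattening early posteriors prevents the
   flexible error model from locking in a degenerate labeling before the
   outcome and propensity models have taken shape. The parametric
   backends use standard EM (temperature 1) — their results, including
   the deliberately misspecified linear error model in the nonlinear
   scenario, are produced by the plain procedure.
2. **Adaptive multi-start**: up to three full EM runs, keeping the state
   with the highest final observed log-likelihood (inferior modes sit
   tens of nats below the dominant one, so likelihood selection is
   unambiguous). The first two starts use independently cross-validated
   hyperparameters with distinct folds and network seeds; if both
   converge to the same mode (final log-likelihoods within a few nats)
   the search stops, otherwise a third start fixes the hidden layer at
   the top of the grid with the best decay seen so far — the CV
   criterion, held-out surrogate prediction under the rough initial
   weights, occasionally under-selects capacity that the joint
   likelihood clearly supports.

The label-orientation guard deserves one more note for this backend: a
run can converge into the *mirror* of the dominant mode (labels swapped,
likelihood equal by symmetry). For the glm backend the repair is an exact
reparameterization; a network cannot be mirrored in parameter space, so
the guard flips the posteriors, retrains the network from scratch on
them, lets the EM re-converge (at most 50 iterations), and keeps the
result only if the observed log-likelihood is preserved to within a few
nats (the two orientations of a genuine mirror differ only by training
noise; a flip that loses more did not land in the mirror and is rolled
back, as is a repair that re-converges to a still-mirrored state). The
detection statistic is the median per-subject conditional log-odds shift
of the surrogate, logit P(Tobs=1|T=1,x) − logit P(Tobs=1|T=0,x) — equal
to α₁ for the logistic backend, exactly antisymmetric under the label
swap, and, unlike the mean or marginal sensitivity + specificity,
insensitive to the network's extrapolation in covariate regions where
one arm has no effective data.

## Validation-data backend

When a random subsample has `T` recorded, the logistic error model is fit
once on the validated rows (`Tobs ~ T + X₂`) and frozen; the M-step never
updates it, and validated subjects' posteriors are pinned to their known
labels throughout (known labels are data, not latent variables). The
remaining subjects are handled by the ordinary E-step.

## Synthetic data

The generator emulates the benchmark designs: X₁–X₃ jointly Gaussian with
mean 0, unit variance and AR1(0.3) correlation; X₄, X₅ independent
Bernoulli(0.5), uncorrelated with the Gaussian block; logistic treatment
assignment `logit P(T=1|X) = −2X₁ + 3X₂ + X₃ + 0.5X₄ + 0.5X₅` (no
intercept in generation; estimation always fits one); misclassification
`logit P(Tobs=1|T,X) = −1.4 + 2.8T + g(X)` with `g` zero (Scenario 1),
weak or strong linear in (X₁, X₃, X₅) (Scenario 2), or the nonlinear
`−2·exp(X₁/2) + 2·(X₁X₃/25 + 0.6)³ − 2X₅` (Scenario 3 — the exponent
grouping `exp(X₁/2)` was selected because only it reproduces the
benchmark's published naive and misspecified-model error levels; the
alternative reading is a one-line change in `scenario3_predictor`);
outcomes `Y = 1 + 2T − 0.8X₁ + 0.8X₂ − 0.8X₃ + 0.8X₄ − 0.8X₅ + N(0,1)`
or the logit-linear Bernoulli analogue with intercept −1. Scenario 4 is
the strong Scenario-2 design plus a uniformly random validation mask
(20% or 40%).

Each stochastic stage (covariates, treatment, misclassification, outcome,
validation mask) consumes an independent sub-stream derived from the seed
and a stage tag, so designs differing only downstream (e.g. weak vs
strong misclassification) share identical upstream draws at the same
seed. Everything is a pure function of (config, seed).

What the generator does **not** emulate: covariate measurement error,
differential misclassification (error depending on Y), unmeasured
confounding, non-logistic treatment assignment, missing data, or
time-varying treatment. Passing tests therefore demonstrate correctness
of the estimator under the stated assumptions, not robustness to their
violation. An `generate_rhc_like` fixture provides a purely synthetic
high-dimensional (p = 33) stress cohort shaped loosely like an ICU
observational study; it reproduces no published analysis.

## Monte-Carlo harness

Replicate r draws its cohort with seed `base_seed + r`; summaries over
disjoint replicate ranges pool exactly. Bias and RMSE are computed
against the true estimand (ψ = 2, or the standardized marginal log-OR for
binary designs). Replicates whose estimator raises or returns a
non-finite value are excluded; replicates whose EM merely exhausts the
iteration budget keep their estimate — on hard or misspecified fits the
estimate is stable long before the 1e−6 parameter criterion is met, and
dropping those replicates would selectively censor the hardest cohorts
and understate a misspecified model's error. Both kinds are counted in
`n_failed`, and a summary with more than 20% such replicates is flagged
unreliable.

Default problem sizes: 200 replicates for glm-only experiments and 100
where the neural backend is involved, at cohort sizes n = 200–1000; the
sensitivity/specificity sweep uses a 5×5 grid over {0.55, …, 0.95}. These
desk-scale defaults put every experiment within minutes on one CPU while
keeping Monte-Carlo standard errors a few times smaller than the effects
being compared; `--reps-scale` on the acceptance script scales them up.

## Known limitations

- No standard errors or confidence intervals: the package reports point
  estimates and Monte-Carlo summaries only (Louis/supplemented-EM
  variance estimation is out of scope).
- The neural backend's M-step is a conditional improvement, so likelihood
  ascent is not guaranteed (in practice the selected runs are monotone to
  within numerical slack after the annealing phase).
- Identifiability of the latent model rests on the parametric outcome and
  propensity components; with a surrogate near 50%/50%
  sensitivity/specificity the misclassification is barely informative and
  all correction methods degrade.
- Binary treatments only; multi-level or continuous exposures, gradient
  boosting or other error-model learners are not implemented.
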