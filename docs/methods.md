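# Methods

## Data model

A *task* is one disease's right-censored cohort: follow-up time in years
(strictly positive; day-scale inputs are converted at 365.25 d/yr), a 0/1
event indicator (1 = the disease occurred during follow-up), and a feature
matrix whose columns follow a registry shared by all tasks. Rows with missing
required values are rejected with a per-row report rather than imputed —
complete-case analysis is assumed throughout. Continuous features are
standardized to mean 0, sd 1 using the sample standard deviation (n−1
denominator, the convention of mainstream statistics stacks); binary features
pass through untouched; zero-variance features are centered only, with a
warning. Standardization is pooled across tasks by default (the cohorts
describe one population), with a per-task scope available; the center/scale
are stored so new subjects receive the identical affine transform.

## Partial likelihood

Per task, the negative log partial likelihood, its gradient and its Hessian
use the Breslow approximation for tied event times: all events at one time
reuse the full risk-set denominator. This is the tie rule under which the
textbook gradient/Hessian formulas remain exactly valid, and it is what the
implementation's finite-difference and reference-library checks assume
(scikit-survival with Breslow ties agrees to ~1e-11; lifelines, which uses
Efron ties, agrees only on tie-free data). Risk-set sums are accumulated as
reverse cumulative sums over time-sorted subjects, so one evaluation costs
O(N·P); log denominators use a running log-sum-exp
(`logaddexp.accumulate`), so arbitrarily large linear predictors cannot
overflow. Degenerate inputs: a task with zero events has no partial
likelihood and is rejected.

The baseline cumulative hazard is the Breslow estimator — the canonical
partner of the partial likelihood (with β = 0 and no ties it reduces exactly
to Nelson–Aalen). Absolute risk uses the cumulative-hazard transform
AR = 1 − exp(−H₀(t)·exp(xᵀβ)), which is exact under proportional hazards; a
horizon beyond the last observed time returns the risk at the last step with
a warning.

## The multitask estimator

The objective is Σₖ NLLₖ(βₖ)/Nₖ + λ‖B‖₂,₁. Normalization is by subjects per
task (events-normalization is exposed as an option; with heterogeneous
censoring the two weight tasks differently, and subject-count weighting keeps
each cohort's contribution proportional to its size). The L2,1 penalty is
row-separable, and its proximal operator has the closed form
row ← row·max(0, 1 − τ/‖row‖₂); the implementation is verified against
gradient-based numerical minimization of the prox objective (function-value
minimizers bottom out near √ε ≈ 1.5e-8 and cannot certify tighter agreement).

The solver is accelerated proximal gradient:

* **Momentum.** q₀ = 1, qⱼ = (1 + √(1+4qⱼ₋₁²))/2, search point
  S = B + ((qⱼ₋₁−1)/qⱼ)(B − Bprev).
* **Line search.** The inverse step γ (a local Lipschitz estimate, γ₀ = 1)
  is doubled until the quadratic majorization
  L(Bnew) ≤ L(S) + ⟨∇L(S), Bnew−S⟩ + (γ/2)‖Bnew−S‖²_F holds; γ is carried
  forward between iterations.
* **Monotone-descent guard.** Plain accelerated steps are not monotone; if an
  extrapolated step would increase the objective, the step is retaken from
  the current iterate without extrapolation and the momentum restarts, so the
  recorded objective history is nonincreasing.
* **Stopping.** Relative objective change < 1e-6 or relative coefficient
  change < 1e-5, capped at 5,000 iterations; non-convergence is flagged on
  the result, not raised. B⁽⁰⁾ = 0 — deterministic and consistent with the
  λ_max stationarity property.
* **Fixed-step mode.** For convergence-rate checks the solver also runs
  without acceleration at a fixed γ; `lipschitz_bound` supplies a
  conservative valid inverse step (each event's Hessian term is a weighted
  covariate covariance whose spectral norm is at most the squared largest
  covariate row norm), under which the O(1/j) suboptimality envelope holds.

λ_max = maxₚ ‖row p of ∇L(0)‖₂ is the smallest penalty at which B = 0 is
stationary. The search grid is geometric with 50 points from 1·λ_max down to
0.01 of the first point — the three path controls and their defaults
(50, 0.01, 1).

**Penalty selection.** 5-fold cross-validation, event-stratified so every
fold of every task keeps events (events and censored subjects are shuffled
separately and dealt round-robin). The score is the concordance index of the
linear predictor on the held-out fold, averaged over tasks; the default rule
takes the argmax with exact ties resolved toward the larger (sparser) λ.
Because the C-index is rank-invariant, the CV curve is nearly flat in λ
wherever shrinkage preserves the risk ordering; a `one_se` rule (largest λ
within one standard error of the best) is provided as the conservative
variant — it collapses to the null model on pure-noise features, at the cost
of slightly weaker small-sample prediction.

**Debiasing refit.** Any λ large enough to recover the support also shrinks
the surviving rows toward zero, so penalized coefficient values carry a
systematic downward bias that no CV choice removes (the flat C-index curve
cannot distinguish shrinkage levels). `refit_on_support` therefore provides
the relaxed estimator: keep the penalized support, refit each task's Cox
model without penalty on those features (tasks decouple once the penalty is
gone). Support decisions come from the penalized fit; coefficient values, and
everything downstream that consumes them, can use the refit.

## Baselines

* **Newton Cox** — damped Newton–Raphson on the Breslow-tie NLL with
  step-halving, a 1e-8 ridge jitter for near-singular Hessians, and a
  coefficient cap at |β| = 10 with a warning as the monotone-likelihood
  (separation) flag.
* **Cox-LASSO** — the Lagrangian form NLL/N + penalty·‖β‖₁, solved by the
  K = 1 reduction of the multitask solver (the row prox collapses to scalar
  soft-thresholding); equivalent to the constrained form along the path. Its
  penalty is selected by the same grid-plus-CV protocol as the multitask
  model, for comparability.
* **Weibull PH** — h(t|x) = ν·ρ·t^{ν−1}·exp(θᵀx), maximum likelihood over
  (log ν, log ρ, θ) by BFGS with analytic gradients; the log parameterization
  keeps positivity unconstrained. θ carries log-hazard-ratio meaning,
  directly comparable with Cox coefficients.

## Personalized risk layer

All quantities live in tidy subject × disease × horizon tables, horizons
defaulting to 1/3/5/7 years. Basis risk is the mean absolute risk of the
subject's age group (default bins 40–49, 50–59, 60–69, ≥70; half-open
intervals, ages outside all bins labeled "other"); RAR = AR/basis,
EAR = AR − basis (also reported in percentage points). When a bin's basis
risk is exactly zero, RAR is reported as undefined (NaN), not infinity. By
construction, within every bin the mean RAR is exactly 1 and the mean EAR
exactly 0 — a useful internal consistency check.

Risk strata cut the absolute-risk distribution at the 0.33/0.50/0.66
quantiles (linear interpolation between order statistics, the "type 7"
convention), by default within each disease × age group × horizon cell, with
a pooled-ages mode. Labels: AR ≤ low bound → low (boundary inclusive
downward), AR ≥ high bound → high, otherwise average; when the bounds
coincide (degenerate distribution) records satisfying both rules are labeled
average. Disease ranking orders each subject's diseases by absolute risk
descending, ties broken alphabetically so the ranking is deterministic.

## Evaluation

* **C-index.** Comparable pairs: i has an event and timeᵢ < timeⱼ; censored-
  first and equal-time pairs carry no ordering information and are skipped;
  tied scores count ½. The score is the linear predictor (absolute risk at a
  fixed horizon gives identical ranks within a task).
* **Horizon binarization.** Positive = event by the horizon; negative =
  followed past it; censored before the horizon without an event = excluded,
  because the horizon label is unknown — treating such subjects as negatives
  would contaminate the labels. Inverse-probability-of-censoring weighting is
  out of scope.
* **AUC / cutoff.** Mann–Whitney rank formulation (identical to trapezoidal
  ROC integration); the operating cutoff maximizes Youden's index
  (sensitivity + specificity − 1) over observed thresholds.
* **Method comparison.** Two-sided paired Wilcoxon signed-rank test on
  disease × fold cells; zero differences dropped, exact null distribution for
  small samples, normal approximation with continuity correction otherwise.
  All-zero differences are reported as p = 1 with a flag.

## Experiment pipeline

One event-stratified outer split (5 folds) is shared by every method, so the
Wilcoxon pairing is valid; penalty selection for the multitask model and the
LASSO is nested inside each training split to avoid selection leakage. The
optional two-stage feature screen (off by default) keeps features with
univariate Cox Wald p below a configurable threshold (default 0.05, flagged
as a choice the protocol leaves open), then forward-selects among survivors
by likelihood-ratio entry tests; the union of per-disease selections feeds
the multitask model. Reports are delimited text written with a fixed float
format, plus a JSON metadata file carrying the seed, a config echo and a
config hash; identical config + seed reproduce every report byte-for-byte.

## Synthetic cohorts

The generator draws K related proportional-hazards cohorts: exchangeable-
correlation Gaussian features (one-factor construction, default ρ = 0.2);
coefficients with a shared sparse row support, alternating signs ±effect
(default 0.8), optional per-task Gaussian jitter as the task-relatedness
knob (0 = identical tasks); event times by inverse transform from a Weibull
baseline (default shape 1.5, scale 0.05 — accelerating hazard, median event
times of a few years on the null subject); administrative-uniform censoring
C ~ U(0, c_max) with c_max calibrated by bisection so the realized censoring
fraction lands within 2 percentage points of the target (default 0.30). An
optional age covariate (uniform 40–80 years, positive effect) exercises the
age-binned risk layer end to end.

What it does *not* emulate: real cohorts' marginal feature distributions,
informative (outcome-dependent) censoring, competing risks, non-proportional
hazards, or measurement error. Passing recovery tests therefore demonstrates
correctness of the estimator under its own assumptions, not robustness to
their violation.

Study scenarios used by the test suite and `scripts/acceptance.py`, chosen as
desk-scale analogues of a large-cohort design: support/value recovery on
K = 3 cohorts of 1,000 subjects, P = 20 with 5 signal rows at ±0.8, 30%
censoring, 10 seeds; multitask-versus-single-task comparison on K = 5 related
cohorts (jitter sd 0.1) with 150 training and 150 held-out subjects per task,
10 seeds; one full pipeline on K = 3 cohorts of 600 subjects with an age
covariate.

## Known limitations

* Breslow ties only; Efron's correction would be more accurate under heavy
  tying and is a possible extension.
* No time-varying covariates, stratified baselines, or competing-risks
  adjustment — diseases are modeled as independent endpoints.
* The Hessian is materialized as an N×P×P intermediate; fine for the feature
  counts this package targets (tens), not for high-dimensional designs.
* Fixed-horizon AUC uses complete-case binarization, which is unbiased only
  when censoring is independent of risk; no IPCW estimator is provided.
* The C-index-based CV curve is flat in λ; users who need aggressive null
  protection should prefer `rule="one_se"`.
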