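# mtlcox

Multitask Cox proportional-hazards models with shared sparse feature
selection, and a personalized absolute-risk layer on top.

## Who this is for

Epidemiologists and biostatisticians who model the incidence of several
related diseases in one cohort — e.g. a panel of chronic diseases followed in
a biobank — from right-censored time-to-event data with a common set of
clinical and demographic covariates. Fitting each disease separately ignores
that related diseases share risk factors; `mtlcox` couples the per-disease
Cox models so they borrow strength from each other and select one shared set
of predictive features.

## The model

For task (disease) *k* with design matrix *X<sub>k</sub>*, the hazard is the
Cox proportional-hazards model *h(t|x) = h₀ₖ(t) exp(xᵀβₖ)*. Stacking the
per-task coefficient vectors into a matrix **B** = [β₁ … β_K] ∈ ℝ^{P×K}, the
estimator minimizes

```
F(B) = Σₖ NLLₖ(βₖ)/Nₖ + λ ‖B‖₂,₁ ,     ‖B‖₂,₁ = Σₚ ‖B[p,·]‖₂
```

where NLLₖ is the negative log partial likelihood (Breslow handling of tied
event times) and the L2,1 norm — the sum of Euclidean norms of the rows of
**B** — zeroes entire rows, i.e. removes a feature from *all* diseases at
once. Optimization is accelerated proximal gradient (FISTA-type momentum,
backtracking line search, closed-form row-wise group soft-thresholding, and a
monotone-descent guard). λ is chosen on a 50-point geometric grid from the
data-derived λ_max down to 0.01·λ_max by 5-fold cross-validated concordance.

Around the estimator the package provides:

* Breslow baseline hazards and absolute risk AR(t|x) = 1 − exp(−H₀(t)eˣᵀᵝ);
* the personalized risk layer: age-group basis risk, relative absolute risk
  RAR = AR/basis, excess absolute risk EAR = AR − basis, 33/50/66% quantile
  risk strata, per-subject disease ranking;
* single-task baselines (Newton Cox, Cox-LASSO, Weibull PH regression);
* censoring-aware evaluation (Harrell's C-index, fixed-horizon ROC AUC,
  sensitivity/specificity/Youden, paired Wilcoxon method comparison);
* a synthetic multitask survival simulator with known shared-support
  coefficients, so every estimator is testable by parameter recovery.

## Worked example

```python
import numpy as np
from mtlcox import (SimulationConfig, generate, select_lambda, fit,
                    recovery_report, MultiTaskCoxModel, risk_table,
                    basis_risk, relative_and_excess)
from mtlcox.mtl_solver import refit_on_support

# three related cohorts, 600 subjects each, 30% censoring, 4 signal features
# (plus an age covariate) out of 13
sim = generate(SimulationConfig(n_tasks=3, n_features=12, support_size=4,
                                n_per_task=600, censoring=0.30,
                                with_age=True, seed=1))

sel = select_lambda(sim.dataset, folds=5, seed=1)     # CV over the λ grid
res = fit(sim.dataset, sel.lam)                       # final multitask fit
print(f"selected lambda: {sel.lam:.4f}")
print(f"nonzero coefficient rows: {int(res.coefficients.support().sum())} / 13")
rep = recovery_report(refit_on_support(sim.dataset, res.coefficients),
                      sim.true_coefficients)
print(f"support F1: {rep['support_f1']:.3f}   RMSE on true support: {rep['rmse_on_support']:.3f}")

model = MultiTaskCoxModel.from_fit(sim.dataset, res)
X = np.vstack([t.features for t in sim.dataset.tasks])
ages, ids = np.concatenate(sim.ages), np.arange(len(X))
risks = risk_table(model, X, ids, horizons=(1, 3, 5, 7))
basis = basis_risk(risks, ages, ids)
prof = relative_and_excess(risks, basis, ages, ids)
row = prof[(prof.subject == 0) & (prof.horizon == 5.0) & (prof.disease == "task0")].iloc[0]
print(f"subject 0, task0, 5-year AR: {row.AR:.4f}  basis: {row.basis_AR:.4f}  "
      f"RAR: {row.RAR:.2f}  EAR: {row.EAR_pct:.2f} pct-pts  age group: {row.age_group}")
```

prints

```
selected lambda: 0.0878
nonzero coefficient rows: 5 / 13
support F1: 1.000   RMSE on true support: 0.077
subject 0, task0, 5-year AR: 0.5075  basis: 0.5369  RAR: 0.95  EAR: -2.94 pct-pts  age group: 60-70
```

The estimator kept exactly the five truly predictive rows (age + the four
signal features), recovered their values to RMSE 0.077 after the debiasing
refit, and the risk layer reads: subject 0's five-year absolute risk for
task0 is 50.8%, which is 0.95× the average risk of 60–70-year-olds in this
cohort — 2.9 percentage points *below* their age group's basis risk.

## Command line

The same pipeline is scriptable from a YAML config:

```sh
mtlcox simulate --config run.yaml      # write synthetic cohorts + truth
mtlcox fit      --config run.yaml      # CV-select λ, fit, save the model
mtlcox compare  --config run.yaml      # full study: CV metrics per method,
                                       # Wilcoxon comparisons, risk reports
```

All outputs are delimited text plus one JSON metadata file, and are byte-for-
byte reproducible from config + seed.

## Documentation

`docs/methods.md` describes the model, the solver, the defaults and their
rationale, what the simulator does and does not emulate, and known
limitations.
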