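# cat2eq5d

Mapping algorithms that predict **EQ-5D-3L health utilities** from the
**COPD Assessment Test (CAT)**, for health-economic analyses of chronic
obstructive pulmonary disease.

The CAT is an eight-item symptom questionnaire (items scored 0–5, total
0–40, higher = worse). It cannot be used directly for quality-adjusted
life-year calculations, which need a preference-based utility anchored at
1 (full health) and 0 (dead). This package implements the crosswalk
families a trial statistician would compare, with Taiwanese coefficient
sets built in:

- **Response mapping (MLR)** — one multinomial logistic model per EQ-5D
  dimension *d* (levels 1/2/3, level 1 reference),

  P(Y_d = k | x) = exp(x'β_dk) / (1 + Σ_{j∈{2,3}} exp(x'β_dj)),  k = 2, 3,

  with covariates x built from the CAT total score (or selected items), age
  and sex. The predicted level per dimension is the probability argmax, and
  the predicted five-dimension state is scored with the Taiwanese
  time-trade-off tariff
  u(s) = 1 − 0.185 − Σ_d δ_d(s_d) − 0.190·1{any s_d = 3}
  (the constant applies only off full health, so u(11111) = 1).
- **Direct OLS** — published linear equations from CAT items or CAT total
  (and age) straight to utility, deliberately unclamped.
- **Two-part ("M6") models** — logistic group expressions classify a visit
  into utility groups (1 / middle / low), then a group-specific equation is
  evaluated. The printed expressions are reproduced literally, including
  their incoherences (documented in `docs/methods.md`).
- **Mean Rank Method (MRM)** — nonparametric rank matching: a CAT total is
  mapped to the utility holding the same mean rank in the training sample.

For refitting on new cohorts with repeated visits per patient, the fitting
module estimates each dimension's multinomial logit by pooled maximum
likelihood (the estimating-equation solution under an independence working
correlation), with **cluster-robust (sandwich) covariance**, joint 2-df Wald
**backward elimination** (α = 0.05) and **QIC** model selection; linear
equations are re-estimated by OLS. A validation module produces
observation-level MAE/RMSE subgroup tables and bubble-chart data, and a
synthetic-cohort generator reproduces the study-scale marginals so every
workflow runs without access to the original (non-public) patient data.

## Worked example

```python
from cat2eq5d import CatResponse, get_builtin, predict_utility_mlr, predict_utility_ols

cat = CatResponse(3, 3, 2, 3, 2, 3, 2, 2)          # CAT total 20
pred = predict_utility_mlr(get_builtin("taiwan_mlr_total"), cat, age=68, sex=0)
print(pred.state.levels(), pred.utility)            # (2, 1, 2, 2, 2)  0.332
print(predict_utility_ols(get_builtin("hoyle_m3"), cat))   # 0.699
```

The response mapping predicts the EQ-5D state (2,1,2,2,2) — some problems
in every dimension except self-care — whose tariff value is 0.332; the
UK four-item linear equation returns 0.699 for the same questionnaire,
illustrating how strongly the algorithm choice matters for sicker patients.

Running `python examples/validate_models.py` trains on 160 synthetic
patients and validates on the rest, printing (among others):

```
model                  N    mean     min     max      MAE     RMSE
taiwan_mlr_total    1199   0.951  -0.153   1.000   0.0673   0.1496
hoyle_m6            1199   0.530   0.221   0.799   0.4207   0.4968
mrm                 1199   0.889   0.165   1.000   0.0694   0.1449
```

— the literal two-part model collapses predictions downward (its "utility
= 1" group is unreachable as printed), while response mapping and the MRM
track observed utilities. The other scripts in `examples/` cover
prediction, simulation, refitting and the MRM table, one capability each.

## Command line

```bash
cat2eq5d --seed 7 simulate --out synth.csv
cat2eq5d predict  --model taiwan_mlr_total --in synth.csv --out pred.csv
cat2eq5d fit      --data synth.csv --dimension mobility --covariates cat_total,age,sex --out mobility.json
cat2eq5d validate --model taiwan_mlr_items --data synth.csv --report report.csv --bubbles bubbles.csv
```

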