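"""Refit the per-dimension multinomial logits and recover known coefficients.

Demonstrates the model-development loop: estimating-equation fits with
cluster-robust inference, backward elimination at alpha = 0.05, and QIC
reporting.  Fitting a three-level logit needs all three levels observed per
dimension, so the data come from the full-severity-range recovery design
(the calibrated clinic-like cohort is too healthy to show level 3 often).
"""

from cat2eq5d import fit_response_mapping, get_builtin
from cat2eq5d.simulate import recovery_design, simulate_from_spec

truth = get_builtin("taiwan_mlr_total")
design = recovery_design(n_patients=1000, n_visits=3, seed=5)
train = simulate_from_spec(truth, design, seed=6)
print(f"fitting on {len(train)} visits from 1000 synthetic patients\n")

spec, fits = fit_response_mapping(train, ["cat_total", "age", "sex"], backward=True)
print(f"{'dimension':20s} {'kept covariates':28s} {'QIC':>9s}  {'CAT slope (L2) est/true':>24s}")
for dim, fit in fits.items():
    kept = ", ".join(fit.covariates[1:]) or "(intercept only)"
    j = fit.covariates.index("cat_total")
    true_b = truth.dimensions[dim].beta2[truth.dimensions[dim].covariates.index("cat_total")]
    flag = "  [quasi-separated]" if fit.separation_flag else ""
    print(f"{dim:20s} {kept:28s} {fit.qic:>9.1f}  {fit.beta2[j]:>10.3f} / {true_b:<.2f}{flag}")

print(
    "\nEach dimension keeps the covariates whose joint 2-df cluster-robust"
    " Wald test stays below 0.05; the CAT-total slope of the level-2 logit"
    " lands on the generating value. Fits marked quasi-separated carry a"
    " coefficient on a likelihood ridge (here the level-3 sex terms, whose"
    " generating values make sex=0 level-3 responses essentially"
    " impossible) -- their point estimates are direction-only."
)
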