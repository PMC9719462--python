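"""Compare mapping algorithms on a held-out synthetic validation cohort.

Reproduces the validation protocol: train on one patient subset, predict the
other, and report observation-level MAE / RMSE plus bubble-chart data.
"""

from cat2eq5d import (
    build_mrm_table,
    bubble_grid,
    get_builtin,
    predict_observations,
    simulate_cohort,
    split_by_patient,
    subgroup_report,
)
from cat2eq5d.simulate import SimParams

cohort = simulate_cohort(SimParams(), seed=23)
train, valid = split_by_patient(cohort, n_train=160, seed=2)

models = {name: get_builtin(name) for name in
          ("taiwan_mlr_total", "taiwan_mlr_items", "hoyle_m3", "hoyle_m6", "lim_total")}
models["mrm"] = build_mrm_table(train).to_spec()

print(f"{'model':18s} {'N':>5s} {'mean':>7s} {'min':>7s} {'max':>7s} {'MAE':>8s} {'RMSE':>8s}")
for name, spec in models.items():
    df = predict_observations(spec, valid)
    full = subgroup_report(df, model=name).row("full")
    print(f"{name:18s} {full.n:>5d} {full.mean_pred:>7.3f} {full.min_pred:>7.3f} "
          f"{full.max_pred:>7.3f} {full.mae:>8.4f} {full.rmse:>8.4f}")

df = predict_observations(models["taiwan_mlr_total"], valid)
grid = bubble_grid(df.pred_utility, df.utility)
on_diag = int(grid.counts.diagonal().sum())
print(f"\nbubble grid (0.05-wide bins): {grid.n} pairs, {on_diag} in diagonal cells")
print(
    "Lower MAE/RMSE is better; the two-part model's large errors show the"
    " downward collapse of its literal group expressions, while the"
    " response mapping and the Mean Rank Method track observed utilities"
    " across the range."
)
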