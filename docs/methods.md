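# Methods

This note documents the statistical content of `cat2eq5d`: the mapping
algorithms, the fitting machinery, the validation conventions, and the
synthetic-cohort generator, together with the numerical and design choices
made where the published material left the construction open.

## Instruments and scale conventions

The CAT has eight items — cough (Q1), phlegm (Q2), chest tightness (Q3),
breathlessness (Q4), activities (Q5), confidence (Q6), sleep (Q7), energy
(Q8) — each scored 0–5; the total ranges 0–40, higher meaning worse
symptoms. The EQ-5D-3L describes health on five dimensions (mobility,
self-care, usual activities, pain/discomfort, anxiety/depression) at levels
1–3. Utilities live on a scale anchored at 1 (full health) and 0 (dead);
states worse than dead are negative.

Sex enters several equations as a bare 0/1 covariate whose coding the
source material never states. CSV input uses a `sex_code` column with the
documented default convention male = 1; any prediction using sex is
sensitive to this coding, so fitting and prediction must share it. (The
synthetic-data generator uses the opposite assignment internally — see
below — precisely because the coding is an open question.)

## Taiwanese tariff

The time-trade-off value set subtracts a constant 0.185 for any departure
from full health, per-dimension level-2/3 decrements (mobility 0.123/0.272,
self-care 0.167/0.276, usual activities 0.085/0.208, pain/discomfort
0.121/0.261, anxiety/depression 0.154/0.282), and 0.190 once if any
dimension is at level 3. Read literally the formula would assign 0.815 to
full health; observed data and the validation tables make clear that
(1,1,1,1,1) scores exactly 1, so the constant applies only off full health.
A `literal=True` flag evaluates the verbatim formula for audit. The value
set spans [−0.674, 1] over the 243 states and is monotone: worsening any
single dimension never raises utility (both verified exhaustively in the
tests). The "any level 3" decrement is applied at most once, reading the
clause as an indicator rather than a count.

## Mapping algorithms

**Response mapping.** Per dimension, a three-level multinomial logit with
level 1 as reference; probabilities are computed in log space with a
max-shift, so even the extreme published coefficient sets (a 104.76 item
slope, a −512.27 intercept) saturate to 0/1 without overflow. The
predicted level is the argmax of (p1, p2, p3); exact ties resolve to the
lowest (healthiest) level — a deterministic, conservative rule. Predicted
states are scored by the tariff, so predictions live on the 243-value grid.

**Direct OLS.** Linear equations evaluated as printed and never clamped to
[0, 1]: the re-estimated variants exceed 1 at low symptom burden (printed
validation maxima of 1.04 and 1.12 confirm the source did not clamp).

**Two-part models.** The printed group expressions are logistic ratios with
a shared slope sum; they are evaluated literally even where they are not
coherent probabilities. Two consequences are worth flagging. First, the
original variant's top ("utility = 1") expression shares its slopes with
the middle expression but has a lower intercept, so it is dominated
everywhere: the top group is unreachable and predictions collapse downward
— visible in validation as a mean prediction near 0.5 on near-healthy
cohorts. Second, the re-estimated variant's middle expression reuses the
top intercept in its denominator, exactly as printed. Selection is by the
maximum expression value with tie precedence top > middle > low. A
`canonical_ordinal=True` option replaces the literal expressions with a
proper cumulative-logit construction (sharing the printed intercepts and
slopes) for sensitivity analysis; it is never the default.

**Mean Rank Method.** Training visits are ranked by CAT total (ties share
the mean of their rank positions). A total with mean rank r among n visits
is matched to the lower-step empirical quantile of the utility sample at
percentile 1 − (r − 0.5)/n, i.e. the order statistic u_(⌈pn⌉). Unseen
totals interpolate linearly between bracketing knots and clamp at the
extremes. The rank-matching concept fixes only the idea, not these details;
quantile type, interpolation and clamping are this package's choices,
isolated behind `MrmTable` so alternatives can be swapped. The construction
is monotone non-increasing by design.

## Fitting clustered repeated measures

Visits cluster within patients. Estimation uses estimating equations with
an **independence working correlation**: the estimating equations then
coincide with the pooled multinomial likelihood score, so point estimates
are pooled MLE — matching the behaviour of standard GEE software under
working independence — and uncertainty comes from the cluster sandwich
V = A⁻¹ B A⁻¹ with A the model-based information and B the outer product
of within-patient score sums. Newton iterations with step halving run to a
gradient norm below 1e−8 (cap 100 iterations); both tolerances are
overridable. A fit whose largest |coefficient| exceeds 50 is flagged as
quasi-separated but not failed, since published coefficient sets of this
kind are themselves of that character; ridge coefficients should be read as
direction-only, and their empirical-sandwich standard errors are
unreliable (with zero observed events in a covariate pattern the empirical
score variance in the ridge direction vanishes rather than diverges).

**Backward elimination** tests each non-intercept covariate jointly across
the two logits (2-df Wald with robust covariance) and repeatedly drops the
largest p-value above α = 0.05, refitting until all survivors are
significant; intercepts are never dropped. Joint 2-df testing (rather than
per-logit 1-df) was chosen because a covariate enters or leaves both logits
together in the published model forms; Wald rather than score/likelihood
ratio because only the robust covariance is meaningful under the
working-independence contract. Simulation places the null-covariate
retention rate at ~5–6% of fits, matching the nominal level.

**QIC** is −2·QL + 2·trace(A·V_R) with QL the pooled multinomial log
likelihood. For independent data under a correct model the penalty reduces
to twice the parameter count (AIC limit, verified by simulation), and
adding a pure-noise covariate raises QIC in the majority of simulated
datasets.

**OLS refitting** of the linear mapping equations delegates to statsmodels.

## Validation conventions

Metrics are observation-level: every visit counts once, so patients with
more visits weigh more, matching validation tables whose N counts
observations. Subgroups: severity stages 1/2/3; observed-utility bands with
lower-inclusive edges and the top band closed above (a value of exactly
0.75 counts in the ≥ 0.75 band); CAT bands 0–10 / 11–20 / 21–30 / 31–40 as
inclusive integer ranges. The bottom utility band is open below rather than
starting at 0 so the bands partition cohorts containing
states-worse-than-dead. Bubble-chart data bins predicted × observed
utilities on [−0.7, 1] in half-open bins (default width 0.05, final bin
closed); rendering is a side effect, all analysis runs off the counts.

## Synthetic cohort generator

No public dataset accompanies the published equations, so the package
ships a generator calibrated once to the study-scale descriptive targets —
323 patients, ~2,327 visits (range 1–16, mean ≈ 7.2), mean CAT ≈ 9.88,
mean utility ≈ 0.917 with ≈ 69.8% of visits at full health, and a
utility–CAT correlation ≈ −0.69 — and frozen.

Construction: patient latent severity b_i ~ N(0,1) with visit-level noise
(within-patient variance share 0.75, optional lognormal skew and mean
shift); each CAT item is an ordinal cut of the visit severity plus
item-specific noise (loading 0.5, thresholds [−0.40, 0.34, 1.08, 2.00,
3.00] common to all items); the EQ-5D state is sampled from the built-in
total-score response mapping at the visit's CAT total, age and sex; the
observed utility is the tariff of the sampled state (measurement
disagreement between the questionnaires is out of scope). Visit counts are
truncated negative binomial on [1, 16] (size 6, mean 7.55 before
truncation) — the real visit-count distribution beyond its range and mean
is unreported, so this default is unverifiable. Stage is cut from the
patient intercept at ±0.74 (≈ 23/54/23% mild/moderate/severe).

Because the EQ-5D side is *generated from* the published coefficients, the
marginals are not independently tunable: demographics and item thresholds
were chosen jointly so that all five targets sit inside their tolerance
bands. Two consequences deserve emphasis. The calibrated demographics
(age 58 ± 10, 95% of patients with sex covariate 0) are calibration
artefacts, not demographic claims — in particular, the large positive sex
coefficients in the published level-3 logits force the dominant group to
the sex baseline for ~70% full health to be attainable, which is itself
evidence about the unstated coding. And the mean utility equilibrates near
0.893, inside but below the centre of its band: reproducing 0.917 exactly
at mean CAT 9.88 would require a flatter utility-given-CAT relationship
than the published model implies.

What passing tests on this cohort do **not** show about real data: the
generator has no exacerbations, dropout, treatment effects, item-level
response styles, or disagreement between CAT and EQ-5D beyond what the
response model carries; a mild clinic population like the calibrated one
yields very few level-3 responses, so refitting three-level logits on the
default cohort can fail for want of a level — the full-range
`recovery_design` exists for estimation studies.

## Known limitations

- Level-3 logit coefficients of the published total-score model imply a
  quasi-separated generating process (the sex = 0 level-3 probability is
  below e⁻¹⁵ across the feasible covariate space); such coefficient pairs
  cannot be recovered by refitting from any design, and empirical-sandwich
  coverage statements about them fail structurally.
- Only an independence working correlation is offered; non-diagonal working
  structures would change neither the point estimates' target nor the
  sandwich's validity but are out of scope.
- No EQ-5D-5L, no non-TTO scoring; alternative 3L value sets plug in via
  `TariffTable`.
- Age is taken at the visit wherever an equation uses age; whether the
  source equations meant age at enrolment is unstated.
- Rows with missing CAT items are rejected rather than imputed; no
  imputation rule is defined anywhere in the source material.
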