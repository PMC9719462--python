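"""Prediction algorithms mapping CAT responses to EQ-5D-3L utilities.

Four families:

* **MLR response mapping** — per-dimension multinomial logits give the
  probabilities of levels 1/2/3; the predicted level is the argmax; the
  tariff turns the predicted five-level state into a utility.  Predictions
  therefore live on the 243-value grid of the tariff.
* **Direct OLS** — a single linear equation straight to utility.  Outputs
  are deliberately not clamped to [0, 1]; published re-estimated equations
  exceed 1 at low symptom burden, and clamping would hide that.
* **Two-part** — logistic group expressions pick a utility group (1, middle,
  low); the group's outcome equation is then evaluated.  The printed group
  expressions are evaluated literally even where they are not coherent
  probabilities (they need not sum to one); selection by maximum is still
  well defined, and a ``canonical_ordinal=True`` option substitutes a proper
  cumulative-logit construction for sensitivity analysis.
* **Mean Rank Method** — nonparametric rank matching: a CAT total is mapped
  to the utility holding the same mean rank in the training sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_data import CAT_ITEMS, CatResponse, Eq5dState, Observation
from .models import (
    DirectOlsSpec,
    LinearEquation,
    MlrResponseSpec,
    MnlDimensionModel,
    MrmSpec,
    TwoPartSpec,
)
from .tariff import DIMENSIONS, TariffTable, utility_from_state


class CovariateError(KeyError):
    """A model asks for a covariate the caller did not supply."""


def _covariate_values(
    cat: CatResponse, age: Optional[float] = None, sex: Optional[int] = None
) -> Dict[str, float]:
    vals: Dict[str, float] = {"intercept": 1.0, "cat_total": float(cat.total)}
    vals.update({name: float(v) for name, v in zip(CAT_ITEMS, cat.items())})
    if age is not None:
        vals["age"] = float(age)
    if sex is not None:
        vals["sex"] = float(sex)
    return vals


def _resolve(names: Iterable[str], vals: Mapping[str, float]) -> np.ndarray:
    out = []
    for n in names:
        if n not in vals:
            raise CovariateError(f"model requires covariate {n!r} but it was not supplied")
        out.append(vals[n])
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# MLR response mapping
# ---------------------------------------------------------------------------


def mnl_probabilities(
    model: MnlDimensionModel,
    x: Union[Mapping[str, float], Sequence[float], np.ndarray],
) -> np.ndarray:
    """Level probabilities (p1, p2, p3) of one EQ-5D dimension.

    ``x`` is either a mapping of covariate name to value (the intercept is
    implicit) or an array whose columns align with ``model.covariates``
    (leading intercept column included).  Accepts a 2-D array of shape
    (n, p) and then returns shape (n, 3).  Computation is shifted into log
    space, so coefficient sets with huge linear predictors (the published
    selected-items pain/discomfort equation has a 104.76 item slope)
    saturate cleanly instead of overflowing.
    """
    if isinstance(x, Mapping):
        X = _resolve(model.covariates, {**x, "intercept": 1.0})[None, :]
        squeeze = True
    else:
        X = np.atleast_2d(np.asarray(x, dtype=float))
        squeeze = X.ndim == 2 and np.asarray(x).ndim == 1
        if X.shape[1] != len(model.covariates):
            raise CovariateError(
                f"expected {len(model.covariates)} columns "
                f"({', '.join(model.covariates)}), got {X.shape[1]}"
            )
    eta = np.column_stack(
        [
            np.zeros(X.shape[0]),
            X @ np.asarray(model.beta2),
            X @ np.asarray(model.beta3),
        ]
    )
    eta -= eta.max(axis=1, keepdims=True)  # log-sum-exp shift
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def predict_state_mlr(
    spec: MlrResponseSpec,
    cat: CatResponse,
    age: Optional[float] = None,
    sex: Optional[int] = None,
) -> Eq5dState:
    """Predicted EQ-5D-3L state: per-dimension argmax of the level
    probabilities; exact ties resolve to the lowest (healthiest) level."""
    vals = _covariate_values(cat, age, sex)
    levels = {}
    for dim in DIMENSIONS:
        p = mnl_probabilities(spec.dimensions[dim], vals)
        levels[dim] = int(np.argmax(p)) + 1  # argmax takes the first max
    return Eq5dState(**levels)


@dataclass(frozen=True)
class MlrPrediction:
    utility: float
    state: Eq5dState


def predict_utility_mlr(
    spec: MlrResponseSpec,
    cat: CatResponse,
    age: Optional[float] = None,
    sex: Optional[int] = None,
    tariff: Optional[TariffTable] = None,
) -> MlrPrediction:
    """Response-mapping utility: predicted state pushed through the tariff."""
    state = predict_state_mlr(spec, cat, age, sex)
    return MlrPrediction(utility=utility_from_state(state, tariff), state=state)


# ---------------------------------------------------------------------------
# Direct OLS
# ---------------------------------------------------------------------------


def evaluate_linear(eq: LinearEquation, vals: Mapping[str, float]) -> float:
    out = eq.intercept
    for name, slope in eq.slopes.items():
        if name not in vals:
            raise CovariateError(f"equation requires covariate {name!r}")
        out += slope * vals[name]
    return out


def predict_utility_ols(
    model: DirectOlsSpec, cat: CatResponse, age: Optional[float] = None
) -> float:
    """Linear-equation utility; not clamped to [0, 1]."""
    return evaluate_linear(model.equation, _covariate_values(cat, age))


# ---------------------------------------------------------------------------
# Two-part ("M6"-style) models
# ---------------------------------------------------------------------------

TWO_PART_GROUPS = ("top", "mid", "low")


def two_part_group_values(
    model: TwoPartSpec, cat: CatResponse, canonical_ordinal: bool = False
) -> Tuple[float, float, float]:
    """The three group expressions (top, middle, low), evaluated as printed.

    ``canonical_ordinal=True`` replaces the literal expressions with a proper
    cumulative-logit construction sharing the printed slopes and intercepts:
    P(top) = expit(a_top + s), P(top or mid) = expit(a_mid + s).
    """
    vals = _covariate_values(cat)
    s = sum(slope * vals[name] for name, slope in model.slopes.items())
    if canonical_ordinal:
        from scipy.special import expit

        p_top = float(expit(model.intercept_top + s))
        p_top_or_mid = float(expit(model.intercept_mid + s))
        p_mid = max(p_top_or_mid - p_top, 0.0)
        return p_top, p_mid, 1.0 - p_top - p_mid
    # literal logistic ratios; overflow-safe via log space
    p_top = float(np.exp((model.intercept_top + s) - np.logaddexp(0.0, model.denom_intercept_top + s)))
    p_mid = float(np.exp((model.intercept_mid + s) - np.logaddexp(0.0, model.denom_intercept_mid + s)))
    return p_top, p_mid, 1.0 - p_top - p_mid


def two_part_outcome(model: TwoPartSpec, group: str, cat: CatResponse) -> float:
    """The outcome equation of one utility group, evaluated directly."""
    vals = _covariate_values(cat)
    if group == "top":
        return model.outcome_top
    if group == "mid":
        return evaluate_linear(model.outcome_mid, vals)
    if group == "low":
        return evaluate_linear(model.outcome_low, vals)
    raise ValueError(f"unknown group {group!r}; expected one of {TWO_PART_GROUPS}")


def predict_utility_two_part(
    model: TwoPartSpec, cat: CatResponse, canonical_ordinal: bool = False
) -> float:
    """Two-part prediction: the maximal group expression picks the group
    (precedence top > middle > low on exact ties), whose outcome equation
    gives the utility."""
    p = two_part_group_values(model, cat, canonical_ordinal)
    group = TWO_PART_GROUPS[int(np.argmax(p))]
    return two_part_outcome(model, group, cat)


# ---------------------------------------------------------------------------
# Mean Rank Method
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MrmTable:
    """Trained rank-matching table.

    ``cat_totals`` are the distinct training totals (ascending) and
    ``knot_utilities`` the utilities holding the same mean rank in the
    training utility sample; unseen totals interpolate linearly between
    bracketing knots and clamp at the extremes.
    """

    cat_totals: np.ndarray
    mean_ranks: np.ndarray
    knot_utilities: np.ndarray
    utilities: np.ndarray  # sorted training sample
    n: int

    def to_spec(self, name: str = "mrm", note: str = "") -> MrmSpec:
        return MrmSpec(
            name=name,
            note=note,
            cat_totals=[float(v) for v in self.cat_totals],
            knot_utilities=[float(v) for v in self.knot_utilities],
            n=self.n,
        )


def build_mrm_table(train: Sequence[Observation]) -> MrmTable:
    """Train the Mean Rank Method on observations with observed utilities.

    CAT totals are ranked ascending (ties share the mean of their rank
    positions); a total with mean rank r among n observations matches the
    lower-step empirical quantile of the utility sample at percentile
    ``1 - (r - 0.5) / n`` — higher totals (worse symptoms) match lower
    utilities, so the table is monotone non-increasing.
    """
    totals = np.array([o.cat.total for o in train], dtype=float)
    utils = np.array(
        [o.utility for o in train if o.utility is not None], dtype=float
    )
    if totals.size == 0:
        raise ValueError("cannot train the Mean Rank Method on an empty sample")
    if utils.size != totals.size:
        raise ValueError("every training observation needs an observed utility")
    n = totals.size
    ranks = rankdata(totals, method="average")
    u_sorted = np.sort(utils)
    knots_x, first = np.unique(totals, return_index=True)
    knots_u = []
    mean_ranks = []
    for x in knots_x:
        r = float(ranks[totals == x][0])  # tied totals share one mean rank
        p = 1.0 - (r - 0.5) / n
        k = min(max(int(np.ceil(p * n)), 1), n)  # lower-step quantile
        mean_ranks.append(r)
        knots_u.append(u_sorted[k - 1])
    return MrmTable(
        cat_totals=knots_x,
        mean_ranks=np.asarray(mean_ranks),
        knot_utilities=np.asarray(knots_u),
        utilities=u_sorted,
        n=n,
    )


def predict_utility_mrm(table: Union[MrmTable, MrmSpec], cat_total: float) -> float:
    """Mean-rank utility for a CAT total: exact knots return their mapped
    value, gaps interpolate linearly, totals past the extremes clamp."""
    if not (0 <= cat_total <= 40):
        raise ValueError(f"CAT total {cat_total} outside [0, 40]")
    xs = np.asarray(table.cat_totals, dtype=float)
    us = np.asarray(table.knot_utilities, dtype=float)
    return float(np.interp(cat_total, xs, us))


# ---------------------------------------------------------------------------
# Frame-level dispatch
# ---------------------------------------------------------------------------


def predict_observations(spec, obs: Sequence[Observation], tariff=None) -> pd.DataFrame:
    """Run any mapping model over observations; returns the observation table
    with ``pred_utility`` (and, for response mapping, ``pred_mo`` .. ``pred_ad``)
    and ``model`` columns appended."""
    from .core_data import observations_to_frame

    df = observations_to_frame(obs)
    kind = spec.kind if hasattr(spec, "kind") else "mrm"
    if kind == "mlr_response":
        preds = [predict_utility_mlr(spec, o.cat, o.age, o.sex, tariff) for o in obs]
        df["pred_utility"] = [p.utility for p in preds]
        for col, dim in zip(("pred_mo", "pred_sc", "pred_ua", "pred_pd", "pred_ad"), DIMENSIONS):
            df[col] = [getattr(p.state, dim) for p in preds]
    elif kind == "direct_ols":
        df["pred_utility"] = [predict_utility_ols(spec, o.cat, o.age) for o in obs]
    elif kind == "two_part":
        df["pred_utility"] = [predict_utility_two_part(spec, o.cat) for o in obs]
    elif kind == "mrm":
        df["pred_utility"] = [predict_utility_mrm(spec, o.cat.total) for o in obs]
    else:  # pragma: no cover
        raise ValueError(f"unknown model kind {kind!r}")
    df["model"] = getattr(spec, "name", kind)
    return df
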