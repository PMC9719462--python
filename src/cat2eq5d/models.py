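"""Mapping-model specifications: schema, JSON (de)serialization, built-ins.

A :data:`ModelSpec` is a tagged union over the four mapping-algorithm
families used to crosswalk CAT scores to EQ-5D-3L utilities:

``mlr_response``
    Response mapping — one multinomial logistic model per EQ-5D dimension
    (level 1 as reference) followed by the tariff transformation.
``direct_ols``
    A single linear equation from CAT items / CAT total (and optionally age)
    straight to utility.
``two_part``
    Classify a visit into a utility group (1, middle, low) by the maximum of
    three printed group expressions, then apply the group's outcome equation.
``mrm``
    Mean Rank Method — a trained nonparametric rank-matching table.

Built-in specs carry published coefficient sets: the Taiwanese response
mapping (total-score and selected-items variants), the UK CAT→EQ-5D OLS and
two-part equations of the "M3"/"M6" family, the Korean linear equations, and
the Taiwanese re-estimated ("modified") versions of each.  Coefficients are
frozen as printed; the MRM has no frozen parameters and is trained from data
(see :func:`cat2eq5d.mappers.build_mrm_table`).
"""

from __future__ import annotations

import json
from typing import Annotated, Dict, List, Literal, Optional, Union

from pydantic import BaseModel, Field, model_validator

from .tariff import DIMENSIONS

SPEC_SCHEMA_VERSION = 1


class MnlDimensionModel(BaseModel):
    """Level-2 and level-3 logit coefficients for one EQ-5D dimension.

    ``covariates`` starts with ``"intercept"``; ``beta2`` / ``beta3`` are the
    coefficient vectors of the level-2 and level-3 logits in the same order.
    """

    covariates: List[str]
    beta2: List[float]
    beta3: List[float]

    @model_validator(mode="after")
    def _check(self) -> "MnlDimensionModel":
        if not self.covariates or self.covariates[0] != "intercept":
            raise ValueError("covariates must start with 'intercept'")
        if len(self.beta2) != len(self.covariates) or len(self.beta3) != len(
            self.covariates
        ):
            raise ValueError("beta2/beta3 must match the covariate list length")
        return self


class MlrResponseSpec(BaseModel):
    kind: Literal["mlr_response"] = "mlr_response"
    name: str = "mlr_response"
    note: str = ""
    schema_version: int = SPEC_SCHEMA_VERSION
    dimensions: Dict[str, MnlDimensionModel]

    @model_validator(mode="after")
    def _check(self) -> "MlrResponseSpec":
        missing = [d for d in DIMENSIONS if d not in self.dimensions]
        if missing:
            raise ValueError(
                f"mlr_response spec missing dimension model(s): {', '.join(missing)}"
            )
        return self


class LinearEquation(BaseModel):
    """``intercept + sum(slopes[name] * value[name])`` over named covariates."""

    intercept: float
    slopes: Dict[str, float] = Field(default_factory=dict)


class DirectOlsSpec(BaseModel):
    kind: Literal["direct_ols"] = "direct_ols"
    name: str = "direct_ols"
    note: str = ""
    schema_version: int = SPEC_SCHEMA_VERSION
    #: slopes may be empty only for the degenerate intercept-only refit
    equation: LinearEquation


class TwoPartSpec(BaseModel):
    """Two-part ("M6"-style) classifier + per-group outcome equations.

    The three group expressions are evaluated literally as printed: the top
    and middle expressions are logistic ratios ``exp(a + s) / (1 + exp(d +
    s))`` with a shared slope sum ``s`` and possibly mismatched numerator /
    denominator intercepts (``denom_intercept_mid`` of the re-estimated
    variant reuses the top intercept, exactly as published); the low
    expression is one minus the other two.  They need not sum to 1 or stay in
    [0, 1] — selection by maximum is still well defined.
    """

    kind: Literal["two_part"] = "two_part"
    name: str = "two_part"
    note: str = ""
    schema_version: int = SPEC_SCHEMA_VERSION
    slopes: Dict[str, float]
    intercept_top: float
    intercept_mid: float
    denom_intercept_top: float
    denom_intercept_mid: float
    outcome_top: float = 1.0
    outcome_mid: LinearEquation
    outcome_low: LinearEquation


class MrmSpec(BaseModel):
    """A trained Mean Rank Method table (see ``mappers.build_mrm_table``)."""

    kind: Literal["mrm"] = "mrm"
    name: str = "mrm"
    note: str = ""
    schema_version: int = SPEC_SCHEMA_VERSION
    cat_totals: List[float]
    knot_utilities: List[float]
    n: int

    @model_validator(mode="after")
    def _check(self) -> "MrmSpec":
        if len(self.cat_totals) != len(self.knot_utilities):
            raise ValueError("cat_totals and knot_utilities must align")
        if sorted(self.cat_totals) != self.cat_totals:
            raise ValueError("cat_totals must be sorted ascending")
        return self


ModelSpec = Annotated[
    Union[MlrResponseSpec, DirectOlsSpec, TwoPartSpec, MrmSpec],
    Field(discriminator="kind"),
]


class _SpecAdapter(BaseModel):
    spec: ModelSpec


def load_model_spec(doc: Union[str, dict]) -> ModelSpec:
    """Parse a model spec from JSON text / dict, or resolve a built-in name."""
    if isinstance(doc, str):
        stripped = doc.strip()
        if not stripped.startswith("{"):
            return get_builtin(stripped)
        doc = json.loads(stripped)
    return _SpecAdapter(spec=doc).spec


def dump_model_spec(spec) -> str:
    """Serialize a ModelSpec to JSON text (inverse of :func:`load_model_spec`)."""
    return spec.model_dump_json(indent=2)


# ---------------------------------------------------------------------------
# Built-in coefficient sets (frozen as published)
# ---------------------------------------------------------------------------


def _mnl(covs, beta2, beta3):
    return MnlDimensionModel(
        covariates=["intercept"] + list(covs), beta2=beta2, beta3=beta3
    )


def _taiwan_mlr_total() -> MlrResponseSpec:
    c = ["cat_total", "age", "sex"]
    return MlrResponseSpec(
        name="taiwan_mlr_total",
        note="Taiwanese response mapping from CAT total score, age and sex",
        dimensions={
            "mobility": _mnl(c, [-13.79, 0.37, 0.10, 0.64], [-43.98, 0.52, 0.27, 10.33]),
            "self_care": _mnl(c, [-14.04, 0.40, 0.06, 3.11], [-35.06, 0.59, 0.13, 13.91]),
            "usual_activities": _mnl(
                c, [-15.37, 0.48, 0.09, 2.04], [-37.84, 0.75, 0.14, 13.42]
            ),
            "pain_discomfort": _mnl(
                c, [-5.61, 0.30, 0.01, -0.84], [-31.06, 0.79, 0.02, 8.77]
            ),
            "anxiety_depression": _mnl(
                c, [-4.07, 0.28, -0.02, -0.41], [-25.77, 1.39, -0.22, 3.75]
            ),
        },
    )


def _taiwan_mlr_items() -> MlrResponseSpec:
    return MlrResponseSpec(
        name="taiwan_mlr_items",
        note="Taiwanese response mapping from backward-selected CAT items",
        dimensions={
            "mobility": _mnl(
                ["q2", "q3", "q4", "q5", "q6", "q8", "age"],
                [-10.89, -0.46, -0.04, 0.60, 0.63, 1.19, 0.39, 0.07],
                [-37.51, -0.92, 1.26, 0.74, 0.47, 1.74, 0.01, 0.31],
            ),
            "self_care": _mnl(
                ["q2", "q5", "q6", "q7", "age", "sex"],
                [-9.21, -0.39, 1.30, 1.11, 0.35, 0.03, 1.98],
                [-29.54, -0.53, 1.80, 1.47, 0.79, 0.09, 12.68],
            ),
            "usual_activities": _mnl(
                ["q3", "q4", "q5", "q6", "q7", "age", "sex"],
                [-11.90, 0.28, 0.43, 1.08, 1.52, 0.25, 0.06, 0.98],
                [-33.79, 0.53, 0.37, 2.37, 1.68, 0.57, 0.11, 11.41],
            ),
            "pain_discomfort": _mnl(
                ["q1", "q3", "q4", "q6", "q8", "age", "sex"],
                [-3.29, 0.03, 0.39, -0.02, 0.96, 0.72, -0.01, -1.15],
                [-512.27, 37.26, -6.14, 104.76, 12.01, 19.15, -2.05, -30.83],
            ),
            "anxiety_depression": _mnl(
                ["q2", "q3", "q5", "q6", "q7", "age"],
                [-2.78, -0.34, 0.59, 0.31, 0.64, 0.59, -0.03],
                [-216.48, -4.28, 17.46, 7.08, 27.76, 28.40, -0.86],
            ),
        },
    )


def _hoyle_m3() -> DirectOlsSpec:
    return DirectOlsSpec(
        name="hoyle_m3",
        note="UK four-item OLS equation (chest tightness, activities, confidence, energy)",
        equation=LinearEquation(
            intercept=0.9831816,
            slopes={"q8": -0.0220703, "q6": -0.0418119, "q5": -0.0312604, "q3": -0.0260971},
        ),
    )


def _hoyle_m3_mod() -> DirectOlsSpec:
    return DirectOlsSpec(
        name="hoyle_m3_mod",
        note="four-item OLS equation re-estimated on the Taiwanese cohort",
        equation=LinearEquation(
            intercept=1.03670,
            slopes={"q8": -0.01273, "q6": -0.06367, "q5": -0.03794, "q3": -0.01211},
        ),
    )


_M6_SLOPES = {
    "q3": 0.2536439,
    "q4": 0.1635303,
    "q5": 0.4407377,
    "q6": 0.3709118,
    "q7": 0.088462,
    "q8": 0.186294,
}

_M6_MOD_SLOPES = {
    "q3": 0.2622,
    "q4": 0.3884,
    "q5": 0.8401,
    "q6": 1.0693,
    "q7": 0.1832,
    "q8": 0.1565,
}


def _hoyle_m6() -> TwoPartSpec:
    return TwoPartSpec(
        name="hoyle_m6",
        note="UK two-part mapping: classify into utility groups then regress",
        slopes=_M6_SLOPES,
        intercept_top=-7.1242,
        intercept_mid=-1.4836,
        denom_intercept_top=-7.1242,
        denom_intercept_mid=-1.4836,
        outcome_mid=LinearEquation(
            intercept=0.8150928,
            slopes={"q3": -0.0114207, "q5": -0.0102185, "q6": -0.0270919, "q8": -0.0053779},
        ),
        outcome_low=LinearEquation(intercept=0.3183917, slopes={"cat_total": -0.00752}),
    )


def _hoyle_m6_mod() -> TwoPartSpec:
    # The published middle-group expression reuses the top intercept in its
    # denominator; evaluated literally on purpose.
    return TwoPartSpec(
        name="hoyle_m6_mod",
        note="two-part mapping re-estimated on the Taiwanese cohort (literal form)",
        slopes=_M6_MOD_SLOPES,
        intercept_top=-10.9642,
        intercept_mid=-4.6737,
        denom_intercept_top=-10.9642,
        denom_intercept_mid=-10.9642,
        outcome_mid=LinearEquation(
            intercept=0.92209,
            slopes={"q3": -0.01266, "q5": -0.01911, "q6": -0.03696, "q8": -0.02121},
        ),
        outcome_low=LinearEquation(intercept=0.53984, slopes={"cat_total": -0.01008}),
    )


def _lim_total() -> DirectOlsSpec:
    return DirectOlsSpec(
        name="lim_total",
        note="Korean linear equation from CAT total score and age",
        equation=LinearEquation(
            intercept=1.1376, slopes={"cat_total": -0.0103, "age": -0.0020}
        ),
    )


def _lim_items() -> DirectOlsSpec:
    return DirectOlsSpec(
        name="lim_items",
        note="Korean linear equation from five CAT items",
        equation=LinearEquation(
            intercept=1.0661,
            slopes={"q3": -0.0103, "q4": -0.0120, "q5": -0.0168, "q6": -0.0255, "q8": -0.0125},
        ),
    )


def _lim_total_mod() -> DirectOlsSpec:
    return DirectOlsSpec(
        name="lim_total_mod",
        note="total-score linear equation re-estimated on the Taiwanese cohort",
        equation=LinearEquation(
            intercept=1.26848, slopes={"cat_total": -0.02159, "age": -0.00188}
        ),
    )


def _lim_items_mod() -> DirectOlsSpec:
    return DirectOlsSpec(
        name="lim_items_mod",
        note="five-item linear equation re-estimated on the Taiwanese cohort",
        equation=LinearEquation(
            intercept=1.05245,
            slopes={"q3": -0.01137, "q4": -0.00810, "q5": -0.03702, "q6": -0.05993, "q8": -0.01286},
        ),
    )


_BUILTIN_FACTORIES = {
    "taiwan_mlr_total": _taiwan_mlr_total,
    "taiwan_mlr_items": _taiwan_mlr_items,
    "hoyle_m3": _hoyle_m3,
    "hoyle_m6": _hoyle_m6,
    "hoyle_m3_mod": _hoyle_m3_mod,
    "hoyle_m6_mod": _hoyle_m6_mod,
    "lim_total": _lim_total,
    "lim_items": _lim_items,
    "lim_total_mod": _lim_total_mod,
    "lim_items_mod": _lim_items_mod,
}

#: all registry names, including the data-trained Mean Rank Method
BUILTIN_NAMES = tuple(_BUILTIN_FACTORIES) + ("mrm",)


def get_builtin(name: str) -> ModelSpec:
    """Return the built-in spec registered under ``name``."""
    if name == "mrm":
        raise ValueError(
            "the Mean Rank Method has no frozen coefficients; train it with "
            "cat2eq5d.mappers.build_mrm_table and serialize the result"
        )
    try:
        return _BUILTIN_FACTORIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; built-ins: {', '.join(BUILTIN_NAMES)}"
        ) from None
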