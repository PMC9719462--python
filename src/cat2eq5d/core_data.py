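"""Domain types and long-format table I/O for repeated CAT / EQ-5D-3L data.

One row = one clinic visit.  The CAT (COPD Assessment Test) has eight items
scored 0-5 (total 0-40, higher = worse); the EQ-5D-3L state and its tariff
utility are optional, as is an airflow-severity stage (1 = mild, 2 =
moderate, 3 = severe, the last merging FEV1 < 50%).

Sex is stored as a 0/1 code in column ``sex_code``.  The default coding is
male = 1, female = 0; predictions that use sex are sensitive to this coding
because the source models never state it, so keep the coding consistent
between fitting and prediction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tariff import DIMENSIONS, TariffTable, utility_from_state

CAT_ITEMS = ("q1", "q2", "q3", "q4", "q5", "q6", "q7", "q8")

#: item index -> everyday name, in CAT order
CAT_ITEM_LABELS = {
    "q1": "cough",
    "q2": "phlegm",
    "q3": "chest tightness",
    "q4": "breathlessness",
    "q5": "activities",
    "q6": "confidence",
    "q7": "sleep",
    "q8": "energy",
}

EQ5D_COLUMNS = ("mo", "sc", "ua", "pd", "ad")

REQUIRED_COLUMNS = ("patient_id", "visit", "age", "sex_code") + CAT_ITEMS
OPTIONAL_COLUMNS = EQ5D_COLUMNS + ("utility", "stage")


class DataFormatError(ValueError):
    """A table is structurally unusable (missing required columns)."""


class ValidationError(ValueError):
    """A row holds an out-of-range or inconsistent value."""


@dataclass(frozen=True)
class CatResponse:
    """One completed CAT questionnaire: eight items, each 0-5."""

    q1: int
    q2: int
    q3: int
    q4: int
    q5: int
    q6: int
    q7: int
    q8: int

    def __post_init__(self):
        for name in CAT_ITEMS:
            v = getattr(self, name)
            if not (0 <= v <= 5):
                raise ValidationError(
                    f"CAT item {name} = {v} outside the allowed range [0, 5]"
                )

    @property
    def total(self) -> int:
        return sum(getattr(self, name) for name in CAT_ITEMS)

    def items(self) -> Tuple[int, ...]:
        return tuple(getattr(self, name) for name in CAT_ITEMS)


@dataclass(frozen=True)
class Eq5dState:
    """An EQ-5D-3L health state: five dimensions, each at level 1, 2 or 3."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self):
        for dim in DIMENSIONS:
            lv = getattr(self, dim)
            if lv not in (1, 2, 3):
                raise ValidationError(
                    f"EQ-5D dimension {dim} = {lv}; levels must be 1, 2 or 3"
                )

    def levels(self) -> Tuple[int, int, int, int, int]:
        return tuple(getattr(self, dim) for dim in DIMENSIONS)


@dataclass
class Observation:
    """One clinic visit of one patient."""

    patient_id: str
    visit: int
    age: float
    sex: int
    cat: CatResponse
    eq5d: Optional[Eq5dState] = None
    utility: Optional[float] = None
    stage: Optional[int] = None

    def __post_init__(self):
        if self.visit < 1:
            raise ValidationError(f"visit must be >= 1, got {self.visit}")
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        if self.sex not in (0, 1):
            raise ValidationError(f"sex code must be 0 or 1, got {self.sex}")
        if self.stage is not None and self.stage not in (1, 2, 3):
            raise ValidationError(f"stage must be 1, 2 or 3, got {self.stage}")


def read_observations(
    source, tariff: TariffTable | None = None, check_utility: bool = True
) -> List[Observation]:
    """Read a long-format observation table (CSV text, path or file object).

    Required columns: patient_id, visit, age, sex_code, q1..q8.  Optional:
    mo, sc, ua, pd, ad (EQ-5D levels), utility, stage.  When both an EQ-5D
    state and a utility are present the utility must agree with the tariff
    of the state to 1e-9 (``check_utility=False`` disables the check).
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source)
    return observations_from_frame(df, tariff=tariff, check_utility=check_utility)


def observations_from_frame(
    df: pd.DataFrame, tariff: TariffTable | None = None, check_utility: bool = True
) -> List[Observation]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing required column(s): {', '.join(missing)}")

    have_eq5d = all(c in df.columns for c in EQ5D_COLUMNS)
    out: List[Observation] = []
    for idx, row in df.iterrows():
        try:
            cat = CatResponse(*(int(row[c]) for c in CAT_ITEMS))
        except ValidationError as e:
            raise ValidationError(f"row {idx}: {e}") from None
        eq5d = None
        if have_eq5d and not any(pd.isna(row[c]) for c in EQ5D_COLUMNS):
            try:
                eq5d = Eq5dState(*(int(row[c]) for c in EQ5D_COLUMNS))
            except ValidationError as e:
                raise ValidationError(f"row {idx}: {e}") from None
        utility = None
        if "utility" in df.columns and not pd.isna(row["utility"]):
            utility = float(row["utility"])
        stage = None
        if "stage" in df.columns and not pd.isna(row["stage"]):
            stage = int(row["stage"])
        try:
            obs = Observation(
                patient_id=str(row["patient_id"]),
                visit=int(row["visit"]),
                age=float(row["age"]),
                sex=int(row["sex_code"]),
                cat=cat,
                eq5d=eq5d,
                utility=utility,
                stage=stage,
            )
        except ValidationError as e:
            raise ValidationError(f"row {idx}: {e}") from None
        if check_utility and utility is not None and eq5d is not None:
            expected = utility_from_state(eq5d, tariff)
            if abs(utility - expected) > 1e-9:
                raise ValidationError(
                    f"row {idx}: utility {utility} does not match the tariff value "
                    f"{expected:.6f} of state {eq5d.levels()}"
                )
        out.append(obs)
    return out


def observations_to_frame(obs: Iterable[Observation]) -> pd.DataFrame:
    rows = []
    for o in obs:
        row = {
            "patient_id": o.patient_id,
            "visit": o.visit,
            "age": o.age,
            "sex_code": o.sex,
        }
        row.update({c: v for c, v in zip(CAT_ITEMS, o.cat.items())})
        row["cat_total"] = o.cat.total
        if o.eq5d is not None:
            row.update({c: v for c, v in zip(EQ5D_COLUMNS, o.eq5d.levels())})
        if o.utility is not None:
            row["utility"] = o.utility
        if o.stage is not None:
            row["stage"] = o.stage
        rows.append(row)
    return pd.DataFrame(rows)


def write_observations(obs: Sequence[Observation], path_or_buf) -> None:
    """Write observations back to CSV (inverse of :func:`read_observations`)."""
    observations_to_frame(obs).to_csv(path_or_buf, index=False)


def split_by_patient(
    obs: Sequence[Observation], n_train: int, seed: int
) -> Tuple[List[Observation], List[Observation]]:
    """Randomly partition *patients* into a training and a validation group.

    All visits of a patient land on the same side; the partition is a
    deterministic function of ``seed``.  The study design this mirrors is a
    160 / 163 patient split of a 323-patient cohort.
    """
    patients = sorted({o.patient_id for o in obs})
    if n_train > len(patients):
        raise ValueError(
            f"n_train = {n_train} exceeds the number of distinct patients "
            f"({len(patients)})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    train_ids = {patients[i] for i in order[:n_train]}
    train = [o for o in obs if o.patient_id in train_ids]
    valid = [o for o in obs if o.patient_id not in train_ids]
    return train, valid
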