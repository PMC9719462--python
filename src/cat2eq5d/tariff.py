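"""Taiwanese EQ-5D-3L time-trade-off value set.

The EQ-5D-3L describes health as five dimensions (mobility, self-care, usual
activities, pain/discomfort, anxiety/depression), each at level 1 (no
problems), 2 (some problems) or 3 (extreme problems).  A country-specific
tariff converts a state to a utility anchored at 1 (full health) and 0
(dead); states worse than dead get negative utilities.

The built-in table is the Taiwanese time-trade-off tariff: a fixed decrement
applied to any departure from full health, per-dimension decrements for
levels 2 and 3, and an extra "N3" decrement if any dimension is at level 3.
Alternative value sets can be supplied as ``TariffTable`` instances.
"""

from __future__ import annotations

from itertools import product
from typing import TYPE_CHECKING, Dict, Tuple

from pydantic import BaseModel, model_validator

if TYPE_CHECKING:  # pragma: no cover
    from .core_data import Eq5dState

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)


class TariffTable(BaseModel):
    """Value-set constants for a 3-level EQ-5D tariff.

    ``constant`` is subtracted once for any state other than full health,
    ``dec2[d]`` / ``dec3[d]`` for dimension ``d`` at level 2 / 3, and ``n3``
    once if at least one dimension is at level 3.
    """

    name: str = "custom"
    constant: float
    dec2: Dict[str, float]
    dec3: Dict[str, float]
    n3: float

    @model_validator(mode="after")
    def _check(self) -> "TariffTable":
        for d in DIMENSIONS:
            if d not in self.dec2 or d not in self.dec3:
                raise ValueError(f"tariff missing decrements for dimension {d!r}")
            if self.dec2[d] < 0 or self.dec3[d] < self.dec2[d]:
                raise ValueError(
                    f"dimension {d!r}: need 0 <= level-2 decrement <= level-3 decrement"
                )
        if self.constant < 0 or self.n3 < 0:
            raise ValueError("constant and n3 decrements must be non-negative")
        return self


def taiwan_tariff() -> TariffTable:
    """The Taiwanese EQ-5D-3L time-trade-off value set."""
    return TariffTable(
        name="taiwan_tto",
        constant=0.185,
        dec2={
            "mobility": 0.123,
            "self_care": 0.167,
            "usual_activities": 0.085,
            "pain_discomfort": 0.121,
            "anxiety_depression": 0.154,
        },
        dec3={
            "mobility": 0.272,
            "self_care": 0.276,
            "usual_activities": 0.208,
            "pain_discomfort": 0.261,
            "anxiety_depression": 0.282,
        },
        n3=0.190,
    )


def utility_from_state(
    state: "Eq5dState | Tuple[int, int, int, int, int]",
    tariff: TariffTable | None = None,
    *,
    literal: bool = False,
) -> float:
    """Utility of an EQ-5D-3L state under a tariff.

    Full health (1,1,1,1,1) scores exactly 1.0: the fixed decrement applies
    only once the state departs from full health.  ``literal=True`` instead
    evaluates the decrement formula verbatim (constant always subtracted),
    for auditing the printed form of the scoring equation.
    """
    if tariff is None:
        tariff = taiwan_tariff()
    levels = _levels(state)
    for lv in levels:
        if lv not in (1, 2, 3):
            raise ValueError(f"EQ-5D levels must be 1, 2 or 3; got {lv}")
    if not literal and all(lv == 1 for lv in levels):
        return 1.0
    u = 1.0 - tariff.constant
    for dim, lv in zip(DIMENSIONS, levels):
        if lv == 2:
            u -= tariff.dec2[dim]
        elif lv == 3:
            u -= tariff.dec3[dim]
    if any(lv == 3 for lv in levels):
        u -= tariff.n3  # applied once, however many dimensions are at level 3
    return u


def all_states() -> list[Tuple[int, int, int, int, int]]:
    """All 243 EQ-5D-3L states in lexicographic order."""
    return list(product((1, 2, 3), repeat=5))


def tariff_value_set(tariff: TariffTable | None = None) -> Dict[Tuple[int, ...], float]:
    """Map every EQ-5D-3L state to its utility (243 entries)."""
    return {s: utility_from_state(s, tariff) for s in all_states()}


def _levels(state) -> Tuple[int, int, int, int, int]:
    if hasattr(state, "levels"):
        return tuple(state.levels())
    return tuple(state)
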