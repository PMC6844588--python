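"""State space and ADL/IADL disability classification.

The model distinguishes four states: no disability (0), mild disability (1),
severe disability (2) and death (3).  Severity is graded from ten activity
items: five basic activities of daily living (BADL) and five instrumental
activities of daily living (IADL).  Needing help with any BADL item defines
severe disability; intact BADLs but needing help with any IADL item defines
mild disability; full independence on all ten items defines no disability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

NO_DISABILITY: int = 0
MILD: int = 1
SEVERE: int = 2
DEATH: int = 3

LIVING_STATES: Tuple[int, ...] = (NO_DISABILITY, MILD, SEVERE)
ALL_STATES: Tuple[int, ...] = (NO_DISABILITY, MILD, SEVERE, DEATH)
N_STATES: int = 4
ABSORBING_STATES: Tuple[int, ...] = (DEATH,)

STATE_LABELS = {
    NO_DISABILITY: "no disability",
    MILD: "mild disability",
    SEVERE: "severe disability",
    DEATH: "death",
}

BADL_ITEMS: Tuple[str, ...] = (
    "bathing",
    "dressing",
    "eating",
    "toileting",
    "indoor_transferring",
)
IADL_ITEMS: Tuple[str, ...] = (
    "visiting_neighbors",
    "shopping",
    "washing_clothes",
    "preparing_meals",
    "public_transportation",
)


class ClassificationUndefinedError(ValueError):
    """Raised when disability cannot be graded because an item is missing."""


def _check_items(values: Sequence[Optional[bool]], kind: str) -> None:
    if len(values) != 5:
        raise ValueError(f"expected exactly 5 {kind} items, got {len(values)}")
    for v in values:
        if v is not None and not isinstance(v, (bool,)):
            raise ValueError(f"{kind} item must be bool or None, got {v!r}")


@dataclass(frozen=True)
class DisabilityItems:
    """One wave's ten activity answers.

    Each entry is ``True`` if the person needs help with the item, ``False``
    if independent, and ``None`` if the answer is missing.
    """

    badl: Tuple[Optional[bool], ...]
    iadl: Tuple[Optional[bool], ...]

    def __post_init__(self) -> None:
        _check_items(self.badl, "BADL")
        _check_items(self.iadl, "IADL")

    @property
    def any_missing(self) -> bool:
        return any(v is None for v in self.badl + self.iadl)


def classify_disability(items: DisabilityItems) -> int:
    """Grade a complete set of ten activity answers into a living state.

    Returns :data:`SEVERE` if help is needed with any BADL item,
    :data:`MILD` if BADLs are intact but help is needed with any IADL item,
    and :data:`NO_DISABILITY` otherwise.

    Raises
    ------
    ClassificationUndefinedError
        If any of the ten items is missing.  The caller decides whether to
        exclude the wave or impute the item first.
    """
    if items.any_missing:
        missing = [n for n, v in zip(BADL_ITEMS + IADL_ITEMS, items.badl + items.iadl) if v is None]
        raise ClassificationUndefinedError(
            f"cannot classify disability with missing items: {', '.join(missing)}"
        )
    if any(items.badl):
        return SEVERE
    if any(items.iadl):
        return MILD
    return NO_DISABILITY
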