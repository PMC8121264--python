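"""Anatomical position categories within a uterine horn.

Feti are numbered 1..n from the ovarian end. A horn with at least five
feti maps onto five anatomical slots: ovarian end (OE, fetus 1),
next-to-ovarian end (NOE, fetus 2), middle (MD, feti 3..n-2), next-to-
cervical end (NCE, fetus n-1) and cervical end (CE, fetus n). When the
horn carries more than five feti the several middle feti are averaged,
so the analysis unit is always one observation per dam x side x
position.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from statistics import fmean
from typing import Optional

from .records import DamRecord, FetusRecord, HornSide

MIN_HORN_SIZE = 5


class Position(str, Enum):
    """Five-slot intrauterine position scheme, ovary to cervix."""

    OE = "OE"
    NOE = "NOE"
    MD = "MD"
    NCE = "NCE"
    CE = "CE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


POSITION_ORDER = [Position.OE, Position.NOE, Position.MD, Position.NCE, Position.CE]


class HornTooSmallError(ValueError):
    """Raised when a horn with fewer than five feti reaches positional code."""


@dataclass(frozen=True)
class PositionalObservation:
    """One dam x horn-side x position value after middle collapsing.

    ``raw_fetal_weight_g`` (and, when available, ``raw_placental_weight_g``)
    is the single fetus value for the four end slots and the arithmetic
    mean over the middle feti for MD. ``n_feti_in_horn`` is the horn's
    fetus count before collapsing; it feeds the litter-size term of the
    normalized-weight equation.
    """

    dam_id: str
    group_label: str
    horn_side: HornSide
    position: Position
    raw_fetal_weight_g: float
    raw_placental_weight_g: Optional[float]
    n_feti_in_horn: int
    maternal_gd20_weight_g: float


def assign_positions(horn: list[FetusRecord]) -> dict[Position, list[int]]:
    """Partition a horn's fetus indices into the five position slots.

    Returns a map position -> member ``fetus_index`` list; MD receives
    the n - 4 middle indices. Raises :class:`HornTooSmallError` for
    horns under five feti (the inclusion filter must have run first).
    """
    n = len(horn)
    if n < MIN_HORN_SIZE:
        raise HornTooSmallError(
            f"positional mapping needs >= {MIN_HORN_SIZE} feti per horn, got {n}"
        )
    indices = [f.fetus_index for f in horn]
    if indices != list(range(1, n + 1)):
        raise ValueError(f"horn indices must run 1..{n}, got {indices}")
    return {
        Position.OE: [1],
        Position.NOE: [2],
        Position.MD: list(range(3, n - 1)),
        Position.NCE: [n - 1],
        Position.CE: [n],
    }


def collapse_horn(horn: list[FetusRecord], dam: DamRecord) -> list[PositionalObservation]:
    """Collapse one included horn to its five positional observations.

    The MD fetal weight is the mean over the middle feti; the MD
    placental weight is the mean over middle feti whose placenta was
    weighed (missing if none were).
    """
    membership = assign_positions(horn)
    by_index = {f.fetus_index: f for f in horn}
    n = len(horn)
    side = horn[0].horn_side
    out: list[PositionalObservation] = []
    for position in POSITION_ORDER:
        members = [by_index[i] for i in membership[position]]
        fetal = fmean(m.fetal_weight_g for m in members)
        placentas = [m.placental_weight_g for m in members if m.placental_weight_g is not None]
        placental = fmean(placentas) if placentas else None
        out.append(
            PositionalObservation(
                dam_id=dam.dam_id,
                group_label=dam.group_label,
                horn_side=side,
                position=position,
                raw_fetal_weight_g=fetal,
                raw_placental_weight_g=placental,
                n_feti_in_horn=n,
                maternal_gd20_weight_g=dam.maternal_gd20_weight_g,
            )
        )
    return out


def collapse_dataset(dataset) -> list[PositionalObservation]:
    """Collapse every horn of an (already filtered) dataset.

    Horns under five feti are skipped silently here; run the inclusion
    filter first if an audit trail of exclusions is needed.
    """
    obs: list[PositionalObservation] = []
    for dam in dataset.dams:
        for side in (HornSide.LEFT, HornSide.RIGHT):
            horn = dam.horn(side)
            if len(horn) >= MIN_HORN_SIZE:
                obs.extend(collapse_horn(horn, dam))
    return obs
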