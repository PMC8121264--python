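"""Data model for per-fetus necropsy records.

A study is a collection of pregnant dams. Each dam carries two uterine
horns (left and right), and each horn an ordered run of feti numbered
from the ovarian end (fetus 1) toward the cervix. At term (GD 20 in the
rat) every fetus and its placenta are weighed wet, and the dam's body
weight is recorded.

Weights are in grams throughout. Placental weight may be missing for a
fetus (recorded as ``None``); such a fetus is excluded from placental
endpoints only, never from fetal-weight endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class HornSide(str, Enum):
    """Side of the bicornuate uterus."""

    LEFT = "L"
    RIGHT = "R"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SchemaError(ValueError):
    """Input table does not match the documented CSV schema."""


class IntegrityError(ValueError):
    """Structurally inconsistent data (duplicates, index gaps)."""


class ValidationError(ValueError):
    """A field value violates a domain invariant."""


@dataclass(frozen=True)
class FetusRecord:
    """One fetus: its slot within a horn and its wet weights.

    ``fetus_index`` is 1-based counted from the ovarian end, so the
    cervical-end fetus carries the horn's maximum index.
    """

    dam_id: str
    horn_side: HornSide
    fetus_index: int
    fetal_weight_g: float
    placental_weight_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fetus_index < 1:
            raise ValidationError(
                f"fetus_index must be >= 1, got {self.fetus_index} "
                f"(dam {self.dam_id}, horn {self.horn_side.value})"
            )
        if not self.fetal_weight_g > 0:
            raise ValidationError(
                f"fetal_weight_g must be positive, got {self.fetal_weight_g} "
                f"(dam {self.dam_id}, horn {self.horn_side.value}, "
                f"fetus {self.fetus_index})"
            )
        if self.placental_weight_g is not None and not self.placental_weight_g > 0:
            raise ValidationError(
                f"placental_weight_g must be positive when present, got "
                f"{self.placental_weight_g} (dam {self.dam_id}, horn "
                f"{self.horn_side.value}, fetus {self.fetus_index})"
            )


@dataclass
class DamRecord:
    """One pregnant dam: group label, term body weight and two horns.

    ``horns`` maps side to the ordered fetus list; a horn absent from the
    map (or empty) carried no feti. Horn lists must be sorted by
    ``fetus_index`` starting at 1 with no gaps.
    """

    dam_id: str
    group_label: str
    maternal_gd20_weight_g: float
    horns: dict[HornSide, list[FetusRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.maternal_gd20_weight_g > 0:
            raise ValidationError(
                f"maternal_gd20_weight_g must be positive, got "
                f"{self.maternal_gd20_weight_g} (dam {self.dam_id})"
            )
        total_fetal = 0.0
        for side, feti in self.horns.items():
            for i, fetus in enumerate(feti, start=1):
                if fetus.dam_id != self.dam_id or fetus.horn_side != side:
                    raise IntegrityError(
                        f"fetus record filed under wrong dam/horn "
                        f"(dam {self.dam_id}, horn {side.value})"
                    )
                if fetus.fetus_index != i:
                    raise IntegrityError(
                        f"fetus indices in horn must run 1..n without gaps; "
                        f"expected {i}, got {fetus.fetus_index} "
                        f"(dam {self.dam_id}, horn {side.value})"
                    )
                total_fetal += fetus.fetal_weight_g
        if self.maternal_gd20_weight_g <= total_fetal:
            raise ValidationError(
                f"maternal weight ({self.maternal_gd20_weight_g} g) must exceed "
                f"summed fetal weight ({total_fetal:.3f} g) (dam {self.dam_id})"
            )

    @property
    def litter_size(self) -> int:
        """Total number of feti across both horns."""
        return sum(len(f) for f in self.horns.values())

    def horn(self, side: HornSide) -> list[FetusRecord]:
        return self.horns.get(side, [])

    def all_feti(self) -> list[FetusRecord]:
        out: list[FetusRecord] = []
        for side in (HornSide.LEFT, HornSide.RIGHT):
            out.extend(self.horns.get(side, []))
        return out


@dataclass
class StudyDataset:
    """All dams of one study plus the label of the reference group."""

    dams: list[DamRecord]
    control_label: str = "control"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for dam in self.dams:
            if dam.dam_id in seen:
                raise IntegrityError(f"duplicate dam_id {dam.dam_id!r}")
            seen.add(dam.dam_id)
        if self.dams and self.control_label not in self.group_labels():
            raise ValidationError(
                f"control_label {self.control_label!r} not found among group "
                f"labels {sorted(self.group_labels())}"
            )

    def group_labels(self) -> set[str]:
        return {d.group_label for d in self.dams}

    def exposed_labels(self) -> list[str]:
        """Non-control group labels, sorted for deterministic iteration."""
        return sorted(self.group_labels() - {self.control_label})

    def dams_in_group(self, label: str) -> list[DamRecord]:
        return [d for d in self.dams if d.group_label == label]
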