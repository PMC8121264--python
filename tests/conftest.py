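"""Shared fixtures: tiny hand-built litters and dataset builders."""

from __future__ import annotations

import pytest

from hornwise.records import DamRecord, FetusRecord, HornSide, StudyDataset


def make_horn(dam_id: str, side: str, weights, placentas=None):
    """Ordered fetus list from a weight sequence (index 1 = ovarian end)."""
    side = HornSide(side)
    if placentas is None:
        placentas = [None] * len(weights)
    return [
        FetusRecord(
            dam_id=dam_id,
            horn_side=side,
            fetus_index=i + 1,
            fetal_weight_g=w,
            placental_weight_g=p,
        )
        for i, (w, p) in enumerate(zip(weights, placentas))
    ]


def make_dam(
    dam_id: str,
    group: str = "control",
    maternal: float = 300.0,
    right=(),
    left=(),
    right_placentas=None,
    left_placentas=None,
) -> DamRecord:
    horns = {}
    if len(right):
        horns[HornSide.RIGHT] = make_horn(dam_id, "R", right, right_placentas)
    if len(left):
        horns[HornSide.LEFT] = make_horn(dam_id, "L", left, left_placentas)
    return DamRecord(
        dam_id=dam_id, group_label=group, maternal_gd20_weight_g=maternal, horns=horns
    )


@pytest.fixture
def small_study() -> StudyDataset:
    """Three dams, two groups, with one small horn and one small litter."""
    dams = [
        make_dam("c1", "control", 310.0, right=[2.6, 2.7, 2.5, 2.6, 2.8],
                 left=[2.5, 2.6, 2.4, 2.5, 2.6, 2.7]),
        make_dam("c2", "control", 295.0, right=[2.7, 2.6, 2.8, 2.6, 2.5, 2.6],
                 left=[2.4, 2.5]),  # small left horn
        make_dam("x1", "dosed", 305.0, right=[2.0, 2.1, 1.9, 2.0, 2.2],
                 left=[2.3, 2.2, 2.4, 2.3, 2.2]),
    ]
    return StudyDataset(dams=dams, control_label="control")
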