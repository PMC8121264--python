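"""Read and write the flat per-fetus study table.

The on-disk format is a UTF-8 RFC-4180 CSV with one row per fetus and
columns::

    dam_id, group_label, maternal_gd20_weight_g, horn_side,
    fetus_index, fetal_weight_g, placental_weight_g

``horn_side`` is ``L`` or ``R``; ``fetus_index`` is 1-based from the
ovarian end; an empty ``placental_weight_g`` cell means the placenta was
not weighed for that fetus. Maternal weight and group label must be
constant within a dam.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Union

import pandas as pd

from .records import (
    DamRecord,
    FetusRecord,
    HornSide,
    IntegrityError,
    SchemaError,
    StudyDataset,
    ValidationError,
)

COLUMNS = [
    "dam_id",
    "group_label",
    "maternal_gd20_weight_g",
    "horn_side",
    "fetus_index",
    "fetal_weight_g",
    "placental_weight_g",
]


def read_study_table(path: Union[str, Path], control_label: str = "control") -> StudyDataset:
    """Read and validate a per-fetus CSV into a :class:`StudyDataset`.

    Rows are grouped into dams and horns and sorted by
    ``(dam_id, horn_side, fetus_index)``; every domain invariant is
    enforced during construction.

    Raises
    ------
    SchemaError
        If a required column is missing.
    IntegrityError
        On duplicate or gapped fetus indices, or inconsistent per-dam
        metadata.
    ValidationError
        On nonpositive weights (the message carries the offending row).
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"dam_id": str, "group_label": str, "horn_side": str},
        float_precision="round_trip",
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)} in {path}")

    dams: list[DamRecord] = []
    if len(df) == 0:
        return StudyDataset(dams=[], control_label=control_label)

    for col in ("dam_id", "group_label", "horn_side"):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2  # header is line 1
            raise ValidationError(f"empty {col} at line {row} of {path}")

    for dam_id, dam_rows in df.groupby("dam_id", sort=True):
        groups = dam_rows["group_label"].unique()
        if len(groups) != 1:
            raise IntegrityError(
                f"dam {dam_id!r} carries multiple group labels: {sorted(groups)}"
            )
        weights = dam_rows["maternal_gd20_weight_g"].unique()
        if len(weights) != 1:
            raise IntegrityError(
                f"dam {dam_id!r} carries multiple maternal weights: {sorted(weights)}"
            )
        horns: dict[HornSide, list[FetusRecord]] = {}
        for side_str, horn_rows in dam_rows.groupby("horn_side", sort=True):
            try:
                side = HornSide(side_str)
            except ValueError:
                raise SchemaError(
                    f"horn_side must be 'L' or 'R', got {side_str!r} (dam {dam_id!r})"
                ) from None
            horn_rows = horn_rows.sort_values("fetus_index")
            indices = horn_rows["fetus_index"].tolist()
            if len(set(indices)) != len(indices):
                raise IntegrityError(
                    f"duplicate fetus_index in dam {dam_id!r} horn {side.value}"
                )
            if indices != list(range(1, len(indices) + 1)):
                raise IntegrityError(
                    f"fetus_index sequence for dam {dam_id!r} horn {side.value} "
                    f"is {indices}; must run 1..n without gaps"
                )
            feti = []
            for _, row in horn_rows.iterrows():
                pw = row["placental_weight_g"]
                pw = None if (pw is None or (isinstance(pw, float) and math.isnan(pw))) else float(pw)
                try:
                    feti.append(
                        FetusRecord(
                            dam_id=str(dam_id),
                            horn_side=side,
                            fetus_index=int(row["fetus_index"]),
                            fetal_weight_g=float(row["fetal_weight_g"]),
                            placental_weight_g=pw,
                        )
                    )
                except ValidationError as exc:
                    raise ValidationError(f"{exc} [line {int(row.name) + 2} of {path}]") from None
            horns[side] = feti
        dams.append(
            DamRecord(
                dam_id=str(dam_id),
                group_label=str(groups[0]),
                maternal_gd20_weight_g=float(weights[0]),
                horns=horns,
            )
        )
    return StudyDataset(dams=dams, control_label=control_label)


def dataset_to_frame(dataset: StudyDataset) -> pd.DataFrame:
    """Flatten a dataset to the documented tidy per-fetus table."""
    rows = []
    for dam in sorted(dataset.dams, key=lambda d: d.dam_id):
        for side in (HornSide.LEFT, HornSide.RIGHT):
            for fetus in dam.horn(side):
                rows.append(
                    {
                        "dam_id": dam.dam_id,
                        "group_label": dam.group_label,
                        "maternal_gd20_weight_g": dam.maternal_gd20_weight_g,
                        "horn_side": side.value,
                        "fetus_index": fetus.fetus_index,
                        "fetal_weight_g": fetus.fetal_weight_g,
                        "placental_weight_g": fetus.placental_weight_g,
                    }
                )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_study_table(dataset: StudyDataset, path: Union[str, Path]) -> None:
    """Write a dataset as the documented CSV (header-only when empty).

    Floats are written with :func:`repr` precision so that a read/write
    round trip reproduces the parsed values exactly.
    """
    df = dataset_to_frame(dataset)
    df.to_csv(path, index=False, float_format=None)
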