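"""Study endpoints: normalized fetal weight, placental weight, efficiency.

Three endpoints are computed per positional observation:

* ``normalized_fetal_weight`` — fetal weight divided by the per-fetus
  share of maternal body weight, fw / (M / n) = fw * n / M with n the
  number of feti in that horn. This corrects jointly for maternal size
  and horn crowding. Although dimensionally grams-fetal per
  (grams-maternal per fetus), the field reports it simply in "g"
  (typical control values near 0.06); we treat it as unitless.
* ``raw_placental_weight`` — the placental wet weight in grams.
* ``placental_efficiency`` — raw fetal / raw placental weight, a
  dimensionless proxy of placental function (about 5-6 in the near-term
  rat).

The traditional litter-mean summary (dam means, then group mean +/- SEM,
with integer percent decrease vs. control) is also provided; it is the
baseline the positional approach is compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .positions import PositionalObservation
from .records import StudyDataset

ENDPOINTS = ("normalized_fetal_weight", "raw_placental_weight", "placental_efficiency")

TABLE_COLUMNS = [
    "dam_id",
    "group_label",
    "horn_side",
    "position",
    "endpoint",
    "value",
    "n_feti_in_horn",
]


def normalize_fetal_weight(
    fetal_weight_g: float, maternal_gd20_weight_g: float, n_feti_in_horn: int
) -> float:
    """fw / (M / n): fetal weight per gram of maternal weight per fetus."""
    if fetal_weight_g <= 0 or maternal_gd20_weight_g <= 0 or n_feti_in_horn <= 0:
        raise ValueError(
            "normalize_fetal_weight requires positive inputs, got "
            f"fw={fetal_weight_g}, M={maternal_gd20_weight_g}, n={n_feti_in_horn}"
        )
    return fetal_weight_g * n_feti_in_horn / maternal_gd20_weight_g


def placental_efficiency(fetal_weight_g: float, placental_weight_g: float) -> float:
    """Raw fetal weight divided by its own raw placental weight."""
    if fetal_weight_g <= 0 or placental_weight_g <= 0:
        raise ValueError(
            "placental_efficiency requires positive weights, got "
            f"fw={fetal_weight_g}, pw={placental_weight_g}"
        )
    return fetal_weight_g / placental_weight_g


def percent_decrease(control_mean: float, group_mean: float) -> int:
    """Integer percent reduction vs. control, floored at zero.

    Rounds half away from zero; a group mean above control prints 0
    (no negative "decrease").
    """
    if control_mean <= 0:
        raise ValueError(f"control_mean must be positive, got {control_mean}")
    pct = 100.0 * (control_mean - group_mean) / control_mean
    rounded = int(math.floor(pct + 0.5)) if pct >= 0 else -int(math.floor(-pct + 0.5))
    return max(rounded, 0)


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SEM for one group; ``sem`` is NaN when n < 2."""

    group_label: str
    mean: float
    sem: float
    n: int


def _mean_sem(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size >= 2 else float("nan")
    return mean, sem


def traditional_summary(
    dataset: StudyDataset,
) -> tuple[dict[str, GroupSummary], dict[str, float]]:
    """Litter-then-group averaging of raw fetal weight.

    Every fetus of every retained dam contributes to its dam mean
    (litters under five feti should already have been excluded; no horn
    rule applies here). Returns per-group summaries (n = dams) and the
    per-dam means.
    """
    dam_means: dict[str, float] = {}
    by_group: dict[str, list[float]] = {}
    for dam in dataset.dams:
        feti = dam.all_feti()
        if not feti:
            continue
        m = float(np.mean([f.fetal_weight_g for f in feti]))
        dam_means[dam.dam_id] = m
        by_group.setdefault(dam.group_label, []).append(m)
    summaries = {}
    for label in sorted(by_group):
        mean, sem = _mean_sem(by_group[label])
        summaries[label] = GroupSummary(label, mean, sem, len(by_group[label]))
    return summaries, dam_means


def traditional_table(dataset: StudyDataset) -> pd.DataFrame:
    """Table-style traditional block: group mean +/- SEM and % decrease."""
    summaries, _ = traditional_summary(dataset)
    control = summaries.get(dataset.control_label)
    rows = []
    for label, s in summaries.items():
        rows.append(
            {
                "group_label": label,
                "n_dams": s.n,
                "fetal_weight_mean_g": s.mean,
                "fetal_weight_sem_g": s.sem,
                "percent_decrease": (
                    percent_decrease(control.mean, s.mean)
                    if control is not None and label != dataset.control_label
                    else (0 if label == dataset.control_label else None)
                ),
            }
        )
    return pd.DataFrame(rows)


def _endpoint_value(obs: PositionalObservation, endpoint: str) -> Optional[float]:
    if endpoint == "normalized_fetal_weight":
        return normalize_fetal_weight(
            obs.raw_fetal_weight_g, obs.maternal_gd20_weight_g, obs.n_feti_in_horn
        )
    if endpoint == "raw_placental_weight":
        return obs.raw_placental_weight_g
    if endpoint == "placental_efficiency":
        if obs.raw_placental_weight_g is None:
            return None
        return placental_efficiency(obs.raw_fetal_weight_g, obs.raw_placental_weight_g)
    raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")


def compute_endpoint_table(
    observations: list[PositionalObservation], endpoints: tuple[str, ...] = ENDPOINTS
) -> pd.DataFrame:
    """Tidy endpoint table: one row per observation x endpoint.

    Observations missing a placental weight contribute no row to the
    placental endpoints but keep their fetal-weight rows.
    """
    rows = []
    for obs in observations:
        for endpoint in endpoints:
            value = _endpoint_value(obs, endpoint)
            if value is None:
                continue
            rows.append(
                {
                    "dam_id": obs.dam_id,
                    "group_label": obs.group_label,
                    "horn_side": obs.horn_side.value,
                    "position": obs.position.value,
                    "endpoint": endpoint,
                    "value": value,
                    "n_feti_in_horn": obs.n_feti_in_horn,
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def positional_cell_summary(endpoint_df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM per group x side x position cell (n = dams in cell)."""
    def agg(g: pd.Series) -> pd.Series:
        mean, sem = _mean_sem(list(g))
        return pd.Series({"mean": mean, "sem": sem, "n": g.size})

    out = (
        endpoint_df.groupby(["endpoint", "group_label", "horn_side", "position"])["value"]
        .apply(agg)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
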