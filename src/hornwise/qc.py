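"""Inclusion criteria and Grubbs outlier screening.

Two layers of quality control precede inference:

1. *Inclusion criteria* — a dam whose total litter is under five feti is
   excluded entirely; a horn with under five feti is excluded
   individually while the dam's other horn may remain. Counts are
   reported per group in ``k/N`` form for auditability.
2. *Grubbs screening* — within each analysis cell (group x horn side x
   position, per endpoint) an iterative two-sided Grubbs test at
   alpha = 0.05 removes at most one extreme value per pass until none
   remains significant.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import HornSide, StudyDataset

MIN_LITTER = 5
MIN_HORN = 5


@dataclass(frozen=True)
class GroupExclusions:
    """Exclusion tallies for one treatment group, Table-style ``k/N``."""

    group_label: str
    litters_excluded: int
    litters_total: int
    right_horns_excluded: int
    left_horns_excluded: int
    horns_total: int  # number of dams in the group (one horn each side)

    def as_row(self) -> dict:
        return {
            "group_label": self.group_label,
            "litters_excluded": f"{self.litters_excluded}/{self.litters_total}",
            "right_horns_excluded": f"{self.right_horns_excluded}/{self.horns_total}",
            "left_horns_excluded": f"{self.left_horns_excluded}/{self.horns_total}",
        }


@dataclass
class ExclusionReport:
    """Auditable record of every unit dropped before analysis."""

    groups: dict[str, GroupExclusions] = field(default_factory=dict)
    #: (dam_id, reason) for whole-litter exclusions
    excluded_dams: list[tuple[str, str]] = field(default_factory=list)
    #: (dam_id, side, reason) for per-horn exclusions
    excluded_horns: list[tuple[str, str, str]] = field(default_factory=list)
    #: (group, horn_side, position, endpoint, value) removed by Grubbs
    outliers_removed: list[tuple[str, str, str, str, float]] = field(default_factory=list)

    def summary_lines(self) -> list[str]:
        lines = ["Exclusions (excluded/total):"]
        for g in self.groups.values():
            r = g.as_row()
            lines.append(
                f"  {g.group_label}: litters {r['litters_excluded']}, "
                f"right horns {r['right_horns_excluded']}, "
                f"left horns {r['left_horns_excluded']}"
            )
        if self.outliers_removed:
            lines.append("Grubbs outliers removed:")
            for group, side, pos, endpoint, value in self.outliers_removed:
                lines.append(f"  {group} {side}{pos} [{endpoint}]: {value:.4g}")
        return lines


def apply_inclusion_criteria(dataset: StudyDataset) -> tuple[StudyDataset, ExclusionReport]:
    """Apply the litter-size and horn-size inclusion rules.

    Returns a deep-copied, filtered dataset together with an
    :class:`ExclusionReport`. Idempotent: re-applying to the output
    changes nothing. An empty result is permitted.
    """
    report = ExclusionReport()
    kept_dams = []
    tallies: dict[str, dict[str, int]] = {}
    for dam in dataset.dams:
        t = tallies.setdefault(
            dam.group_label,
            {"litters": 0, "litters_excl": 0, "r_excl": 0, "l_excl": 0},
        )
        t["litters"] += 1
        if dam.litter_size < MIN_LITTER:
            t["litters_excl"] += 1
            report.excluded_dams.append(
                (dam.dam_id, f"litter size {dam.litter_size} < {MIN_LITTER}")
            )
            continue
        new_dam = copy.deepcopy(dam)
        for side, key in ((HornSide.RIGHT, "r_excl"), (HornSide.LEFT, "l_excl")):
            horn = new_dam.horn(side)
            # an absent/empty horn was never a unit of analysis; only
            # populated horns under the threshold count as exclusions
            if 0 < len(horn) < MIN_HORN:
                t[key] += 1
                report.excluded_horns.append(
                    (dam.dam_id, side.value, f"horn has {len(horn)} feti < {MIN_HORN}")
                )
                new_dam.horns.pop(side, None)
        if not any(new_dam.horns.values()):
            # both horns fell to the horn rule: the dam contributes nothing
            # positionally and is dropped (not tallied under the litter rule)
            report.excluded_dams.append(
                (dam.dam_id, f"no horn with >= {MIN_HORN} feti")
            )
            continue
        kept_dams.append(new_dam)

    for label, t in tallies.items():
        report.groups[label] = GroupExclusions(
            group_label=label,
            litters_excluded=t["litters_excl"],
            litters_total=t["litters"],
            right_horns_excluded=t["r_excl"],
            left_horns_excluded=t["l_excl"],
            horns_total=t["litters"],
        )

    control = dataset.control_label
    if kept_dams and control not in {d.group_label for d in kept_dams}:
        control = kept_dams[0].group_label
    filtered = StudyDataset(dams=kept_dams, control_label=control)
    return filtered, report


@dataclass(frozen=True)
class GrubbsResult:
    """Outcome of one two-sided Grubbs pass on a sample of size ``n``."""

    n: int
    g_statistic: float
    g_critical: float
    outlier_index: Optional[int]
    alpha: float


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the
    upper alpha/(2n) quantile of Student-t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError(f"Grubbs test needs n >= 3, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_single_pass(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """One two-sided Grubbs test: flag the most extreme point if significant.

    Uses the sample standard deviation (n-1 denominator). A constant
    sample (sd = 0) flags nothing.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"Grubbs test needs n >= 3, got {n}")
    sd = x.std(ddof=1)
    crit = grubbs_critical(n, alpha)
    if sd == 0:
        return GrubbsResult(n=n, g_statistic=0.0, g_critical=crit, outlier_index=None, alpha=alpha)
    dev = np.abs(x - x.mean())
    idx = int(dev.argmax())
    g = float(dev[idx] / sd)
    return GrubbsResult(
        n=n,
        g_statistic=g,
        g_critical=crit,
        outlier_index=idx if g > crit else None,
        alpha=alpha,
    )


def grubbs_screen(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[list[float], list[GrubbsResult]]:
    """Iteratively remove Grubbs outliers (one per pass) from a sample.

    Stops when no point is significant or fewer than three remain; the
    kept values preserve input order. Samples under three values pass
    through untouched.
    """
    kept = [float(v) for v in values]
    results: list[GrubbsResult] = []
    while len(kept) >= 3:
        res = grubbs_single_pass(kept, alpha=alpha)
        results.append(res)
        if res.outlier_index is None:
            break
        kept.pop(res.outlier_index)
    return kept, results
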