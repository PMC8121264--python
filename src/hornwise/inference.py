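"""Statistical comparisons: Student's t, two-way Type-III ANOVA, Sidak.

The positional analysis feeds unbalanced designs (cell counts differ
because of horn exclusions), so the two-way ANOVA computes Type-III
sums of squares by model comparison: the full cell-means model is fit
by least squares under sum-to-zero factor encoding, each source's SS is
the residual-SS increase when that source's columns are dropped, and
F = MS_source / MS_residual. On balanced data this reduces exactly to
the textbook mean-decomposition sums of squares.

Pairwise contrasts between the two levels of one factor, at each level
of the other, use the ANOVA's pooled residual mean square and are
Sidak-adjusted with family size m = number of within-factor levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TTestResult:
    """Two-sided pooled-variance (classic Student) t-test."""

    group_a: str
    group_b: str
    t_statistic: float
    df: float
    p_value: float
    mean_difference: float


def students_t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
) -> TTestResult:
    """Classic pooled-variance Student's t-test, two-sided.

    df = n_a + n_b - 2; the t sign follows mean(a) - mean(b).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each sample needs n >= 2, got {a.size} and {b.size}")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        group_a=label_a,
        group_b=label_b,
        t_statistic=float(res.statistic),
        df=float(a.size + b.size - 2),
        p_value=float(res.pvalue),
        mean_difference=float(a.mean() - b.mean()),
    )


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with n-1-weighted pooled standard deviation."""

    cohens_d: float
    description: str


def cohens_d(
    sample_a: Sequence[float], sample_b: Sequence[float], description: str = ""
) -> EffectSize:
    """d = (mean_a - mean_b) / pooled sd; NaN when the pooled sd is zero."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each sample needs n >= 2, got {a.size} and {b.size}")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        warnings.warn("zero pooled sd: Cohen's d undefined", stacklevel=2)
        return EffectSize(cohens_d=float("nan"), description=description)
    d = float((a.mean() - b.mean()) / math.sqrt(pooled_var))
    return EffectSize(cohens_d=d, description=description)


@dataclass(frozen=True)
class PairwiseContrast:
    """One Sidak-adjusted cell contrast within a fixed factor level."""

    within_level: str
    level_1: str
    level_2: str
    mean_diff: float
    t_statistic: float
    raw_p: float
    sidak_p: float
    significant: bool
    family_size: int


@dataclass
class AnovaResult:
    """Two-factor Type-III ANOVA table plus cell means.

    ``table`` maps source ('factor_a' name, 'factor_b' name,
    'interaction', 'residual') to SS/df/MS/F/p. ``no_variance`` flags a
    degenerate fit (total SS = 0), in which case F and p are NaN.
    """

    factor_a: str
    factor_b: str
    levels_a: list[str]
    levels_b: list[str]
    table: dict[str, dict[str, float]]
    cell_means: dict[tuple[str, str], tuple[float, int]]
    ms_residual: float
    df_residual: int
    no_variance: bool = False
    pairwise: list[PairwiseContrast] = field(default_factory=list)


def _sum_to_zero_columns(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-coded indicator columns (n_obs x (n_levels - 1))."""
    cols = np.zeros((codes.size, n_levels - 1))
    for j in range(n_levels - 1):
        cols[:, j] = (codes == j).astype(float) - (codes == n_levels - 1).astype(float)
    return cols


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    name_a: str = "A",
    name_b: str = "B",
) -> AnovaResult:
    """Fit the two-factor cell-means model; Type-III SS by model comparison.

    Every cell must hold at least one observation and the residual df
    (N minus number of cells) must be positive.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factor arrays must share one length")
    levels_a = sorted(set(fa.tolist()))
    levels_b = sorted(set(fb.tolist()))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError(
            f"each factor needs >= 2 levels, got {len(levels_a)} x {len(levels_b)}"
        )
    a_codes = np.array([levels_a.index(v) for v in fa])
    b_codes = np.array([levels_b.index(v) for v in fb])

    cell_means: dict[tuple[str, str], tuple[float, int]] = {}
    for i, la in enumerate(levels_a):
        for j, lb in enumerate(levels_b):
            mask = (a_codes == i) & (b_codes == j)
            n = int(mask.sum())
            if n == 0:
                raise ValueError(f"empty cell ({name_a}={la}, {name_b}={lb})")
            cell_means[(la, lb)] = (float(y[mask].mean()), n)

    n_cells = len(levels_a) * len(levels_b)
    df_res = y.size - n_cells
    if df_res < 1:
        raise ValueError(f"residual df = {df_res}; need at least one replicate cell")

    ones = np.ones((y.size, 1))
    A = _sum_to_zero_columns(a_codes, len(levels_a))
    B = _sum_to_zero_columns(b_codes, len(levels_b))
    AB = np.einsum("ij,ik->ijk", A, B).reshape(y.size, -1)

    X_full = np.hstack([ones, A, B, AB])
    rss_full = _rss(X_full, y)
    ss = {
        name_a: max(_rss(np.hstack([ones, B, AB]), y) - rss_full, 0.0),
        name_b: max(_rss(np.hstack([ones, A, AB]), y) - rss_full, 0.0),
        "interaction": max(_rss(np.hstack([ones, A, B]), y) - rss_full, 0.0),
    }
    dfs = {
        name_a: len(levels_a) - 1,
        name_b: len(levels_b) - 1,
        "interaction": (len(levels_a) - 1) * (len(levels_b) - 1),
    }

    total_ss = float(((y - y.mean()) ** 2).sum())
    no_variance = total_ss <= 1e-14 * max(1.0, float(np.abs(y).max()) ** 2)
    ms_res = rss_full / df_res

    table: dict[str, dict[str, float]] = {}
    for source in (name_a, name_b, "interaction"):
        ms = ss[source] / dfs[source]
        if no_variance or ms_res == 0:
            f_stat, p = float("nan"), float("nan")
        else:
            f_stat = ms / ms_res
            p = float(stats.f.sf(f_stat, dfs[source], df_res))
        table[source] = {"ss": ss[source], "df": dfs[source], "ms": ms, "F": f_stat, "p": p}
    table["residual"] = {
        "ss": rss_full,
        "df": df_res,
        "ms": ms_res,
        "F": float("nan"),
        "p": float("nan"),
    }

    return AnovaResult(
        factor_a=name_a,
        factor_b=name_b,
        levels_a=[str(v) for v in levels_a],
        levels_b=[str(v) for v in levels_b],
        table=table,
        cell_means={(str(a), str(b)): v for (a, b), v in cell_means.items()},
        ms_residual=ms_res,
        df_residual=df_res,
        no_variance=no_variance,
    )


def sidak_adjust(raw_p: float, m: int) -> float:
    """Sidak family adjustment 1 - (1 - p)^m, clipped to [0, 1]."""
    if not 0 <= raw_p <= 1:
        raise ValueError(f"raw p must be in [0, 1], got {raw_p}")
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    if m == 1 or raw_p == 1:
        return float(raw_p)
    # expm1/log1p form stays accurate for tiny raw p; never below raw p
    return float(min(1.0, max(-math.expm1(m * math.log1p(-raw_p)), raw_p)))


def sidak_pairwise(
    anova: AnovaResult,
    compare_factor: str,
    alpha: float = 0.05,
) -> list[PairwiseContrast]:
    """Compare the two levels of one factor at each level of the other.

    ``compare_factor`` must name the ANOVA factor with exactly two
    levels; the other factor's levels define both the contrast family
    and the Sidak family size m. The t statistic pools variance through
    the ANOVA's residual mean square with its residual df.
    """
    if compare_factor == anova.factor_a:
        cmp_levels, within_levels = anova.levels_a, anova.levels_b
        key = lambda c, w: (c, w)  # noqa: E731
    elif compare_factor == anova.factor_b:
        cmp_levels, within_levels = anova.levels_b, anova.levels_a
        key = lambda c, w: (w, c)  # noqa: E731
    else:
        raise ValueError(
            f"compare_factor {compare_factor!r} is not a factor of this ANOVA "
            f"({anova.factor_a!r}, {anova.factor_b!r})"
        )
    if len(cmp_levels) != 2:
        raise ValueError(
            f"compare factor must have exactly 2 levels, got {len(cmp_levels)}"
        )
    l1, l2 = cmp_levels
    m = len(within_levels)
    contrasts: list[PairwiseContrast] = []
    for w in within_levels:
        (m1, n1) = anova.cell_means[key(l1, w)]
        (m2, n2) = anova.cell_means[key(l2, w)]
        if n1 == 0 or n2 == 0:  # defensive; two_way_anova rejects empty cells
            warnings.warn(f"empty cell at {w}; contrast skipped", stacklevel=2)
            continue
        diff = m1 - m2
        if anova.no_variance or anova.ms_residual == 0:
            t_stat, raw_p = float("nan"), float("nan")
            adj = float("nan")
            sig = False
        else:
            se = math.sqrt(anova.ms_residual * (1.0 / n1 + 1.0 / n2))
            t_stat = diff / se
            raw_p = float(2.0 * stats.t.sf(abs(t_stat), anova.df_residual))
            adj = sidak_adjust(raw_p, m)
            sig = adj < alpha
        contrasts.append(
            PairwiseContrast(
                within_level=str(w),
                level_1=str(l1),
                level_2=str(l2),
                mean_diff=diff,
                t_statistic=t_stat,
                raw_p=raw_p,
                sidak_p=adj,
                significant=sig,
                family_size=m,
            )
        )
    return contrasts


@dataclass
class PositionalAnalyses:
    """Layered positional inference for one endpoint.

    * ``within_group`` — per group: horn-side x position ANOVA with R-vs-L
      contrasts at each position (the within-group layer).
    * ``vs_control`` — per exposed group and horn side: group-vs-control x
      position ANOVA with group contrasts at each position.
    * ``horn_marginal_p`` — per group: the marginal horn-side p of the
      within-group ANOVA (overall R-vs-L comparison).
    * ``horn_ttest`` — plain pooled t-test of all R values vs. all L
      values per group, offered as the alternative overall comparison.
    """

    endpoint: str
    within_group: dict[str, AnovaResult]
    vs_control: dict[tuple[str, str], AnovaResult]
    horn_marginal_p: dict[str, float]
    horn_ttest: dict[str, TTestResult]


def run_positional_analyses(
    endpoint_table: pd.DataFrame,
    control_label: str,
    alpha: float = 0.05,
    endpoint: Optional[str] = None,
) -> PositionalAnalyses:
    """Run the full positional comparison battery on one endpoint table.

    ``endpoint_table`` is the tidy table from
    :func:`hornwise.endpoints.compute_endpoint_table` (post outlier
    screening), optionally restricted to one endpoint via ``endpoint``.
    """
    df = endpoint_table
    if endpoint is not None:
        df = df[df["endpoint"] == endpoint]
    names = df["endpoint"].unique()
    if len(names) != 1:
        raise ValueError(
            f"endpoint table must hold exactly one endpoint, got {sorted(names)}"
        )
    endpoint_name = str(names[0])

    within_group: dict[str, AnovaResult] = {}
    horn_marginal_p: dict[str, float] = {}
    horn_ttest: dict[str, TTestResult] = {}
    for group in sorted(df["group_label"].unique()):
        sub = df[df["group_label"] == group]
        try:
            res = two_way_anova(
                sub["value"], sub["horn_side"], sub["position"],
                name_a="horn_side", name_b="position",
            )
            res.pairwise = sidak_pairwise(res, "horn_side", alpha=alpha)
            within_group[group] = res
            horn_marginal_p[group] = res.table["horn_side"]["p"]
        except ValueError as exc:
            warnings.warn(f"within-group ANOVA skipped for {group!r}: {exc}", stacklevel=2)
        r_vals = sub.loc[sub["horn_side"] == "R", "value"]
        l_vals = sub.loc[sub["horn_side"] == "L", "value"]
        if len(r_vals) >= 2 and len(l_vals) >= 2:
            horn_ttest[group] = students_t_test(r_vals, l_vals, "R", "L")

    vs_control: dict[tuple[str, str], AnovaResult] = {}
    exposed = sorted(set(df["group_label"].unique()) - {control_label})
    for group in exposed:
        for side in ("R", "L"):
            sub = df[
                df["group_label"].isin([control_label, group])
                & (df["horn_side"] == side)
            ]
            try:
                res = two_way_anova(
                    sub["value"], sub["group_label"], sub["position"],
                    name_a="group", name_b="position",
                )
                res.pairwise = sidak_pairwise(res, "group", alpha=alpha)
                vs_control[(group, side)] = res
            except ValueError as exc:
                warnings.warn(
                    f"vs-control ANOVA skipped for ({group!r}, {side}): {exc}",
                    stacklevel=2,
                )
    return PositionalAnalyses(
        endpoint=endpoint_name,
        within_group=within_group,
        vs_control=vs_control,
        horn_marginal_p=horn_marginal_p,
        horn_ttest=horn_ttest,
    )
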