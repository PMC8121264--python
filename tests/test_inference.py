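"""t-test, two-way Type-III ANOVA, Sidak contrasts, effect sizes."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hornwise.endpoints import compute_endpoint_table
from hornwise.inference import (
    cohens_d,
    run_positional_analyses,
    sidak_adjust,
    sidak_pairwise,
    students_t_test,
    two_way_anova,
)
from hornwise.pipeline import screen_endpoint_table
from hornwise.positions import collapse_dataset
from hornwise.qc import apply_inclusion_criteria
from hornwise.simulate import scenario_gd4_like, simulate_study


# ---------------------------------------------------------------- t-test
def test_t_identical_samples():
    res = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t_statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_t_extreme_separation():
    res = students_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
    assert res.p_value < 0.001
    assert res.mean_difference == -10.0
    assert res.t_statistic < 0  # sign follows the mean difference


def test_t_matches_pooled_variance_closed_form():
    a, b = [2.0, 2.2], [2.1, 2.3]
    res = students_t_test(a, b)
    sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2  # equal n
    t_manual = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 2 + 1 / 2))
    from scipy import stats

    assert res.t_statistic == pytest.approx(t_manual, abs=1e-10)
    assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t_manual), 2), abs=1e-10)
    assert res.df == 2


def test_t_squared_equals_one_way_anova_f():
    """Model-comparison F for a single two-level factor equals t squared."""
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 1, 7), rng.normal(0.5, 1, 9)
    res = students_t_test(a, b)
    y = np.concatenate([a, b])
    x = np.concatenate([np.zeros(7), np.ones(9)])
    X1 = np.column_stack([np.ones_like(y), x])
    rss1 = float(np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    f = (rss0 - rss1) / (rss1 / (y.size - 2))
    assert f == pytest.approx(res.t_statistic**2, rel=1e-10)


# ------------------------------------------------------------- Cohen's d
def test_cohens_d_values():
    assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).cohens_d == 0.0
    assert cohens_d([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]).cohens_d == pytest.approx(-1.0)
    with pytest.warns(UserWarning):
        assert math.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]).cohens_d)


# ----------------------------------------------------------------- Sidak
def test_sidak_closed_form_and_boundaries():
    assert sidak_adjust(0.01, 5) == pytest.approx(1 - 0.99**5, abs=1e-12)
    assert sidak_adjust(0.01, 5) == pytest.approx(0.049010, abs=1e-6)
    assert sidak_adjust(0.0, 5) == 0.0
    assert sidak_adjust(1.0, 5) == 1.0
    assert sidak_adjust(0.037, 1) == pytest.approx(0.037)


@given(
    p=st.floats(min_value=0.0, max_value=1.0),
    q=st.floats(min_value=0.0, max_value=1.0),
    m=st.integers(min_value=1, max_value=20),
)
@settings(max_examples=100, deadline=None)
def test_sidak_monotone_in_p_and_m(p, q, m):
    lo, hi = sorted([p, q])
    assert sidak_adjust(lo, m) <= sidak_adjust(hi, m)
    assert sidak_adjust(p, m) <= sidak_adjust(p, m + 1)
    assert sidak_adjust(p, m) >= p


# ----------------------------------------------------------------- ANOVA
def brute_force_balanced_ss(y, a, b):
    """Textbook mean-decomposition sums of squares for balanced designs."""
    df = pd.DataFrame({"y": y, "a": a, "b": b})
    grand = df["y"].mean()
    na, nb = df["a"].nunique(), df["b"].nunique()
    r = len(df) // (na * nb)
    ss_a = nb * r * sum((df.groupby("a")["y"].mean() - grand) ** 2)
    ss_b = na * r * sum((df.groupby("b")["y"].mean() - grand) ** 2)
    cell = df.groupby(["a", "b"])["y"].mean()
    ma = df.groupby("a")["y"].mean()
    mb = df.groupby("b")["y"].mean()
    ss_ab = r * sum(
        (cell[(ai, bi)] - ma[ai] - mb[bi] + grand) ** 2
        for ai, bi in itertools.product(ma.index, mb.index)
    )
    ss_e = sum((df["y"] - df.set_index(["a", "b"]).index.map(cell)) ** 2)
    return ss_a, ss_b, ss_ab, ss_e


def test_balanced_2x2_exact_example():
    y = [1, 2, 3, 4, 5, 6, 7, 8]
    a = ["a1"] * 4 + ["a2"] * 4
    b = ["b1", "b1", "b2", "b2"] * 2
    res = two_way_anova(y, a, b)
    ss_a, ss_b, ss_ab, ss_e = brute_force_balanced_ss(y, a, b)
    assert res.table["A"]["ss"] == pytest.approx(ss_a, rel=1e-12)
    assert res.table["B"]["ss"] == pytest.approx(ss_b, rel=1e-12)
    assert res.table["interaction"]["ss"] == pytest.approx(ss_ab, rel=1e-12)
    assert res.table["residual"]["ss"] == pytest.approx(ss_e, rel=1e-12)


@pytest.mark.parametrize("seed", range(8))
def test_balanced_2x5_matches_textbook_decomposition(seed):
    rng = np.random.default_rng(seed)
    reps = int(rng.integers(2, 5))
    levels_a, levels_b = ["L", "R"], ["OE", "NOE", "MD", "NCE", "CE"]
    a = [la for la in levels_a for _ in levels_b for _ in range(reps)]
    b = [lb for _ in levels_a for lb in levels_b for _ in range(reps)]
    y = rng.normal(0, 1, len(a))
    res = two_way_anova(y, a, b)
    ss = brute_force_balanced_ss(y, a, b)
    for src, expected in zip(("A", "B", "interaction", "residual"), ss):
        assert res.table[src]["ss"] == pytest.approx(expected, rel=1e-9)
    # balanced additivity and df bookkeeping
    total = float(((y - y.mean()) ** 2).sum())
    assert sum(res.table[s]["ss"] for s in res.table) == pytest.approx(total, rel=1e-9)
    assert sum(res.table[s]["df"] for s in res.table) == len(y) - 1


@pytest.mark.parametrize("seed", range(6))
def test_unbalanced_type3_matches_statsmodels(seed):
    """Independent oracle: statsmodels OLS with sum-to-zero contrasts."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(100 + seed)
    rows = []
    for la in ("L", "R"):
        for lb in ("OE", "NOE", "MD", "NCE", "CE"):
            for _ in range(int(rng.integers(2, 6))):
                rows.append((la, lb, rng.normal(la == "R", 1)))
    df = pd.DataFrame(rows, columns=["a", "b", "y"])
    res = two_way_anova(df["y"], df["a"], df["b"])
    fit = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=3)
    assert res.table["A"]["ss"] == pytest.approx(table.loc["C(a, Sum)", "sum_sq"], rel=1e-8)
    assert res.table["B"]["ss"] == pytest.approx(table.loc["C(b, Sum)", "sum_sq"], rel=1e-8)
    assert res.table["interaction"]["ss"] == pytest.approx(
        table.loc["C(a, Sum):C(b, Sum)", "sum_sq"], rel=1e-8
    )
    assert res.table["residual"]["ss"] == pytest.approx(table.loc["Residual", "sum_sq"], rel=1e-8)
    for src in ("A", "B", "interaction"):
        sm_row = {"A": "C(a, Sum)", "B": "C(b, Sum)", "interaction": "C(a, Sum):C(b, Sum)"}[src]
        assert res.table[src]["p"] == pytest.approx(table.loc[sm_row, "PR(>F)"], rel=1e-8)


def test_anova_degenerate_and_error_cases():
    # zero variance: guarded, F undefined
    y = [2.0] * 20
    a = ["L", "R"] * 10
    b = (["OE"] * 2 + ["NOE"] * 2 + ["MD"] * 2 + ["NCE"] * 2 + ["CE"] * 2) * 2
    res = two_way_anova(y, a, b)
    assert res.no_variance
    assert math.isnan(res.table["A"]["F"])
    # empty cell named in the message
    with pytest.raises(ValueError, match="R.*MD|MD"):
        two_way_anova([1.0, 2.0, 3.0, 2.0], ["L", "L", "R", "R"], ["MD", "OE", "OE", "OE"])
    # no residual df
    with pytest.raises(ValueError, match="residual df"):
        two_way_anova([1.0, 2.0, 3.0, 4.0], ["L", "L", "R", "R"], ["OE", "MD", "OE", "MD"])


def test_sidak_pairwise_structure_and_family_size():
    rng = np.random.default_rng(2)
    a = ["L", "R"] * 25
    b = [p for p in ("OE", "NOE", "MD", "NCE", "CE") for _ in range(10)]
    res = two_way_anova(rng.normal(0, 1, 50), a, b)
    contrasts = sidak_pairwise(res, "A")
    assert len(contrasts) == 5
    assert all(c.family_size == 5 for c in contrasts)
    for c in contrasts:
        assert c.sidak_p == pytest.approx(sidak_adjust(c.raw_p, 5))
        assert c.sidak_p >= c.raw_p


# ------------------------------------------------- positional analyses
@pytest.fixture(scope="module")
def gd4_analysis():
    ds = simulate_study(scenario_gd4_like(), seed=1)
    filtered, _ = apply_inclusion_criteria(ds)
    table = compute_endpoint_table(
        collapse_dataset(filtered), endpoints=("normalized_fetal_weight",)
    )
    table = screen_endpoint_table(table)
    return run_positional_analyses(table, "control")


def test_positional_analysis_family_structure(gd4_analysis):
    """Exactly five contrasts per (group, horn-side) vs-control family."""
    assert set(gd4_analysis.vs_control) == {("gd4", "R"), ("gd4", "L")}
    for res in gd4_analysis.vs_control.values():
        assert len(res.pairwise) == 5
        assert sorted(c.within_level for c in res.pairwise) == sorted(
            ["OE", "NOE", "MD", "NCE", "CE"]
        )
    assert set(gd4_analysis.within_group) == {"control", "gd4"}
    assert "control" in gd4_analysis.horn_marginal_p


def test_right_horn_reduction_recovered_as_significant_rmd(gd4_analysis):
    """An injected 45% right-horn reduction flags the RMD contrast."""
    res = gd4_analysis.vs_control[("gd4", "R")]
    by_pos = {c.within_level: c for c in res.pairwise}
    assert by_pos["MD"].significant
    assert by_pos["MD"].mean_diff > 0  # control minus exposed
    left = gd4_analysis.vs_control[("gd4", "L")]
    assert not any(c.significant for c in left.pairwise)


def test_sidak_familywise_error_under_null():
    """Family-wise error of the 5-contrast Sidak family stays near alpha."""
    rng = np.random.default_rng(2024)
    n_rep, reject = 10_000, 0
    positions = ("OE", "NOE", "MD", "NCE", "CE")
    a = np.array(["L"] * 20 + ["R"] * 20)
    b = np.array([p for p in positions for _ in range(4)] * 2)
    from scipy import stats as ss

    for _ in range(n_rep):
        y = rng.standard_normal(40)
        # direct cell-mean contrasts with pooled residual variance
        resid_ss = 0.0
        means = {}
        for la in ("L", "R"):
            for p in positions:
                cell = y[(a == la) & (b == p)]
                means[(la, p)] = cell.mean()
                resid_ss += ((cell - cell.mean()) ** 2).sum()
        ms = resid_ss / (40 - 10)
        hit = False
        for p in positions:
            t = (means[("L", p)] - means[("R", p)]) / math.sqrt(ms * (1 / 4 + 1 / 4))
            raw = 2 * ss.t.sf(abs(t), 30)
            if sidak_adjust(raw, 5) < 0.05:
                hit = True
                break
        reject += hit
    assert reject / n_rep <= 0.06
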