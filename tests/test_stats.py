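"""Statistics tests: closed-form oracles, calibration and multiplicity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoscreen import (
    adjust_pvalues,
    oneway_anova_tukey,
    two_sample_t,
    twoway_anova,
)


def _factorial_frame(cells: dict, rng=None, sd=0.0, n=None) -> pd.DataFrame:
    """Build a long-format 2×2 frame from {(a, b): values-or-mean}."""
    rows = []
    for (a, b), v in cells.items():
        values = np.asarray(v, dtype=float)
        if values.ndim == 0:
            values = rng.normal(float(v), sd, n)
        for y in values:
            rows.append({"y": y, "ethanol": bool(a), "gsi": bool(b)})
    return pd.DataFrame(rows)


def brute_force_two_way_f(df: pd.DataFrame) -> dict:
    """Closed-form balanced 2×2 sums of squares, independent of statsmodels."""
    cells = {k: g["y"].to_numpy() for k, g in df.groupby(["ethanol", "gsi"])}
    n = {k: len(v) for k, v in cells.items()}
    assert len(set(n.values())) == 1, "balanced designs only"
    n = next(iter(n.values()))
    m = {k: v.mean() for k, v in cells.items()}
    grand = df["y"].mean()
    a_means = {a: np.mean([m[(a, b)] for b in (False, True)]) for a in (False, True)}
    b_means = {b: np.mean([m[(a, b)] for a in (False, True)]) for b in (False, True)}
    ss_a = 2 * n * sum((a_means[a] - grand) ** 2 for a in (False, True))
    ss_b = 2 * n * sum((b_means[b] - grand) ** 2 for b in (False, True))
    ss_ab = n * sum(
        (m[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
        for a in (False, True) for b in (False, True)
    )
    ss_e = sum(((v - m[k]) ** 2).sum() for k, v in cells.items())
    df_e = 4 * (n - 1)
    mse = ss_e / df_e
    return {"ethanol": ss_a / mse, "gsi": ss_b / mse, "interaction": ss_ab / mse}


class TestTwoSampleT:
    def test_identical_groups(self):
        assert two_sample_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_shifted_groups_highly_significant(self):
        t, p = two_sample_t([1, 2, 3], [11, 12, 13])
        assert p < 0.001
        # closed-form pooled t: diff / (s_p * sqrt(2/3)) with s_p = 1
        assert t == pytest.approx(-10.0 / np.sqrt(2.0 / 3.0), rel=1e-12)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1, 2, 3])

    def test_welch_option(self):
        t_student, _ = two_sample_t([1, 2, 3, 4], [10, 20, 30])
        t_welch, _ = two_sample_t([1, 2, 3, 4], [10, 20, 30], equal_var=False)
        assert t_student != t_welch


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        res = oneway_anova_tukey([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert res.f == 0.0
        assert (res.tukey["p_adj"] > 0.999).all()

    def test_closed_form_on_balanced_fixture(self):
        """3 groups × 4 observations: F equals MSbetween/MSwithin by hand."""
        groups = [[10, 12, 11, 13], [15, 17, 16, 18], [20, 22, 21, 23]]
        res = oneway_anova_tukey(*groups)
        means = [np.mean(g) for g in groups]
        grand = np.mean(np.concatenate([np.asarray(g, float) for g in groups]))
        ss_b = 4 * sum((m - grand) ** 2 for m in means)
        ss_w = sum(((np.asarray(g, float) - np.mean(g)) ** 2).sum() for g in groups)
        f_expected = (ss_b / 2) / (ss_w / 9)
        assert res.f == pytest.approx(f_expected, rel=1e-12)
        assert res.p < 1e-4

    def test_fewer_than_two_groups(self):
        with pytest.raises(ValueError):
            oneway_anova_tukey([1, 2, 3])


class TestTwoWayAnova:
    def test_balanced_f_matches_brute_force(self):
        rng = np.random.default_rng(8)
        df = _factorial_frame(
            {(0, 0): 10.0, (1, 0): 8.0, (0, 1): 12.0, (1, 1): 12.5},
            rng=rng, sd=1.5, n=12,
        )
        res = twoway_anova(df, "y")
        oracle = brute_force_two_way_f(df)
        for term, f in oracle.items():
            assert res.anova.loc[term, "F"] == pytest.approx(f, rel=1e-8)

    def test_empty_cell_is_estimability_error(self):
        rng = np.random.default_rng(9)
        df = _factorial_frame(
            {(0, 0): 10.0, (1, 0): 8.0, (0, 1): 12.0}, rng=rng, sd=1.0, n=5
        )
        with pytest.raises(ValueError, match="empty cell"):
            twoway_anova(df, "y")

    def test_single_observation_cell_rejected(self):
        rng = np.random.default_rng(10)
        df = _factorial_frame(
            {(0, 0): [1.0, 2.0], (1, 0): [2.0, 3.0],
             (0, 1): [3.0, 4.0], (1, 1): [5.0]},
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            twoway_anova(df, "y")

    def test_programmed_interaction_detected(self):
        """A strong rescue pattern yields a significant interaction."""
        rng = np.random.default_rng(11)
        df = _factorial_frame(
            {(0, 0): 14.9, (1, 0): 9.0, (0, 1): 16.9, (1, 1): 16.9},
            rng=rng, sd=1.3, n=24,
        )
        res = twoway_anova(df, "y")
        assert res.interaction_p < 0.001

    def test_permutation_destroys_interaction(self):
        """Shuffling well labels removes a programmed interaction signal."""
        rng = np.random.default_rng(12)
        df = _factorial_frame(
            {(0, 0): 14.9, (1, 0): 12.0, (0, 1): 16.9, (1, 1): 16.9},
            rng=rng, sd=1.3, n=12,
        )
        pvals = []
        for _ in range(60):
            perm = df.copy()
            perm["y"] = rng.permutation(perm["y"].to_numpy())
            pvals.append(twoway_anova(perm, "y").interaction_p)
        assert np.median(pvals) > 0.2

    def test_pairwise_table_with_tukey(self):
        rng = np.random.default_rng(13)
        df = _factorial_frame(
            {(0, 0): 10.0, (1, 0): 10.0, (0, 1): 10.0, (1, 1): 10.0},
            rng=rng, sd=1.0, n=8,
        )
        res = twoway_anova(df, "y", correction="tukey")
        assert len(res.pairwise) == 6
        assert res.correction == "tukey"
        assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-12).all()


class TestAdjustPvalues:
    def test_bonferroni_fixture(self):
        out = adjust_pvalues([0.01, 0.02, 0.03], "bonferroni")
        assert np.allclose(out, [0.03, 0.06, 0.09])

    def test_single_p_unchanged(self):
        for method in ("bonferroni", "bh_fdr"):
            assert adjust_pvalues([0.04], method)[0] == pytest.approx(0.04)

    def test_bh_step_up_fixture(self):
        """Hand-computed step-up: p(i)·m/i with running minimum from the top."""
        out = adjust_pvalues([0.001, 0.01, 0.02, 0.8], "bh_fdr")
        assert np.allclose(out, [0.004, 0.02, 4 * 0.02 / 3, 0.8])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "bonferroni")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_bh_monotone_and_dominated_by_bonferroni(self, pvals):
        bh = adjust_pvalues(pvals, "bh_fdr")
        bonf = adjust_pvalues(pvals, "bonferroni")
        order = np.argsort(pvals)
        assert (np.diff(np.asarray(bh)[order]) >= -1e-12).all()
        assert (bonf >= bh - 1e-12).all()
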