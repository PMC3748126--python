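"""Well-level statistics: t-tests, one-way ANOVA/Tukey, factorial ANOVA.

The replication unit is the well.  The factorial workhorse is the 2×2
ethanol × GSI design: a significant ethanol×GSI interaction is the evidence
that part of the ethanol effect is rescued by gamma-secretase inhibition.
Two-way ANOVA uses type-II sums of squares (identical to the classical
closed form on balanced designs); post-hoc pairwise comparisons can be
corrected by Bonferroni, Benjamini–Hochberg FDR, or Tukey HSD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FactorialResult",
    "OneWayResult",
    "two_sample_t",
    "oneway_anova_tukey",
    "twoway_anova",
    "adjust_pvalues",
]

VALID_CORRECTIONS = {"bonferroni", "bh_fdr", "tukey"}


def two_sample_t(
    group1, group2, *, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled-variance Student by default).

    Welch's correction is available with ``equal_var=False``.  Groups of
    fewer than two observations are degenerate and rejected; two groups
    with zero pooled variance and equal means return (0, 1).
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class OneWayResult:
    f: float
    p: float
    tukey: pd.DataFrame      # columns: group1, group2, diff, p_adj


def oneway_anova_tukey(*groups) -> OneWayResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    F is the classical between/within mean-square ratio; Tukey p-values use
    the studentized-range distribution.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = sum(a.size for a in arrays) - len(arrays)
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else float("inf")
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        rows.append({
            "group1": i, "group2": j,
            "diff": float(arrays[i].mean() - arrays[j].mean()),
            "p_adj": float(res.pvalue[i, j]),
        })
    return OneWayResult(f=float(f), p=p, tukey=pd.DataFrame(rows))


@dataclass
class FactorialResult:
    """Two-way ANOVA output for one response variable.

    ``anova`` indexes terms (factor A, factor B, interaction, residual) with
    sum_sq/df/F/p columns; ``cell_means`` carries per-cell mean, SEM and n;
    ``pairwise`` the corrected pairwise cell comparisons.
    """

    response: str
    factor_a: str
    factor_b: str
    anova: pd.DataFrame
    cell_means: pd.DataFrame
    pairwise: pd.DataFrame
    correction: str

    @property
    def interaction_f(self) -> float:
        return float(self.anova.loc["interaction", "F"])

    @property
    def interaction_p(self) -> float:
        return float(self.anova.loc["interaction", "PR(>F)"])

    def f_p(self, term: str) -> tuple[float, float]:
        return (
            float(self.anova.loc[term, "F"]),
            float(self.anova.loc[term, "PR(>F)"]),
        )


def twoway_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "ethanol",
    factor_b: str = "gsi",
    *,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> FactorialResult:
    """Factorial ANOVA of a well-summary response on two crossed factors.

    Requires every cell of the a×b design to hold at least two wells (an
    empty cell leaves the interaction inestimable and raises).  Type-II sums
    of squares are used, which coincide with the classical closed form on
    balanced designs.  Pairwise comparisons of all cells are corrected by
    ``correction`` ∈ {bonferroni, bh_fdr, tukey}.
    """
    if correction not in VALID_CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(VALID_CORRECTIONS)}")
    df = data[[response, factor_a, factor_b]].dropna().copy()
    df.columns = ["y", "A", "B"]
    levels_a = sorted(df["A"].unique(), key=str)
    levels_b = sorted(df["B"].unique(), key=str)
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = df.groupby(["A", "B"], sort=True).size()
    for la in levels_a:
        for lb in levels_b:
            n = counts.get((la, lb), 0)
            if n == 0:
                raise ValueError(
                    f"empty cell ({factor_a}={la}, {factor_b}={lb}): "
                    "interaction not estimable"
                )
            if n < 2:
                raise ValueError(
                    f"cell ({factor_a}={la}, {factor_b}={lb}) has fewer than "
                    "2 observations"
                )
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={
        "C(A)": factor_a, "C(B)": factor_b,
        "C(A):C(B)": "interaction", "Residual": "residual",
    })

    cells = (
        df.groupby(["A", "B"], sort=True)["y"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
        .rename(columns={"A": factor_a, "B": factor_b})
    )
    cells["sem"] = cells["sd"] / np.sqrt(cells["n"])

    groups = {
        (la, lb): df.loc[(df["A"] == la) & (df["B"] == lb), "y"].to_numpy()
        for la in levels_a for lb in levels_b
    }
    keys = list(groups)
    rows = []
    if correction == "tukey":
        res = stats.tukey_hsd(*[groups[k] for k in keys])
        for i, j in itertools.combinations(range(len(keys)), 2):
            rows.append({
                "cell1": _cell_name(keys[i], factor_a, factor_b),
                "cell2": _cell_name(keys[j], factor_a, factor_b),
                "diff": float(groups[keys[i]].mean() - groups[keys[j]].mean()),
                "p_raw": float(res.pvalue[i, j]),
                "p_adj": float(res.pvalue[i, j]),
            })
    else:
        raw = []
        for i, j in itertools.combinations(range(len(keys)), 2):
            _, p = two_sample_t(groups[keys[i]], groups[keys[j]])
            raw.append((i, j, p))
        adj = adjust_pvalues([p for _, _, p in raw], method=correction, alpha=alpha)
        for (i, j, p), pa in zip(raw, adj):
            rows.append({
                "cell1": _cell_name(keys[i], factor_a, factor_b),
                "cell2": _cell_name(keys[j], factor_a, factor_b),
                "diff": float(groups[keys[i]].mean() - groups[keys[j]].mean()),
                "p_raw": p,
                "p_adj": pa,
            })
    pairwise = pd.DataFrame(
        rows, columns=["cell1", "cell2", "diff", "p_raw", "p_adj"]
    )
    pairwise["significant"] = pairwise["p_adj"] <= alpha
    return FactorialResult(
        response=response, factor_a=factor_a, factor_b=factor_b,
        anova=table, cell_means=cells, pairwise=pairwise, correction=correction,
    )


def _cell_name(key: tuple, factor_a: str, factor_b: str) -> str:
    return f"{factor_a}={key[0]}|{factor_b}={key[1]}"


def adjust_pvalues(pvalues, method: str = "bonferroni", alpha: float = 0.05) -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni min(1, m·p) or BH step-up."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method in {"bh_fdr", "fdr", "bh"}:
        return multipletests(p, alpha=alpha, method="fdr_bh")[1]
    raise ValueError(f"unknown correction method {method!r}")
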