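"""Group-level statistics for morphometric traits.

Per experimental cell (ecotype x plate angle): means with Student-t 95%
confidence intervals; a two-way ANOVA with Type-II sums of squares (each
main effect adjusted for the other, the interaction from the full model);
and Scheffé's post hoc method with a compact letter display.  Grouping for
the post hoc follows the interaction rule: pairwise comparisons run over
the six cells when the interaction is significant, over the marginal
levels of each factor otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf


class RankDeficientDesignError(ValueError):
    """Raised when the two-way design matrix is singular."""


def summarize_groups(
    df: pd.DataFrame,
    value: str,
    factors: tuple[str, ...] = ("ecotype", "angle_gp"),
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-cell mean and t-based confidence interval.

    Cells with a single observation report the mean with NaN CI bounds;
    zero-variance cells collapse the CI onto the mean.
    """
    rows = []
    for keys, sub in df.groupby(list(factors), sort=True, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        x = sub[value].to_numpy(dtype=float)
        n = x.size
        mean = float(x.mean())
        if n >= 2:
            se = float(x.std(ddof=1)) / np.sqrt(n)
            half = stats.t.ppf((1 + conf) / 2, n - 1) * se
            lo, hi = mean - half, mean + half
        else:
            lo = hi = np.nan
        rows.append(
            dict(zip(factors, keys))
            | {"n": n, "mean": mean, "ci95_low": lo, "ci95_high": hi}
        )
    return pd.DataFrame(rows)


def anova2_type2(
    df: pd.DataFrame,
    value: str,
    factors: tuple[str, str] = ("ecotype", "angle_gp"),
) -> pd.DataFrame:
    """Two-way ANOVA with Type-II sums of squares.

    Returns a table indexed by effect (factor A, factor B, A:B,
    Residual) with sum_sq, df, F and p columns.  Requires >= 2 levels per
    factor and positive residual degrees of freedom.
    """
    a, b = factors
    work = df[[a, b, value]].copy()
    work.columns = ["fa", "fb", "y"]
    for f in ("fa", "fb"):
        if work[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    model = smf.ols("y ~ C(fa) * C(fb)", data=work).fit()
    exog = model.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise RankDeficientDesignError(
            "singular two-way design (empty cells make the model rank-deficient)"
        )
    if model.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(fa)": a,
            "C(fb)": b,
            "C(fa):C(fb)": f"{a}:{b}",
        },
        columns={"PR(>F)": "p"},
    )
    return table[["sum_sq", "df", "F", "p"]]


@dataclass(frozen=True)
class PosthocResult:
    """Pairwise Scheffé comparisons plus compact letters per group."""

    groups: pd.DataFrame  # group, n, mean, letters
    pairwise: pd.DataFrame  # group1, group2, diff, F_scheffe, p_adj
    alpha: float


def scheffe_posthoc(
    values: np.ndarray, groups: np.ndarray, alpha: float = 0.05
) -> PosthocResult:
    """Scheffé-adjusted all-pairs comparisons over k groups.

    For each pair the contrast statistic
    ``F_c = (mean_i - mean_j)^2 / (MSE * (1/n_i + 1/n_j))`` is referred to
    the Scheffé bound: ``p_adj = P(F_{k-1, df_err} >= F_c / (k-1))``.
    Letters come from the insert-and-absorb compact letter display at
    ``alpha``, processing groups in descending mean order (deterministic).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = labels.size
    if k < 2:
        raise ValueError("Scheffé post hoc needs >= 2 groups")
    stats_rows = []
    sse = 0.0
    n_total = 0
    means, ns = {}, {}
    for lab in labels:
        x = values[groups == lab]
        means[lab] = float(x.mean())
        ns[lab] = x.size
        sse += float(((x - x.mean()) ** 2).sum())
        n_total += x.size
        stats_rows.append({"group": lab, "n": x.size, "mean": means[lab]})
    df_err = n_total - k
    if df_err <= 0:
        raise ValueError("no error degrees of freedom for post hoc")
    mse = sse / df_err

    pair_rows = []
    sig_pairs: set[tuple] = set()
    for g1, g2 in itertools.combinations(labels, 2):
        diff = means[g1] - means[g2]
        denom = mse * (1.0 / ns[g1] + 1.0 / ns[g2])
        if denom == 0.0:
            p = 0.0 if diff != 0.0 else 1.0
            f_c = np.inf if diff != 0.0 else 0.0
        else:
            f_c = diff * diff / denom
            p = float(stats.f.sf(f_c / (k - 1), k - 1, df_err))
        pair_rows.append(
            {"group1": g1, "group2": g2, "diff": diff, "F_scheffe": f_c, "p_adj": p}
        )
        if p < alpha:
            sig_pairs.add((g1, g2))
            sig_pairs.add((g2, g1))

    order = sorted(labels, key=lambda g: -means[g])
    letters = compact_letter_display(order, sig_pairs)
    gdf = pd.DataFrame(stats_rows)
    gdf["letters"] = gdf["group"].map(letters)
    return PosthocResult(
        groups=gdf,
        pairwise=pd.DataFrame(pair_rows),
        alpha=alpha,
    )


def compact_letter_display(
    ordered_groups: list, sig_pairs: set[tuple]
) -> dict:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different.  Columns are
    built by splitting on each significant pair and absorbing columns that
    are subsets of others; groups are handled in the supplied order so the
    output is deterministic.
    """
    columns: list[set] = [set(ordered_groups)]
    for g1, g2 in sorted(
        {tuple(sorted(p, key=lambda g: ordered_groups.index(g))) for p in sig_pairs},
        key=lambda p: (ordered_groups.index(p[0]), ordered_groups.index(p[1])),
    ):
        for col in list(columns):
            if g1 in col and g2 in col:
                columns.remove(col)
                a, b = col - {g2}, col - {g1}
                if not any(a <= c for c in columns):
                    columns.append(a)
                if not any(b <= c for c in columns):
                    columns.append(b)
        # absorb: drop columns contained in another
        columns = [
            c
            for i, c in enumerate(columns)
            if not any(c < d or (c == d and i > j) for j, d in enumerate(columns))
        ]
    # deterministic letter order: sort columns by first member's rank
    columns.sort(key=lambda c: min(ordered_groups.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict = {g: "" for g in ordered_groups}
    for letter, col in zip(alphabet, columns):
        for g in ordered_groups:
            if g in col:
                out[g] += letter
    return out


def metric_posthoc(
    metrics: pd.DataFrame,
    metric: str,
    factors: tuple[str, str] = ("ecotype", "angle_gp"),
    alpha: float = 0.05,
) -> dict:
    """ANOVA plus the interaction-ruled Scheffé post hoc for one metric.

    When the interaction is significant at ``alpha`` the post hoc compares
    the factorial cells; otherwise each factor's marginal levels are
    compared separately.
    """
    a, b = factors
    table = anova2_type2(metrics, metric, factors)
    p_int = float(table.loc[f"{a}:{b}", "p"])
    values = metrics[metric].to_numpy(dtype=float)
    result: dict = {"anova": table, "interaction_p": p_int}
    if p_int < alpha:
        cells = (
            metrics[a].astype(str) + ":" + metrics[b].astype(str)
        ).to_numpy()
        result["grouping"] = "cells"
        result["posthoc"] = {"cells": scheffe_posthoc(values, cells, alpha)}
    else:
        result["grouping"] = "marginal"
        result["posthoc"] = {
            a: scheffe_posthoc(values, metrics[a].to_numpy(), alpha),
            b: scheffe_posthoc(values, metrics[b].to_numpy(), alpha),
        }
    return result
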