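"""Gene-wise differential expression for the two-ecotype, three-angle design.

The expression data are log2 intensities for genes x samples, with a
factorial design of ecotype (Col-0, WS) x growth-plate angle (45, 90,
135 degrees) x replicate.  Every contrast in the study is a two-group
comparison: within an ecotype against the 90-degree vertical control, or
between ecotypes at one angle with WS as the reference.

The test statistic is an empirical-Bayes moderated t.  Gene-wise pooled
variances s_g^2 (d = n1 + n2 - 2 residual df) are shrunk toward a prior:

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t_tilde   = (mean_test - mean_ref) / (s_tilde * sqrt(1/n1 + 1/n2))

with d0 + d degrees of freedom.  The prior (d0, s0^2) is estimated by
moment matching on the log sample variances under the scaled-F model
s^2 ~ s0^2 * F(d, d0): the sample mean and variance of log s^2 are equated
to their theoretical values via digamma/trigamma functions, and the
trigamma equation is inverted by Newton iteration.  If the observed spread
of log variances does not exceed trigamma(d/2) — no detectable gene-to-gene
variance heterogeneity — the prior is a point mass (d0 = infinity) at the
arithmetic mean variance, and t_tilde reduces to a z-like statistic.

A gene is called differentially expressed when |log2FC| > 1 (strictly) and
p < 0.05 (strictly); q < 0.05 under Benjamini-Hochberg step-up adjustment
is tracked as an additional flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

FC_CUT = 1.0
P_CUT = 0.05
Q_CUT = 0.05


@dataclass(frozen=True)
class ModerationParams:
    """Prior degrees of freedom and prior variance of the moderated t."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0 (infinity allowed)")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


@dataclass
class ExpressionStudy:
    """A log2 expression matrix bound to its factorial sample design.

    values: DataFrame, index = gene IDs, columns = sample IDs.
    design: DataFrame indexed by sample ID with columns
        ecotype, angle_gp, replicate.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in matrix")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        extra = [s for s in self.design.index if s not in self.values.columns]
        if extra:
            raise ValueError(f"design rows without matrix columns: {extra}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        self.design = self.design.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def group_samples(self, ecotype: str, angle_gp: int) -> list[str]:
        mask = (self.design["ecotype"] == ecotype) & (
            self.design["angle_gp"].astype(int) == int(angle_gp)
        )
        return list(self.design.index[mask])

    def cells(self) -> list[tuple[str, int]]:
        return sorted(
            {
                (e, int(a))
                for e, a in zip(self.design["ecotype"], self.design["angle_gp"])
            },
            key=lambda c: (c[0], c[1]),
        )


@dataclass
class ContrastResult:
    """Per-gene statistics for one named two-group contrast.

    table columns: log2fc (test minus reference), t, df, p, q, sig,
    sig_fdr, direction; indexed by gene ID.
    """

    contrast_id: str
    table: pd.DataFrame
    params: ModerationParams | None = None

    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["sig"]])


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean empirical distribution.

    Each column's sorted values are replaced by the row-wise mean of all
    columns' order statistics; ties within a column receive the average of
    the reference values at their rank positions.  (A normalization
    stand-in for pipelines whose upstream summarization is out of scope.)
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in matrix")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")  # 1-based, ties avg
        out[:, j] = np.interp(ranks, np.arange(1, x.shape[0] + 1), ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-13 * y:
            break
    return y


def fit_moderation(sample_vars: np.ndarray, df_resid: int) -> ModerationParams:
    """Moment-match the variance prior on log sample variances.

    Genes with non-positive sample variance are excluded from the fit
    (their log is undefined); they are still shrunk when the prior is
    applied.  With fewer than two usable variances, or no excess spread
    beyond trigamma(df/2), the prior is d0 = inf at the mean variance.
    """
    v = np.asarray(sample_vars, dtype=float)
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("no positive sample variances to fit the prior")
    if pos.size == 1:
        return ModerationParams(d0=np.inf, s0_sq=float(pos[0]))
    d = float(df_resid)
    z = np.log(pos)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(((e - emean) ** 2).sum() / (e.size - 1))
    evar -= float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
        return ModerationParams(d0=d0, s0_sq=s0_sq)
    # no detectable heterogeneity: point-mass prior at the mean variance
    return ModerationParams(d0=np.inf, s0_sq=float(pos.mean()))


def contrast_stats(
    study: ExpressionStudy,
    test_group: tuple[str, int] | list[str],
    ref_group: tuple[str, int] | list[str],
    contrast_id: str | None = None,
    moderated: bool = True,
    params: ModerationParams | None = None,
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
    q_cut: float = Q_CUT,
) -> ContrastResult:
    """Two-group moderated (or plain pooled) t for every gene.

    Groups are given either as (ecotype, angle_gp) cells or as explicit
    sample-ID lists.  log2fc = mean(test) - mean(ref).  With
    ``moderated=False`` (equivalently d0 = 0) the statistic is the
    ordinary pooled-variance two-sample t.  Genes with zero residual
    variance under d0 = 0 get p = 0 when the means differ and p = 1
    otherwise.
    """

    def resolve(g) -> list[str]:
        if isinstance(g, tuple) and len(g) == 2:
            samples = study.group_samples(*g)
            if not samples:
                raise ValueError(f"no samples for group {g!r}")
            return samples
        samples = list(g)
        unknown = [s for s in samples if s not in study.values.columns]
        if unknown:
            raise ValueError(f"unknown samples: {unknown}")
        return samples

    test_samples = resolve(test_group)
    ref_samples = resolve(ref_group)
    n1, n2 = len(test_samples), len(ref_samples)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 replicates")

    x1 = study.values[test_samples].to_numpy(dtype=float)
    x2 = study.values[ref_samples].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log2fc = m1 - m2
    d = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(
        axis=1
    )
    s2 = ss / d

    if moderated:
        if params is None:
            params = fit_moderation(s2, d)
        d0, s0_sq = params.d0, params.s0_sq
    else:
        params = None
        d0, s0_sq = 0.0, 1.0  # s0 unused at d0 = 0

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    zero = se == 0  # only reachable with d0 = 0
    t = log2fc / np.where(zero, 1.0, se)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    if zero.any():
        # convention: no spread -> certain call when means differ
        t_zero = np.where(log2fc > 0, np.inf, np.where(log2fc < 0, -np.inf, 0.0))
        t = np.where(zero, t_zero, t)
        p = np.where(zero, np.where(log2fc != 0, 0.0, 1.0), p)

    q = bh_fdr(p)
    sig = (np.abs(log2fc) > fc_cut) & (p < p_cut)
    sig_fdr = sig & (q < q_cut)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "df": df_total,
            "p": p,
            "q": q,
            "sig": sig,
            "sig_fdr": sig_fdr,
            "direction": direction,
        },
        index=study.genes,
    )
    if contrast_id is None:
        contrast_id = "contrast"
    return ContrastResult(contrast_id=contrast_id, table=table, params=params)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    capped at 1 and mapped back to input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_de(
    result: ContrastResult,
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
    q_cut: float = Q_CUT,
) -> pd.DataFrame:
    """Apply the significance rule and return the called genes.

    Strict inequalities on both cutoffs: |log2fc| > fc_cut AND p < p_cut.
    The returned frame keeps log2fc, p, q, direction and a sig_fdr flag
    (additionally q < q_cut).
    """
    if fc_cut <= 0 or p_cut <= 0:
        raise ValueError("cutoffs must be positive")
    t = result.table
    mask = (t["log2fc"].abs() > fc_cut) & (t["p"] < p_cut)
    out = t.loc[mask, ["log2fc", "p", "q", "direction"]].copy()
    out["sig_fdr"] = out["q"] < q_cut
    return out


# The seven study contrasts: within-ecotype tilted angles against the
# vertical control, and Col-0 against WS (reference) at every angle.
WITHIN_KEYS = tuple(
    (eco, angle) for eco, angle in itertools.product(("Col-0", "WS"), (45, 135))
)
BETWEEN_ANGLES = (45, 90, 135)


def within_contrast_id(ecotype: str, angle: int) -> str:
    return f"{ecotype.replace('-', '')}_{angle}_vs_90"


def between_contrast_id(angle: int) -> str:
    return f"Col0_vs_WS_at_{angle}"


def study_contrasts(
    study: ExpressionStudy,
    moderated: bool = True,
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
    q_cut: float = Q_CUT,
) -> tuple[dict[tuple[str, int], ContrastResult], dict[int, ContrastResult]]:
    """Run all seven contrasts; returns (within, between) maps."""
    kw = dict(moderated=moderated, fc_cut=fc_cut, p_cut=p_cut, q_cut=q_cut)
    within = {
        (eco, angle): contrast_stats(
            study,
            (eco, angle),
            (eco, 90),
            contrast_id=within_contrast_id(eco, angle),
            **kw,
        )
        for eco, angle in WITHIN_KEYS
    }
    between = {
        angle: contrast_stats(
            study,
            ("Col-0", angle),
            ("WS", angle),
            contrast_id=between_contrast_id(angle),
            **kw,
        )
        for angle in BETWEEN_ANGLES
    }
    return within, between
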