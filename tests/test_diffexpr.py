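"""Differential-expression statistics against independent oracles."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from rootskew import (
    ExpressionStudy,
    ModerationParams,
    bh_fdr,
    call_de,
    contrast_stats,
    fit_moderation,
    quantile_normalize,
)


def two_group_study(values: np.ndarray) -> ExpressionStudy:
    """genes x 6 matrix -> study with WS 45 (test) vs WS 90 (ref), n=3."""
    n = values.shape[0]
    samples = [f"s{i}" for i in range(6)]
    design = pd.DataFrame(
        {
            "ecotype": ["WS"] * 6,
            "angle_gp": [45, 45, 45, 90, 90, 90],
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    genes = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    return ExpressionStudy(
        values=pd.DataFrame(values, index=genes, columns=samples), design=design
    )


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_two_columns_share_mean_order_statistics(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_column_means_equalised(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 6)) + rng.normal(0, 2, 6))
        out = quantile_normalize(df)
        means = out.mean(axis=0).to_numpy()
        assert np.allclose(means, means[0], atol=1e-9)

    def test_ties_get_average_reference(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}))


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60)
    )
    def test_sorted_q_monotone_and_capped(self, ps):
        p = np.array(ps)
        q = bh_fdr(p)
        assert (q <= 1).all() and (q >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels(self, seed):
        p = np.random.default_rng(seed).uniform(size=200)
        assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))


def moment_oracle(s2: np.ndarray, d: int):
    """Numerically solve the log-variance moment equations for (d0, s0²)."""
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    emean, evar = e.mean(), e.var(ddof=1)
    target = evar - special.polygamma(1, d / 2)
    if target <= 0:
        return np.inf, float(s2.mean())
    y = optimize.brentq(
        lambda y: special.polygamma(1, y) - target, 1e-8, 1e10, xtol=1e-12
    )
    d0 = 2 * y
    s0 = float(np.exp(emean + special.digamma(y) - np.log(y)))
    return d0, s0


class TestModeratedT:
    def test_unmoderated_equals_pooled_t(self):
        rng = np.random.default_rng(1)
        study = two_group_study(rng.normal(size=(30, 6)))
        res = contrast_stats(study, ("WS", 45), ("WS", 90), moderated=False)
        x = study.values.to_numpy()
        t_ref, p_ref = stats.ttest_ind(x[:, :3].T, x[:, 3:].T, equal_var=True)
        assert np.allclose(res.table["t"], t_ref, atol=1e-10)
        assert np.allclose(res.table["p"], p_ref, atol=1e-10)

    def test_identical_sample_variances_collapse_to_pooled_t(self):
        # every gene has the same sample variance -> point-mass prior at v
        rng = np.random.default_rng(2)
        base = rng.normal(size=6)
        values = np.array([base + k for k in range(25)])  # shifts keep variance
        study = two_group_study(values)
        res = contrast_stats(study, ("WS", 45), ("WS", 90), moderated=True)
        assert np.isinf(res.params.d0)
        v = 2 * (values[0, :3].var(ddof=1) + values[0, 3:].var(ddof=1)) / 4
        assert res.params.s0_sq == pytest.approx(v, rel=1e-12)
        plain = contrast_stats(study, ("WS", 45), ("WS", 90), moderated=False)
        assert np.allclose(res.table["log2fc"], plain.table["log2fc"])
        assert np.allclose(res.table["t"], plain.table["t"], rtol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_prior_fit_matches_numeric_moment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # heterogeneous true variances so d0 is finite
        sd = np.sqrt(0.5 / rng.chisquare(5, 20) * 5)
        values = rng.normal(size=(20, 6)) * sd[:, None]
        study = two_group_study(values)
        res = contrast_stats(study, ("WS", 45), ("WS", 90), moderated=True)
        x = values
        s2 = (
            x[:, :3].var(ddof=1, axis=1) * 2 + x[:, 3:].var(ddof=1, axis=1) * 2
        ) / 4
        d0, s0 = moment_oracle(s2, 4)
        assert res.params.d0 == pytest.approx(d0, rel=1e-6)
        assert res.params.s0_sq == pytest.approx(s0, rel=1e-6)
        fc = x[:, :3].mean(axis=1) - x[:, 3:].mean(axis=1)
        s2_tilde = (d0 * s0 + 4 * s2) / (d0 + 4)
        t_ref = fc / np.sqrt(s2_tilde * (2 / 3))
        p_ref = 2 * stats.t.sf(np.abs(t_ref), d0 + 4)
        assert np.allclose(res.table["t"], t_ref, atol=1e-8)
        assert np.allclose(res.table["p"], p_ref, atol=1e-8)

    def test_huge_prior_df_gives_z_statistic(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(40, 6))
        study = two_group_study(values)
        params = ModerationParams(d0=1e9, s0_sq=0.7)
        res = contrast_stats(study, ("WS", 45), ("WS", 90), params=params)
        fc = values[:, :3].mean(axis=1) - values[:, 3:].mean(axis=1)
        s2 = (
            values[:, :3].var(ddof=1, axis=1) + values[:, 3:].var(ddof=1, axis=1)
        ) * 2 / 4
        z = fc / np.sqrt(0.7 * 2 / 3)
        t_lim = fc / np.sqrt(((1e9 * 0.7 + 4 * s2) / (1e9 + 4)) * 2 / 3)
        assert np.allclose(res.table["t"], z, atol=1e-6)
        assert np.allclose(res.table["t"], t_lim, atol=1e-6)

    def test_swap_groups_negates_fc_keeps_p(self):
        rng = np.random.default_rng(4)
        study = two_group_study(rng.normal(size=(25, 6)))
        a = contrast_stats(study, ("WS", 45), ("WS", 90))
        b = contrast_stats(study, ("WS", 90), ("WS", 45))
        assert np.allclose(a.table["log2fc"], -b.table["log2fc"], atol=1e-12)
        assert np.allclose(a.table["p"], b.table["p"], atol=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        study = two_group_study(rng.normal(size=(25, 6)))
        shuffled = ExpressionStudy(
            values=study.values[["s2", "s0", "s1", "s5", "s3", "s4"]],
            design=study.design.loc[["s2", "s0", "s1", "s5", "s3", "s4"]],
        )
        a = contrast_stats(study, ("WS", 45), ("WS", 90))
        b = contrast_stats(shuffled, ("WS", 45), ("WS", 90))
        assert np.allclose(a.table["t"], b.table["t"], atol=1e-12)

    def test_zero_variance_convention_with_d0_zero(self):
        values = np.array([[1.0, 1.0, 1.0, 0.0, 0.0, 0.0], [2.0, 2.0, 2.0, 2.0, 2.0, 2.0]])
        study = two_group_study(values)
        res = contrast_stats(study, ("WS", 45), ("WS", 90), moderated=False)
        assert res.table["p"].iloc[0] == 0.0  # difference with no spread
        assert res.table["p"].iloc[1] == 1.0  # no difference, no spread

    def test_unknown_group_rejected(self):
        rng = np.random.default_rng(6)
        study = two_group_study(rng.normal(size=(5, 6)))
        with pytest.raises(ValueError):
            contrast_stats(study, ("WS", 45), ("Col-0", 90))

    @pytest.mark.parametrize("moderated", [False, True])
    def test_null_type_one_error_calibrated(self, moderated):
        rng = np.random.default_rng(11)
        study = two_group_study(rng.normal(0, 0.25, size=(2000, 6)))
        res = contrast_stats(study, ("WS", 45), ("WS", 90), moderated=moderated)
        rate = float((res.table["p"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_moderated_t_matches_limma(tmp_path):
    """Independent cross-check: prior fit and moderated t against limma."""
    rng = np.random.default_rng(42)
    sd = np.sqrt(0.3 * 6 / rng.chisquare(6, 30))
    values = rng.normal(8, 1, size=(30, 1)) + rng.normal(size=(30, 6)) * sd[:, None]
    study = two_group_study(values)
    res = contrast_stats(study, ("WS", 45), ("WS", 90), moderated=True)

    mat = tmp_path / "mat.tsv"
    pd.DataFrame(values).to_csv(mat, sep="\t", index=False, header=False)
    script = tmp_path / "limma.R"
    script.write_text(
        textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("%s", header=FALSE))
            design <- cbind(ref=1, diff=c(1,1,1,0,0,0))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(d0=fit$df.prior, s0=fit$s2.prior,
                              t=fit$t[,"diff"], p=fit$p.value[,"diff"])
            write.table(format(out, digits=12), "%s", sep="\t",
                        quote=FALSE, row.names=FALSE)
            """
            % (mat, tmp_path / "out.tsv")
        )
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
    assert res.params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
    assert res.params.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
    assert np.allclose(res.table["t"], ref["t"], rtol=1e-5, atol=1e-8)
    assert np.allclose(res.table["p"], ref["p"], rtol=1e-4, atol=1e-10)


class TestCallDe:
    @pytest.fixture()
    def result(self):
        table = pd.DataFrame(
            {
                "log2fc": [1.0, 2.08, 2.0, -1.5],
                "p": [0.001, 0.01, 0.06, 0.04],
                "q": [0.01, 0.04, 0.2, 0.2],
                "direction": ["up", "up", "up", "down"],
            },
            index=pd.Index(["bound", "asn1_like", "pfail", "dn"], name="gene_id"),
        )
        from rootskew import ContrastResult

        return ContrastResult(contrast_id="c", table=table)

    def test_boundary_fold_change_excluded(self, result):
        called = call_de(result)
        assert "bound" not in called.index  # |log2fc| = 1.0 exactly fails ">"

    def test_clear_case_included_with_direction(self, result):
        called = call_de(result)
        assert called.loc["asn1_like", "direction"] == "up"
        assert bool(called.loc["asn1_like", "sig_fdr"])

    def test_p_above_cut_excluded(self, result):
        assert "pfail" not in call_de(result).index

    def test_downregulated_included(self, result):
        assert call_de(result).loc["dn", "direction"] == "down"

    def test_nonpositive_cutoffs_rejected(self, result):
        with pytest.raises(ValueError):
            call_de(result, fc_cut=0.0)
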