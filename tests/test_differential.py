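import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from g4age.differential import (
    ExpressionMatrix, bh_fdr, design_cultures, design_ordinal,
    ebayes_moderate, encode_ordinal_age, estimate_block_correlation,
    fit_contrasts, fit_f_dist, fit_weighted, log_transform,
    old_vs_young_contrast, run_differential, variance_trend_weights,
)
from g4age.synthetic import default_samples

RNG = np.random.default_rng(0)


def _expr(Y, ids=None, cols=None):
    n_pk, n = Y.shape
    ids = ids or [f"p{i}" for i in range(n_pk)]
    cols = cols or [f"s{j}" for j in range(n)]
    return ExpressionMatrix(pd.DataFrame(Y, index=ids, columns=cols))


def _design(ordinal):
    return pd.DataFrame({"intercept": 1.0, "age_ordinal":
                         np.asarray(ordinal, float)},
                        index=[f"s{j}" for j in range(len(ordinal))])


class TestLogTransform:
    def test_offset_closed_forms(self):
        m = pd.DataFrame([[0.0, 0.9]], index=["p"], columns=["a", "b"])
        out = log_transform(m).values.to_numpy()
        assert out[0, 0] == pytest.approx(np.log(0.1))
        assert out[0, 1] == pytest.approx(0.0)

    def test_constant_row_zero_variance(self):
        m = pd.DataFrame([[3.0] * 5], index=["p"],
                         columns=list("abcde"))
        assert log_transform(m).peak_variances[0] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame([[-1.0]]))


class TestVarianceTrendWeights:
    def test_flat_trend_gives_uniform_inverse(self):
        mu = np.linspace(0, 10, 200)
        v = np.full(200, 0.5)
        w = variance_trend_weights(mu, v)
        assert np.allclose(w, 2.0, rtol=0.01)

    def test_monotone_trend_gives_decreasing_weights(self):
        mu = np.linspace(0, 10, 300)
        v = 0.1 + 0.2 * mu
        w = variance_trend_weights(mu, v)
        rho = stats.spearmanr(mu, w).statistic
        assert rho < -0.95

    def test_requires_ten_peaks(self):
        with pytest.raises(ValueError):
            variance_trend_weights(np.arange(5.0), np.arange(5.0))


class TestOrdinalEncoding:
    def test_study_ages(self):
        ages = [22, 24, 32, 34, 53, 56, 72, 73]
        assert encode_ordinal_age(ages).tolist() == [1, 2, 3, 4, 5, 6, 7, 8]

    def test_ties_share_rank_and_order_free(self):
        assert encode_ordinal_age([30, 30, 40]).tolist() == [1, 1, 2]
        assert encode_ordinal_age([40, 30]).tolist() == [2, 1]

    def test_single_age_rejected(self):
        with pytest.raises(ValueError):
            encode_ordinal_age([50, 50])


class TestBlockCorrelation:
    def _samples(self):
        return default_samples()

    def test_duplicated_replicates_hit_clip_bound(self):
        samples = self._samples()
        Y = RNG.normal(size=(300, 8)).repeat(2, axis=1)
        expr = _expr(Y, cols=[s.sample_id for s in samples])
        rho = estimate_block_correlation(expr, design_ordinal(samples),
                                         [s.culture_id for s in samples])
        assert rho == pytest.approx(0.99)

    def test_independent_noise_near_zero(self):
        samples = self._samples()
        Y = np.random.default_rng(21).normal(size=(5000, 16))
        expr = _expr(Y, cols=[s.sample_id for s in samples])
        rho = estimate_block_correlation(expr, design_ordinal(samples),
                                         [s.culture_id for s in samples])
        assert abs(rho) < 0.05

    def test_planted_icc_recovered(self):
        samples = self._samples()
        rng = np.random.default_rng(22)
        icc = 0.5
        u = rng.normal(0, np.sqrt(icc), size=(4000, 8)).repeat(2, axis=1)
        e = rng.normal(0, np.sqrt(1 - icc), size=(4000, 16))
        expr = _expr(u + e, cols=[s.sample_id for s in samples])
        rho = estimate_block_correlation(expr, design_ordinal(samples),
                                         [s.culture_id for s in samples])
        assert 0.4 <= rho <= 0.6

    def test_requires_multi_member_block(self):
        samples = default_samples(replicates=1)
        expr = _expr(RNG.normal(size=(50, 8)),
                     cols=[s.sample_id for s in samples])
        with pytest.raises(ValueError):
            estimate_block_correlation(expr, design_ordinal(samples),
                                       [s.culture_id for s in samples])


class TestFitWeighted:
    def test_exact_line_interpolation(self):
        ordinal = np.repeat(np.arange(1.0, 9.0), 2)
        y = 2.0 + 0.5 * ordinal
        expr = _expr(np.tile(y, (3, 1)))
        fit = fit_weighted(expr, _design(ordinal))
        assert np.allclose(fit.coefficients, [[2.0, 0.5]] * 3, atol=1e-10)
        assert np.allclose(fit.sigma2, 0.0, atol=1e-18)

    def test_scalar_weight_doubling_leaves_coefficients(self):
        ordinal = np.repeat(np.arange(1.0, 9.0), 2)
        Y = RNG.normal(size=(20, 16))
        expr = _expr(Y)
        w = np.abs(RNG.normal(1, 0.1, 20)) + 0.5
        f1 = fit_weighted(expr, _design(ordinal), weights=w)
        f2 = fit_weighted(expr, _design(ordinal), weights=2 * w)
        assert np.allclose(f1.coefficients, f2.coefficients)

    def test_matches_normal_equations_oracle(self):
        for trial in range(100):
            rng = np.random.default_rng(trial)
            n = int(rng.integers(6, 14))
            ordinal = rng.integers(1, 5, n).astype(float)
            if len(np.unique(ordinal)) < 2:
                continue
            Y = rng.normal(size=(3, n))
            X = np.column_stack([np.ones(n), ordinal])
            expr = _expr(Y, cols=[f"s{j}" for j in range(n)])
            design = pd.DataFrame(X, columns=["intercept", "age_ordinal"],
                                  index=[f"s{j}" for j in range(n)])
            fit = fit_weighted(expr, design)
            beta_oracle = np.linalg.solve(X.T @ X, X.T @ Y.T).T
            assert np.allclose(fit.coefficients, beta_oracle, atol=1e-9)

    def test_gls_rho_zero_equals_wls_bitwise(self):
        ordinal = np.repeat(np.arange(1.0, 9.0), 2)
        Y = RNG.normal(size=(30, 16))
        expr = _expr(Y)
        w = np.abs(RNG.normal(1, 0.2, 16)) + 0.5
        blocks = [f"c{j // 2}" for j in range(16)]
        f0 = fit_weighted(expr, _design(ordinal), weights=w)
        fg = fit_weighted(expr, _design(ordinal), weights=w, rho=0.0,
                          blocks=blocks)
        assert (f0.coefficients == fg.coefficients).all()
        assert (f0.sigma2 == fg.sigma2).all()

    def test_rank_deficient_design_rejected(self):
        expr = _expr(RNG.normal(size=(5, 8)))
        bad = pd.DataFrame({"a": np.ones(8), "b": np.ones(8)},
                           index=[f"s{j}" for j in range(8)])
        with pytest.raises(ValueError, match="rank"):
            fit_weighted(expr, bad)


class TestEbayes:
    def test_identical_variances_give_ordinary_t(self):
        # zero spread in s^2 forces infinite prior df and s2_post = s0^2 = s^2
        ordinal = np.repeat(np.arange(1.0, 9.0), 2)
        rng = np.random.default_rng(9)
        base = rng.normal(size=16)
        Y = np.stack([base + rng.normal(0, 1e-9, 16) for _ in range(20)])
        Y = Y + rng.normal(0, 1.0, size=(20, 1))  # shift rows, same shape
        expr = _expr(Y)
        fit = fit_weighted(expr, _design(ordinal))
        res = ebayes_moderate(fit, "age_ordinal")
        d0 = res.attrs["prior_df"]
        assert np.isinf(d0)
        u = fit.cov_unscaled[:, 1, 1]
        t_ord = fit.coefficients[:, 1] / np.sqrt(res.attrs["prior_var"] * u)
        assert np.allclose(res["moderated_t"], t_ord, rtol=1e-6)

    def test_posterior_variance_is_convex_combination(self):
        ordinal = np.repeat(np.arange(1.0, 9.0), 2)
        Y = RNG.normal(size=(500, 16)) * RNG.uniform(0.5, 2.0, (500, 1))
        expr = _expr(Y)
        fit = fit_weighted(expr, _design(ordinal))
        d0, s0 = fit_f_dist(fit.sigma2, fit.df_resid)
        s2_post = (d0 * s0 + fit.df_resid * fit.sigma2) / (d0 + fit.df_resid)
        lo = np.minimum(fit.sigma2, s0)
        hi = np.maximum(fit.sigma2, s0)
        assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()

    def test_hyperparameter_recovery(self):
        rng = np.random.default_rng(33)
        d0_true, s0_true, d = 4.0, 0.05, 14.0
        s2_prior = s0_true * d0_true / rng.chisquare(d0_true, 5000)
        s2 = s2_prior * rng.chisquare(d, 5000) / d
        d0_hat, s0_hat = fit_f_dist(s2, d)
        assert d0_hat == pytest.approx(d0_true, rel=0.25)
        assert s0_hat == pytest.approx(s0_true, rel=0.25)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            fit_f_dist(np.zeros(20), 10.0)


class TestContrasts:
    def _two_group(self, n_pk=50, per=5, seed=1):
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=(n_pk, 2 * per))
        groups = ["A"] * per + ["B"] * per
        design = pd.DataFrame(
            {"A": [1.0 * (g == "A") for g in groups],
             "B": [1.0 * (g == "B") for g in groups]},
            index=[f"s{j}" for j in range(2 * per)],
        )
        expr = _expr(Y, cols=list(design.index))
        return Y, expr, design, per

    def test_contrast_equals_difference_of_group_means(self):
        Y, expr, design, per = self._two_group()
        fit = fit_weighted(expr, design)
        res = fit_contrasts(fit, np.array([-1.0, 1.0]))
        diff = Y[:, per:].mean(axis=1) - Y[:, :per].mean(axis=1)
        assert np.allclose(res["logFC"] * np.log(2), diff, atol=1e-10)

    def test_matches_pooled_t_before_moderation(self):
        Y, expr, design, per = self._two_group(seed=5)
        fit = fit_weighted(expr, design)
        c = np.array([-1.0, 1.0])
        est = fit.coefficients @ c
        u = np.einsum("i,nij,j->n", c, fit.cov_unscaled, c)
        t_mine = est / np.sqrt(fit.sigma2 * u)
        t_oracle = np.array([
            stats.ttest_ind(Y[i, per:], Y[i, :per]).statistic
            for i in range(Y.shape[0])
        ])
        assert np.allclose(t_mine, t_oracle, atol=1e-9)

    def test_zero_and_mislength_contrasts_rejected(self):
        _, expr, design, _ = self._two_group()
        fit = fit_weighted(expr, design)
        with pytest.raises(ValueError):
            fit_contrasts(fit, np.zeros(2))
        with pytest.raises(ValueError):
            fit_contrasts(fit, np.ones(3))

    def test_old_vs_young_contrast_structure(self):
        samples = default_samples()
        design = design_cultures(samples)
        c = old_vs_young_contrast(samples, design)
        assert c.sum() == pytest.approx(0.0)
        assert (c > 0).sum() == 4 and (c < 0).sum() == 4


class TestBH:
    def test_step_up_worked_example(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2]).tolist() == [0.2]
        assert bh_fdr([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript unavailable")
class TestLimmaCrossCheck:
    def test_moderated_t_matches_limma(self, tmp_path):
        """The whole lmFit+eBayes path agrees with the reference
        implementation to near machine precision."""
        rng = np.random.default_rng(3)
        n_pk, n = 200, 16
        ordinal = np.repeat(np.arange(1.0, 9.0), 2)
        scale = np.sqrt(rng.chisquare(4, n_pk) * 0.05 / 4)
        Y = 2 + 0.1 * ordinal[None, :] + rng.normal(
            0, scale[:, None], (n_pk, n)
        )
        ids = [f"p{i}" for i in range(n_pk)]
        cols = [f"s{j}" for j in range(n)]
        ypath = tmp_path / "y.csv"
        pd.DataFrame(Y, index=ids, columns=cols).to_csv(ypath)
        opath = tmp_path / "ord.txt"
        np.savetxt(opath, ordinal)
        rout = tmp_path / "limma.csv"
        script = tmp_path / "cmp.R"
        script.write_text(f"""
suppressMessages(library(limma))
Y <- as.matrix(read.csv("{ypath}", row.names=1))
ordc <- scan("{opath}")
fit <- eBayes(lmFit(Y, cbind(1, ordc)))
write.csv(data.frame(t=fit$t[,2], p=fit$p.value[,2]), "{rout}")
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        lim = pd.read_csv(rout, index_col=0)
        expr = _expr(Y, ids=ids, cols=cols)
        fit = fit_weighted(expr, _design(ordinal))
        res = ebayes_moderate(fit, "age_ordinal")
        assert np.allclose(res["moderated_t"], lim["t"], atol=1e-10)
        assert np.allclose(res["p_value"], lim["p"], atol=1e-10)


class TestRunDifferential:
    def test_reports_log2_per_step_and_info(self):
        samples = default_samples()
        rng = np.random.default_rng(12)
        n = 200
        ordinal = np.repeat(np.arange(1.0, 9.0), 2)
        # planted effect: x2 per step on 40 peaks, on the depth scale
        beta = np.where(np.arange(n) < 40, 1.0, 0.0)
        depth = 50 * 2 ** (beta[:, None] * ordinal[None, :]) \
            * rng.lognormal(0, 0.05, (n, 16))
        mat = pd.DataFrame(depth, index=[f"p{i}" for i in range(n)],
                           columns=[s.sample_id for s in samples])
        res, info = run_differential(mat, samples, use_weights=False,
                                     use_block_correlation=False)
        top = res.set_index("peak_id").loc[[f"p{i}" for i in range(40)]]
        assert top["logFC"].mean() == pytest.approx(1.0, abs=0.05)
        assert set(info["ordinal_map"].values()) == set(range(1, 9))
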