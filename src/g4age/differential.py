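"""Peak-level differential statistics for the age series.

The model: per-peak normalized depths are log-transformed with an offset of
0.1; a lowess fit of per-peak variance against mean supplies inverse
variance-trend weights; donor age enters as an ordinal rank (sorted
distinct ages mapped to 1..K) treated as a continuous predictor; replicate
non-independence within a culture is absorbed by a single consensus
intra-block correlation used in generalized least squares; residual
variances are moderated by empirical Bayes (variances shrunk toward a
scaled inverse-chi-square prior whose hyperparameters are moment-matched on
log residual variances), giving moderated t-statistics with augmented
degrees of freedom; multiplicity is controlled by Benjamini-Hochberg.

Effects are reported as log2 per ordinal-age step (the natural-log fit
coefficient divided by ln 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist, trim_mean
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io_model import SampleMeta

LOG_OFFSET = 0.1
LN2 = float(np.log(2.0))


@dataclass
class ExpressionMatrix:
    """Log-scale peak x sample values with per-peak moments and weights."""

    values: pd.DataFrame          # peaks x samples, ln(offset + norm_depth)
    offset: float = LOG_OFFSET

    @property
    def peak_means(self) -> np.ndarray:
        return self.values.to_numpy().mean(axis=1)

    @property
    def peak_variances(self) -> np.ndarray:
        return self.values.to_numpy().var(axis=1, ddof=1)


def log_transform(norm_depth: pd.DataFrame,
                  offset: float = LOG_OFFSET) -> ExpressionMatrix:
    """Natural log of (offset + normalized depth)."""
    x = norm_depth.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("normalized depths must be non-negative")
    return ExpressionMatrix(
        pd.DataFrame(np.log(offset + x), index=norm_depth.index,
                     columns=norm_depth.columns),
        offset=offset,
    )


def variance_trend_weights(mu: np.ndarray, v: np.ndarray,
                           span: float = 0.5,
                           floor: float = 1e-6) -> np.ndarray:
    """Inverse fitted-variance weights from a lowess mean-variance trend."""
    mu = np.asarray(mu, dtype=float)
    v = np.asarray(v, dtype=float)
    if mu.size < 10:
        raise ValueError("variance trend needs >= 10 peaks")
    fitted = lowess(v, mu, frac=span, return_sorted=False)
    fitted = np.maximum(fitted, floor)
    return 1.0 / fitted


def encode_ordinal_age(ages) -> np.ndarray:
    """Sorted distinct ages mapped to ranks 1..K; ties share a rank."""
    ages = np.asarray(ages)
    distinct = np.unique(ages)
    if distinct.size < 2:
        raise ValueError("need >= 2 distinct ages to encode an ordinal slope")
    amap = {a: i + 1 for i, a in enumerate(distinct)}
    return np.array([amap[a] for a in ages], dtype=float)


def design_ordinal(samples: list[SampleMeta]) -> pd.DataFrame:
    """Intercept + ordinal-age design (rows indexed by sample id)."""
    ranks = encode_ordinal_age([s.age_years for s in samples])
    return pd.DataFrame(
        {"intercept": 1.0, "age_ordinal": ranks},
        index=[s.sample_id for s in samples],
    )


def design_cultures(samples: list[SampleMeta]) -> pd.DataFrame:
    """Culture-specific indicator design (one column per culture, no intercept)."""
    cultures = sorted({s.culture_id for s in samples})
    mat = pd.DataFrame(
        0.0, index=[s.sample_id for s in samples], columns=cultures
    )
    for s in samples:
        mat.loc[s.sample_id, s.culture_id] = 1.0
    return mat


def _check_full_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")


def _block_cholesky(blocks: list[str], rho: float) -> np.ndarray:
    """Cholesky factor of the block-equicorrelation matrix (1-rho)I + rho J."""
    n = len(blocks)
    R = np.eye(n)
    if rho != 0:
        barr = np.asarray(blocks)
        same = barr[:, None] == barr[None, :]
        R = np.where(same, rho, 0.0)
        np.fill_diagonal(R, 1.0)
    return np.linalg.cholesky(R)


@dataclass
class FitResult:
    """Per-peak GLS fits over a common design."""

    peak_ids: list[str]
    coef_names: list[str]
    coefficients: np.ndarray      # peaks x p, natural-log scale
    sigma2: np.ndarray            # peaks, residual variance
    df_resid: float
    cov_unscaled: np.ndarray      # peaks x p x p, (X'SigmaInv X)^{-1}
    rho: float = 0.0


def fit_weighted(expr: ExpressionMatrix, design: pd.DataFrame,
                 weights: np.ndarray | None = None, rho: float = 0.0,
                 blocks: list[str] | None = None) -> FitResult:
    """Generalized least squares per peak.

    Observation covariance is proportional to W^{-1/2} R W^{-1/2} with W the
    weights and R the block-equicorrelation matrix at ``rho`` (identity when
    rho = 0 or no blocks). Weights may be per peak (scalar row weight), per
    sample, or a full peaks x samples matrix; rho = 0 with no blocks reduces
    to weighted least squares.
    """
    Y = expr.values.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n_peaks, n = Y.shape
    p = X.shape[1]
    if X.shape[0] != n:
        raise ValueError("design rows must match sample count")
    _check_full_rank(X)
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")

    if rho != 0 and blocks is None:
        raise ValueError("rho != 0 requires block labels")
    L = _block_cholesky(blocks, rho) if (blocks is not None and rho != 0) \
        else np.eye(n)
    Linv = sla.solve_triangular(L, np.eye(n), lower=True)

    w = None if weights is None else np.asarray(weights, dtype=float)
    if w is not None and np.any(w <= 0):
        raise ValueError("weights must be positive")

    def _solve(Xw: np.ndarray, Yw: np.ndarray):
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
        beta = Yw @ Xw @ XtX_inv.T
        resid = Yw - beta @ Xw.T
        rss = np.sum(resid ** 2, axis=1)
        return beta, rss, XtX_inv

    if w is not None and w.ndim == 2:
        # full per-observation weight matrix: per-peak whitening
        coefs = np.empty((n_peaks, p))
        rss = np.empty(n_peaks)
        covs = np.empty((n_peaks, p, p))
        for i in range(n_peaks):
            T = Linv * np.sqrt(w[i])[None, :]
            Xw = T @ X
            yw = T @ Y[i]
            XtX_inv = np.linalg.inv(Xw.T @ Xw)
            b = XtX_inv @ Xw.T @ yw
            r = yw - Xw @ b
            coefs[i], rss[i], covs[i] = b, r @ r, XtX_inv
    elif w is not None and w.shape == (n,):
        T = Linv * np.sqrt(w)[None, :]
        coefs, rss, XtX_inv = _solve(T @ X, Y @ T.T)
        covs = np.broadcast_to(XtX_inv, (n_peaks, p, p)).copy()
    else:
        # unweighted, or a scalar row weight per peak (rescales the
        # variance and its unscaled covariance but not the coefficients)
        coefs, rss, XtX_inv = _solve(Linv @ X, Y @ Linv.T)
        covs = np.broadcast_to(XtX_inv, (n_peaks, p, p)).copy()
        if w is not None:
            if w.shape != (n_peaks,):
                raise ValueError("weights must be per peak, per sample, or a "
                                 "full matrix")
            rss = rss * w
            covs = covs / w[:, None, None]

    df = float(n - p)
    return FitResult(
        peak_ids=list(expr.values.index), coef_names=list(design.columns),
        coefficients=coefs, sigma2=rss / df, df_resid=df,
        cov_unscaled=covs, rho=rho,
    )


def estimate_block_correlation(expr: ExpressionMatrix, design: pd.DataFrame,
                               blocks: list[str],
                               trim: float = 0.10) -> float:
    """Consensus intra-block correlation of residuals.

    Per peak, the mean within-block cross-product of OLS residuals over the
    residual variance estimates an intra-class correlation (with a
    first-order hat-matrix correction for the downward bias the fixed-effect
    fit induces on residual cross-products); the consensus is tanh of the
    ``trim``-trimmed mean of atanh of the per-peak estimates, clipped to
    (-0.99, 0.99).
    """
    barr = np.asarray(blocks)
    pair_a, pair_b = [], []
    for b in np.unique(barr):
        idx = np.flatnonzero(barr == b)
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                pair_a.append(idx[i])
                pair_b.append(idx[j])
    if not pair_a:
        raise ValueError("need >= 1 block with >= 2 members")

    Y = expr.values.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    _check_full_rank(X)
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    # E[e_a e_b] ~= sigma^2 (rho - H_ab) to first order, H the hat matrix
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    h_pairs = float(np.mean(H[pair_a, pair_b]))
    num = np.mean(resid[:, pair_a] * resid[:, pair_b], axis=1)
    den = np.sum(resid ** 2, axis=1) / (n - p)
    ok = den > 0
    if not np.any(ok):
        raise ValueError("all residuals are zero; correlation undefined")
    r = np.clip(num[ok] / den[ok] + h_pairs, -0.999, 0.999)
    consensus = float(np.tanh(trim_mean(np.arctanh(r), trim)))
    return float(np.clip(consensus, -0.99, 0.99))


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, well-conditioned)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = _trigamma(y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior on residual variances (on the log scale).

    Returns (prior_df d0, prior_var s0^2); d0 = inf when the log-variances
    show no excess spread beyond sampling variability.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not np.any(pos):
        raise ValueError("all residual variances are zero; moderation "
                         "is degenerate")
    z = np.log(s2[pos])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(_trigamma(df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
    return d0, s0


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _moderate(coef: np.ndarray, u: np.ndarray, sigma2: np.ndarray,
              df: float, d0: float, s0: float) -> pd.DataFrame:
    if np.isinf(d0):
        s2_post = np.full_like(sigma2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df * sigma2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * u)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, coef / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * t_dist.sf(np.abs(t_stat), df_total)
    return pd.DataFrame({
        "logFC": coef / LN2,
        "ordinary_se": np.sqrt(sigma2 * u) / LN2,
        "residual_df": df,
        "moderated_t": t_stat,
        "p_value": p,
        "fdr": bh_fdr(p),
    })


def ebayes_moderate(fit: FitResult, coef: str | int = -1) -> pd.DataFrame:
    """Empirical-Bayes moderated test of one fitted coefficient.

    Effects are reported as log2 per unit of the predictor. Attaches the
    hyperparameters (prior_df, prior_var) and the consensus correlation as
    frame attrs.
    """
    if isinstance(coef, str):
        coef = fit.coef_names.index(coef)
    d0, s0 = fit_f_dist(fit.sigma2, fit.df_resid)
    u = fit.cov_unscaled[:, coef, coef]
    out = _moderate(fit.coefficients[:, coef], u, fit.sigma2, fit.df_resid,
                    d0, s0)
    out.insert(0, "peak_id", fit.peak_ids)
    out.attrs.update(prior_df=d0, prior_var=s0, rho=fit.rho)
    return out


def fit_contrasts(fit: FitResult, contrast: np.ndarray) -> pd.DataFrame:
    """Moderated test of a contrast c'beta (e.g. mean old - mean young)."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(fit.coef_names),):
        raise ValueError(
            f"contrast length {c.size} != {len(fit.coef_names)} coefficients"
        )
    if np.all(c == 0):
        raise ValueError("zero contrast vector")
    est = fit.coefficients @ c
    u = np.einsum("i,nij,j->n", c, fit.cov_unscaled, c)
    d0, s0 = fit_f_dist(fit.sigma2, fit.df_resid)
    out = _moderate(est, u, fit.sigma2, fit.df_resid, d0, s0)
    out.insert(0, "peak_id", fit.peak_ids)
    out.attrs.update(prior_df=d0, prior_var=s0, rho=fit.rho)
    return out


def old_vs_young_contrast(samples: list[SampleMeta],
                          design: pd.DataFrame) -> np.ndarray:
    """Mean of older-half cultures minus mean of younger-half cultures."""
    by_culture = {s.culture_id: s.age_years for s in samples}
    cultures = list(design.columns)
    ages = np.array([by_culture[c] for c in cultures], dtype=float)
    med = np.median(ages)
    old = ages > med
    young = ~old
    c = np.where(old, 1.0 / old.sum(), -1.0 / young.sum())
    return c


def run_differential(norm_depth: pd.DataFrame, samples: list[SampleMeta],
                     offset: float = LOG_OFFSET, span: float = 0.5,
                     use_weights: bool = True,
                     use_block_correlation: bool = True,
                     ) -> tuple[pd.DataFrame, dict]:
    """Full ordinal-age differential analysis of one assay's norm matrix.

    Returns the per-peak results table (log2 per ordinal step) and an info
    dict with hyperparameters, consensus correlation and the ordinal map.
    """
    sample_ids = [s.sample_id for s in samples]
    expr = log_transform(norm_depth[sample_ids], offset=offset)
    design = design_ordinal(samples)
    weights = None
    if use_weights:
        weights = variance_trend_weights(expr.peak_means,
                                         expr.peak_variances, span=span)
    blocks = [s.culture_id for s in samples]
    rho = 0.0
    if use_block_correlation and len(set(blocks)) < len(blocks):
        rho = estimate_block_correlation(expr, design, blocks)
    fit = fit_weighted(expr, design, weights=weights, rho=rho, blocks=blocks)
    res = ebayes_moderate(fit, coef="age_ordinal")
    distinct = sorted({s.age_years for s in samples})
    info = {
        "prior_df": res.attrs["prior_df"],
        "prior_var": res.attrs["prior_var"],
        "consensus_correlation": rho,
        "ordinal_map": {str(a): i + 1 for i, a in enumerate(distinct)},
        "offset": offset,
        "span": span,
    }
    return res, info
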