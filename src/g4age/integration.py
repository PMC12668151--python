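"""Conservative effect-size shrinkage, quadrant classification and selections.

The shrinkage replaces a log2 fold-change by the zero-clamped bound of the
confidence interval implied by its p-value: the two-sided z equivalent of p
gives an implied standard error |lfc|/z_obs, and the effect is pulled
toward zero by z_c standard errors (z_c the normal quantile of the chosen
confidence level, 70% by default); intervals containing zero shrink to
exactly zero. Shrunk ATAC and G4 effects are then jointly classified into
gain/loss/neutral quadrants against an assay-agnostic threshold (0.25 log2
for knockdown contrasts, 0.05 for age trends).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

P_FLOOR = 1e-300

STATES = ("gain", "loss", "neutral")


def shrink_effect(raw_logfc, p_value, confidence: float = 0.70):
    """Zero-clamped confidence-bound shrinkage of log2 effects.

    shrunk = sign(lfc) * max(0, |lfc| - z_c * implied_se)
           = sign(lfc) * |lfc| * max(0, 1 - z_c / z_obs)
    with z_obs the two-sided z for p and z_c the two-sided normal quantile
    at ``confidence``. p = 1 or lfc = 0 give 0. Vectorized.
    """
    lfc = np.asarray(raw_logfc, dtype=float)
    p = np.asarray(p_value, dtype=float)
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    if np.any(~np.isfinite(lfc)):
        raise ValueError("log fold-changes must be finite")
    p = np.maximum(p, P_FLOOR)
    z_obs = norm.isf(p / 2.0)
    z_c = norm.ppf((1.0 + confidence) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(z_obs > 0, 1.0 - z_c / z_obs, 0.0)
    shrunk = np.sign(lfc) * np.abs(lfc) * np.maximum(0.0, factor)
    shrunk = np.where(lfc == 0, 0.0, shrunk)
    if shrunk.ndim == 0:
        return float(shrunk)
    return shrunk


def shrink_table(results: pd.DataFrame, confidence: float = 0.70,
                 ) -> pd.DataFrame:
    """Per-peak shrinkage of a differential results table (peak_id, logFC, p)."""
    p = np.maximum(results["p_value"].to_numpy(dtype=float), P_FLOOR)
    lfc = results["logFC"].to_numpy(dtype=float)
    z_obs = norm.isf(p / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(z_obs > 0, np.abs(lfc) / z_obs, np.inf)
    return pd.DataFrame({
        "peak_id": results["peak_id"].to_numpy(),
        "raw_logfc": lfc, "p_value": p, "z_obs": z_obs, "implied_se": se,
        "confidence": confidence,
        "shrunk_logfc": shrink_effect(lfc, p, confidence),
    })


def _state(shrunk: np.ndarray, threshold: float) -> np.ndarray:
    return np.where(shrunk > threshold, "gain",
                    np.where(shrunk < -threshold, "loss", "neutral"))


def classify_quadrant(shrunk_atac, shrunk_g4, threshold: float,
                      label_prefix: str = "") -> pd.DataFrame:
    """Joint gain/loss/neutral states of the two shrunk effects.

    Strict comparisons against +/-threshold (a value exactly at the
    threshold is neutral). Labels read
    ``"<prefix> ATAC <State> | <prefix> G4 <State>"``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    a = np.atleast_1d(np.asarray(shrunk_atac, dtype=float))
    g = np.atleast_1d(np.asarray(shrunk_g4, dtype=float))
    sa, sg = _state(a, threshold), _state(g, threshold)
    prefix = f"{label_prefix} " if label_prefix else ""
    labels = [
        f"{prefix}ATAC {x.capitalize()} | {prefix}G4 {y.capitalize()}"
        for x, y in zip(sa, sg)
    ]
    return pd.DataFrame({
        "atac_state": sa, "g4_state": sg, "threshold": threshold,
        "label": labels,
    })


def count_by_fdr(results: pd.DataFrame,
                 cutoffs=(0.1, 0.05, 0.01, 0.005, 0.001)) -> pd.DataFrame:
    """Gain/loss counts at a ladder of FDR cutoffs (sign of the effect).

    Counts are monotone non-increasing as the cutoff tightens.
    """
    fdr = results["fdr"].to_numpy(dtype=float)
    lfc = results["logFC"].to_numpy(dtype=float)
    rows = []
    for c in sorted(cutoffs, reverse=True):
        sel = fdr <= c
        rows.append({
            "fdr_cutoff": c,
            "gain": int(np.sum(sel & (lfc > 0))),
            "loss": int(np.sum(sel & (lfc < 0))),
        })
    return pd.DataFrame(rows)


def select_top_and_zscore(results: pd.DataFrame, matrix: pd.DataFrame,
                          fdr_max: float = 0.10) -> pd.DataFrame:
    """Z-score (across samples) the matrix rows passing the FDR cut.

    Constant rows cannot be scaled and are dropped with a warning; an empty
    selection returns an empty frame with a warning.
    """
    keep = results.loc[results["fdr"] <= fdr_max, "peak_id"]
    keep = [pid for pid in keep if pid in matrix.index]
    if not keep:
        warnings.warn("no peaks pass the FDR threshold", stacklevel=2)
        return matrix.iloc[:0]
    sub = matrix.loc[keep].astype(float)
    sd = sub.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"dropping {int(const.sum())} constant row(s) before z-scoring",
            stacklevel=2,
        )
        sub, sd = sub.loc[~const], sd[~const]
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
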