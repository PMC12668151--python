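"""Multi-step G4 peak refinement via an M/A filter on paired assay signal.

A G4 CUT&Tag peak call is kept when it either has sufficient mean
normalized signal in both assays (signal tier), or, failing that, shows
enrichment of G4 signal over baseline accessibility in M/A space, where
M = 1/2(log2 ATAC + log2 G4Q) is the average signal and
A = 1/2(log2 G4Q - log2 ATAC) the signal difference. A final stringent
log2(G4Q) threshold defines high-confidence loci. The refinement's readout
is the fold-enrichment of canonical G4 motifs among high-confidence peaks
relative to the unfiltered set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PSEUDOCOUNT = 1e-4

TIERS = ("signal_pass", "ma_pass", "excluded")


def ma_transform(atac_norm, g4_norm, pseudocount: float = PSEUDOCOUNT):
    """(M, A) from non-negative normalized signals; values <= 0 get a pseudocount."""
    a = np.asarray(atac_norm, dtype=float)
    g = np.asarray(g4_norm, dtype=float)
    if np.any(a < 0) or np.any(g < 0):
        raise ValueError("ma_transform requires non-negative inputs")
    a = np.where(a <= 0, pseudocount, a)
    g = np.where(g <= 0, pseudocount, g)
    la, lg = np.log2(a), np.log2(g)
    m = 0.5 * (la + lg)
    adiff = 0.5 * (lg - la)
    if m.ndim == 0:
        return float(m), float(adiff)
    return m, adiff


def refine_g4_peaks(summary: pd.DataFrame, m_min: float = 1.0,
                    a_min: float = 0.25, signal_min: float = 0.5,
                    hc_log2_g4: float = 3.0,
                    hc_ma_only: bool = False) -> pd.DataFrame:
    """Tier every peak and flag high-confidence G4 loci.

    ``summary`` needs columns peak_id, atac_mean_norm, g4_mean_norm over the
    shared peak universe. Tiers: signal_pass if both means are strictly
    above ``signal_min``; otherwise ma_pass if M >= m_min and A >= a_min
    (inclusive); otherwise excluded. high_confidence additionally requires
    log2(g4 + pseudocount) >= ``hc_log2_g4`` (applied to both retained tiers
    by default; ``hc_ma_only=True`` restricts it to the ma_pass tier, with
    signal_pass peaks counting as high confidence unconditionally excluded
    from the log2 screen).
    """
    need = {"peak_id", "atac_mean_norm", "g4_mean_norm"}
    missing = need - set(summary.columns)
    if missing:
        raise ValueError(f"refinement summary lacks columns {sorted(missing)}")
    if summary[["atac_mean_norm", "g4_mean_norm"]].isna().any().any():
        bad = summary.loc[
            summary[["atac_mean_norm", "g4_mean_norm"]].isna().any(axis=1),
            "peak_id",
        ].iloc[0]
        raise ValueError(f"peak {bad!r} missing in one assay summary")
    a = summary["atac_mean_norm"].to_numpy(dtype=float)
    g = summary["g4_mean_norm"].to_numpy(dtype=float)
    m, adiff = ma_transform(a, g)
    signal = (a > signal_min) & (g > signal_min)
    ma = ~signal & (m >= m_min) & (adiff >= a_min)
    tier = np.where(signal, "signal_pass", np.where(ma, "ma_pass", "excluded"))
    log2_g4 = np.log2(g + PSEUDOCOUNT)
    retained = tier != "excluded"
    if hc_ma_only:
        hc = retained & ((tier == "signal_pass") | (log2_g4 >= hc_log2_g4))
    else:
        hc = retained & (log2_g4 >= hc_log2_g4)
    return pd.DataFrame({
        "peak_id": summary["peak_id"].to_numpy(),
        "atac_mean_norm": a, "g4_mean_norm": g, "M": m, "A": adiff,
        "tier": tier, "high_confidence": hc,
    })


def motif_enrichment_fold(refined: pd.DataFrame,
                          canonical: pd.DataFrame) -> float:
    """Canonical-motif fraction among high-confidence peaks over the
    unfiltered fraction.

    ``canonical`` has columns peak_id, canonical_g4 covering the full
    (unfiltered) universe; ``refined`` is the output of
    :func:`refine_g4_peaks` on that universe.
    """
    flags = canonical.set_index("peak_id")["canonical_g4"].astype(bool)
    if flags.empty:
        raise ValueError("empty unfiltered peak set")
    base = flags.mean()
    if base == 0:
        raise ValueError("no canonical peaks in the unfiltered set")
    hc_ids = refined.loc[refined["high_confidence"], "peak_id"]
    if hc_ids.empty:
        return float("nan")
    return float(flags.loc[hc_ids].mean() / base)
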