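"""Independent brute-force / closed-form oracles used by the test suite.

Each oracle is deliberately implemented from first principles along a
different code path than the library (recursive backtracking instead of the
regex engine, sort-and-slice instead of vectorized trimming, rational
approximation instead of scipy's inverse CDF, exhaustive enumeration
instead of indexed lookup), so agreement is evidence of correctness rather
than repetition.
"""

from __future__ import annotations

import math


# -- inverse standard normal CDF: Acklam rational approximation + one
#    Halley refinement step against math.erfc (accuracy ~1e-15) ------------

_A = [-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
      1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00]
_B = [-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
      6.680131188771972e+01, -1.328068155288572e+01]
_C = [-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
      -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00]
_D = [7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
      3.754408661907416e+00]


def inverse_normal_cdf(p: float) -> float:
    """Phi^{-1}(p) independent of scipy."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    p_low, p_high = 0.02425, 1 - 0.02425
    if p < p_low:
        q = math.sqrt(-2 * math.log(p))
        x = ((((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4])
              * q + _C[5])
             / ((((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1))
    elif p <= p_high:
        q = p - 0.5
        r = q * q
        x = ((((((_A[0] * r + _A[1]) * r + _A[2]) * r + _A[3]) * r + _A[4])
              * r + _A[5]) * q
             / (((((_B[0] * r + _B[1]) * r + _B[2]) * r + _B[3]) * r + _B[4])
                * r + 1))
    else:
        q = math.sqrt(-2 * math.log(1 - p))
        x = -((((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4])
               * q + _C[5])
              / ((((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1))
    # Halley refinement against the exact CDF (via erfc)
    e = 0.5 * math.erfc(-x / math.sqrt(2)) - p
    u = e * math.sqrt(2 * math.pi) * math.exp(x * x / 2)
    return x - u / (1 + x * u / 2)


def shrink_oracle(logfc: float, p: float, confidence: float) -> float:
    """Zero-clamped CI-bound shrinkage via the independent inverse CDF."""
    if logfc == 0 or p >= 1:
        return 0.0
    # -Phi^{-1}(p/2) keeps full precision for tiny two-sided p
    z_obs = -inverse_normal_cdf(p / 2)
    z_c = inverse_normal_cdf((1 + confidence) / 2)
    if z_obs <= 0:
        return 0.0
    se = abs(logfc) / z_obs
    mag = max(0.0, abs(logfc) - z_c * se)
    return math.copysign(mag, logfc)


# -- canonical G4 pattern: recursive greedy backtracking matcher ----------

_TOKENS = 7  # G-run, loop, G-run, loop, G-run, loop, G-run


def _match_g4_at(s: str, i: int) -> int | None:
    """End of the greedy canonical-G4 match starting exactly at i, or None."""

    def match(pos: int, t: int) -> int | None:
        if t == _TOKENS:
            return pos
        if t % 2 == 0:  # G-run of >= 3, greedy
            j = pos
            while j < len(s) and s[j] == "G":
                j += 1
            for length in range(j - pos, 2, -1):
                r = match(pos + length, t + 1)
                if r is not None:
                    return r
            return None
        # loop of 1..7 A/C/G/T (never N), greedy
        for length in range(7, 0, -1):
            if pos + length > len(s):
                continue
            if all(c in "ACGT" for c in s[pos:pos + length]):
                r = match(pos + length, t + 1)
                if r is not None:
                    return r
        return None

    return match(i, 0)


def g4_scan_oracle(sequence: str) -> list[tuple[int, int]]:
    """Non-overlapping leftmost-greedy canonical G4 matches, by backtracking."""
    s = sequence.upper()
    spans = []
    i = 0
    while i < len(s):
        end = _match_g4_at(s, i)
        if end is not None:
            spans.append((i, end))
            i = end
        else:
            i += 1
    return spans


# -- hierarchical annotation by exhaustive feature enumeration ------------

PRIORITY = ["first_exon", "promoter", "exon", "utr5", "utr3", "intron",
            "downstream", "intergenic"]


def features_oracle(t, promoter_up=2500, promoter_down=250,
                    downstream_len=3000) -> list[tuple[int, int, str]]:
    """Re-derive one transcript's features from its fields alone."""
    feats = []
    if t.strand == "+":
        feats.append((t.tx_start - promoter_up, t.tx_start + promoter_down,
                      "promoter"))
        feats.append((t.tx_end, t.tx_end + downstream_len, "downstream"))
        feats.append((t.exons[0][0], t.exons[0][1], "first_exon"))
    else:
        feats.append((t.tx_end - promoter_down, t.tx_end + promoter_up,
                      "promoter"))
        feats.append((t.tx_start - downstream_len, t.tx_start, "downstream"))
        feats.append((t.exons[-1][0], t.exons[-1][1], "first_exon"))
    coding = (t.cds_start is not None and t.cds_end is not None
              and t.cds_start < t.cds_end)
    for s, e in t.exons:
        if coding:
            left = "utr5" if t.strand == "+" else "utr3"
            right = "utr3" if t.strand == "+" else "utr5"
            if s < t.cds_start:
                feats.append((s, min(e, t.cds_start), left))
            if e > t.cds_end:
                feats.append((max(s, t.cds_end), e, right))
            if max(s, t.cds_start) < min(e, t.cds_end):
                feats.append((max(s, t.cds_start), min(e, t.cds_end), "exon"))
        else:
            feats.append((s, e, "exon"))
    for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
        if e1 < s2:
            feats.append((e1, s2, "intron"))
    return [(max(0, s), e, c) for s, e, c in feats if max(0, s) < e]


def annotate_oracle(peak_start: int, peak_end: int, transcripts,
                    **kw) -> str:
    """Highest-priority label over every overlapping (feature, transcript)."""
    best = "intergenic"
    for t in transcripts:
        for s, e, cat in features_oracle(t, **kw):
            if peak_start < e and s < peak_end:
                if PRIORITY.index(cat) < PRIORITY.index(best):
                    best = cat
    return best


# -- misc small oracles ----------------------------------------------------

def trimmed_mean_oracle(values, trim: float) -> float:
    vals = sorted(values)
    k = math.floor(len(vals) * trim)
    kept = vals[k:len(vals) - k]
    return sum(kept) / len(kept)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom
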