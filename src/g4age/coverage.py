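"""Cutsite processing, background-anchored normalization and coverage summaries.

Normalization follows a background-anchored scheme: each sample's scaling
factor is the reciprocal of the 20% trimmed mean of its per-base coverage
over randomly sampled non-peak regions, so ``norm_depth = max_depth x
factor`` is comparable across libraries of different sequencing depth.
Cross-replicate summaries include the log-space SD
``exp(sd(log(1e-4 + norm_depth)))``. Peaks overlapping blacklist regions or
lying outside the allowed chromosomes (autosomes + chrX by default) are
excluded before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import GenomicInterval, Peak, PeakSet, SampleMeta

LOG_OFFSET = 1e-4
DEFAULT_CHROMS = frozenset({f"chr{i}" for i in range(1, 23)} | {"chrX"})


def fragments_to_cutsites(fragments: Iterable[GenomicInterval],
                          width: int = 50,
                          chrom_sizes: Mapping[str, int] | None = None,
                          ) -> list[GenomicInterval]:
    """Fixed-width cutsite intervals centered at both ends of each fragment.

    Each fragment yields two intervals of ``width`` bp centered at its start
    and end coordinates, clipped to chromosome bounds; intervals clipped to
    empty are dropped.
    """
    if width % 2 != 0 or width < 2:
        raise ValueError("cutsite width must be even and >= 2")
    half = width // 2
    out: list[GenomicInterval] = []
    for frag in fragments:
        clen = chrom_sizes.get(frag.chrom) if chrom_sizes else None
        for center in (frag.start, frag.end):
            s, e = center - half, center + half
            s = max(0, s)
            if clen is not None:
                e = min(e, clen)
            if s < e:
                out.append(GenomicInterval(frag.chrom, s, e))
    return out


def trimmed_mean(values: Sequence[float], trim_fraction: float = 0.20) -> float:
    """Symmetric trimmed mean: drop floor(n*trim) values from each tail."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("trimmed_mean of empty input")
    if not (0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must be in [0, 0.5)")
    k = int(np.floor(vals.size * trim_fraction))
    vals = np.sort(vals)
    kept = vals[k:vals.size - k] if k > 0 else vals
    return float(kept.mean())


@dataclass
class NormalizationFactor:
    """Per (sample, assay) reciprocal trimmed-mean background factors."""

    factors: dict[tuple[str, str], float] = field(default_factory=dict)
    background_regions: list[GenomicInterval] = field(default_factory=list)
    trim_fraction: float = 0.20

    def get(self, sample_id: str, assay: str) -> float:
        return self.factors[(sample_id, assay)]


def compute_normalization(
    background_values: Mapping[tuple[str, str], Sequence[float]],
    trim_fraction: float = 0.20,
    background_regions: list[GenomicInterval] | None = None,
) -> NormalizationFactor:
    """Factor = 1 / (trimmed mean of background per-base coverage), per sample.

    Raises if a sample's trimmed-mean background is zero (an all-zero
    background indicates a broken library or region sample, not a factor of
    infinity).
    """
    nf = NormalizationFactor(trim_fraction=trim_fraction,
                             background_regions=background_regions or [])
    for key, vals in background_values.items():
        tm = trimmed_mean(vals, trim_fraction)
        if tm <= 0:
            raise ValueError(
                f"background trimmed mean is zero for sample/assay {key}"
            )
        nf.factors[key] = 1.0 / tm
    return nf


def depth_track(intervals: Iterable[GenomicInterval],
                chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Per-base depth arrays from a pile of intervals (difference array)."""
    diff = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_sizes.items()}
    for iv in intervals:
        d = diff.get(iv.chrom)
        if d is None:
            continue
        n = len(d) - 1
        s, e = min(iv.start, n), min(iv.end, n)
        d[s] += 1
        d[e] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diff.items()}


def summarize_peak_coverage(
    peaks: PeakSet,
    depth: Mapping[str, np.ndarray] | None,
    factor: float,
    max_depth: Mapping[str, float] | None = None,
    avg_depth: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-peak max/avg/normalized depth for one sample.

    Either a per-base ``depth`` track (dict chrom -> array; missing
    chromosomes count as all-zero) or precomputed ``max_depth``/``avg_depth``
    maps (peak_id -> value) may be supplied.
    """
    rows = []
    for p in peaks:
        if depth is not None:
            arr = depth.get(p.chrom)
            if arr is None:
                mx, av = 0.0, 0.0
            else:
                window = arr[p.start:min(p.end, len(arr))]
                if window.size < len(p.interval):
                    window = np.pad(window, (0, len(p.interval) - window.size))
                mx = float(window.max()) if window.size else 0.0
                av = float(window.mean()) if window.size else 0.0
        else:
            mx = float(max_depth[p.peak_id])
            av = mx if avg_depth is None else float(avg_depth[p.peak_id])
        rows.append((p.peak_id, mx, av, mx * factor))
    return pd.DataFrame(rows, columns=["peak_id", "max_depth", "avg_depth",
                                       "norm_depth"])


def summarize_study_coverage(
    peaks: PeakSet, assay: str, samples: Sequence[SampleMeta],
    max_depth: pd.DataFrame, avg_depth: pd.DataFrame,
    factors: NormalizationFactor,
) -> pd.DataFrame:
    """Long-format coverage summary across all samples of one assay."""
    frames = []
    for s in samples:
        df = summarize_peak_coverage(
            peaks, None, factors.get(s.sample_id, assay),
            max_depth=max_depth[s.sample_id],
            avg_depth=avg_depth[s.sample_id],
        )
        df.insert(1, "sample_id", s.sample_id)
        df.insert(2, "assay", assay)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def logspace_sd(norm_values: np.ndarray) -> float:
    """exp of the sample SD of ln(1e-4 + norm_depth); >= 1 by construction."""
    return float(np.exp(np.std(np.log(LOG_OFFSET + norm_values), ddof=1)))


def replicate_summary(summary: pd.DataFrame,
                      samples: Sequence[SampleMeta] | None = None,
                      ) -> pd.DataFrame:
    """Cross-replicate statistics per peak (globally and, when sample
    metadata is given, per culture): mean/SD of norm_depth and log-space SD."""
    def _stats(g: pd.DataFrame) -> pd.Series:
        v = g["norm_depth"].to_numpy(dtype=float)
        return pd.Series({
            "mean_norm": v.mean(),
            "sd_norm": v.std(ddof=1) if v.size > 1 else np.nan,
            "logspace_sd": logspace_sd(v) if v.size > 1 else np.nan,
            "mean_max": g["max_depth"].mean(),
        })

    out = (summary.groupby(["peak_id", "assay"], sort=True)
           .apply(_stats, include_groups=False).reset_index())
    if samples is not None:
        cmap = {s.sample_id: s.culture_id for s in samples}
        df = summary.assign(culture_id=summary["sample_id"].map(cmap))
        per_culture = (df.groupby(["peak_id", "assay", "culture_id"], sort=True)
                       .apply(_stats, include_groups=False).reset_index())
        out = out.merge(
            per_culture, on=["peak_id", "assay"], how="left",
            suffixes=("", "_culture"),
        )
    return out


def filter_peaks(peaks: PeakSet, blacklist: Iterable[GenomicInterval] = (),
                 allowed_chroms: frozenset[str] | set[str] = DEFAULT_CHROMS,
                 ) -> PeakSet:
    """Drop peaks overlapping >=1 bp of blacklist or on disallowed chromosomes."""
    bl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in blacklist:
        bl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    kept: list[Peak] = []
    for p in peaks:
        if p.chrom not in allowed_chroms:
            continue
        hits = bl_by_chrom.get(p.chrom, ())
        if any(p.start < e and s < p.end for s, e in hits):
            continue
        kept.append(p)
    return PeakSet(kept, genome_id=peaks.genome_id)


def sample_background_regions(chrom_sizes: Mapping[str, int], peaks: PeakSet,
                              n: int = 5000, length: int = 1000,
                              seed: int = 0,
                              max_attempts_per_region: int = 200,
                              ) -> list[GenomicInterval]:
    """n uniform peak-free intervals of the given length (self-overlap allowed)."""
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    chroms = [c for c, sz in chrom_sizes.items() if sz > length]
    sizes = np.array([chrom_sizes[c] - length for c in chroms], dtype=float)
    if not chroms:
        raise ValueError("no chromosome long enough for background regions")
    probs = sizes / sizes.sum()
    out: list[GenomicInterval] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > n * max_attempts_per_region:
            raise RuntimeError(
                f"could only place {len(out)}/{n} background regions "
                "without peak overlap"
            )
        c = chroms[int(rng.choice(len(chroms), p=probs))]
        s = int(rng.integers(0, chrom_sizes[c] - length + 1))
        e = s + length
        if any(s < pe and ps < e for ps, pe in by_chrom.get(c, ())):
            continue
        out.append(GenomicInterval(c, s, e))
    return out


def presence_matrix(rep_summary: pd.DataFrame,
                    atac_norm_threshold: float = 5.0,
                    g4_raw_threshold: float = 2.0) -> dict[str, pd.DataFrame]:
    """Binary moderate-abundance calls per (peak, culture) for each assay.

    ATAC: present iff the culture's mean normalized depth >= 5 (inclusive).
    G4 CUT&Tag: present iff the culture's mean raw max depth >= 2 (its
    coverage is lower and more discrete, so raw depth is used).
    Expects the per-culture replicate summary from :func:`replicate_summary`.
    """
    need = {"peak_id", "assay", "culture_id", "mean_norm_culture",
            "mean_max_culture"}
    missing = need - set(rep_summary.columns)
    if missing:
        raise ValueError(f"replicate summary lacks columns {sorted(missing)}")
    out: dict[str, pd.DataFrame] = {}
    for assay, g in rep_summary.groupby("assay"):
        metric = ("mean_norm_culture" if assay == "ATAC"
                  else "mean_max_culture")
        thr = atac_norm_threshold if assay == "ATAC" else g4_raw_threshold
        mat = (g.pivot_table(index="peak_id", columns="culture_id",
                             values=metric, aggfunc="first") >= thr)
        out[assay] = mat.astype(int).sort_index()
    return out


def intersection_counts(presence: pd.DataFrame) -> pd.DataFrame:
    """Exact-subset membership counts over cultures (UpSet-style).

    For every non-empty culture subset, the number of peaks present in
    exactly that subset. Counts sum to the number of peaks present in at
    least one culture.
    """
    cultures = list(presence.columns)
    patterns = presence.astype(bool).apply(
        lambda row: tuple(c for c in cultures if row[c]), axis=1
    )
    counts = patterns[patterns.apply(len) > 0].value_counts()
    rows = [
        {"cultures": "&".join(subset), "n_cultures": len(subset),
         "count": int(n)}
        for subset, n in counts.items()
    ]
    return (pd.DataFrame(rows, columns=["cultures", "n_cultures", "count"])
            .sort_values(["n_cultures", "cultures"])
            .reset_index(drop=True))
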