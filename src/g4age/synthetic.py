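"""Synthetic study generator with known ground truth.

Emulates the study design the pipeline targets: primary astrocyte cultures
from eight donors (ages 22, 24, 32, 34, 53, 56, 72 and 73 years), replicate
samples per culture sharing a culture-level random intercept, and two assays
per sample (ATAC-seq accessibility and G4 CUT&Tag occupancy) quantified as
per-peak read depths. Age effects are planted multiplicatively on the log2
scale per ordinal-age step, in four gain/loss quadrant categories plus a
null majority, so downstream calibration and recovery are testable against
recorded truth.

The generator produces a small genome with planted canonical G4 motifs,
non-overlapping gene models covering every annotation category, a shared
ATAC/G4 peak universe (a configurable fraction of peaks centered on planted
motifs), and negative-binomial per-peak depth matrices with per-sample
sequencing-depth factors plus background coverage draws for normalization.
All randomness flows through one seeded generator recorded in the truth.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import G4_PATTERN
from .io_model import (
    GenomicInterval, Peak, PeakSet, SampleMeta, TranscriptModel,
)

DEFAULT_AGES = (22, 24, 32, 34, 53, 56, 72, 73)

QUADRANT_CATEGORIES = (
    "ATAC_gain|G4_gain",
    "ATAC_gain|G4_loss",
    "ATAC_loss|G4_gain",
    "ATAC_loss|G4_loss",
)

_EXON_LEN = 1000
_INTRON_LEN = 1600
_SLOT = 22000
_PEAK_SPACING = 50


@dataclass(frozen=True)
class EffectSpec:
    """Planted per-peak age effect (log2 change per ordinal-age step)."""

    category: str
    beta_atac: float
    beta_g4: float

    def __post_init__(self) -> None:
        if self.category == "null":
            if self.beta_atac != 0 or self.beta_g4 != 0:
                raise ValueError("null category requires zero betas")
        elif self.category in QUADRANT_CATEGORIES:
            a_sign = 1 if "ATAC_gain" in self.category else -1
            g_sign = 1 if "G4_gain" in self.category else -1
            if np.sign(self.beta_atac) != a_sign or np.sign(self.beta_g4) != g_sign:
                raise ValueError(
                    f"beta signs inconsistent with category {self.category}"
                )
        else:
            raise ValueError(f"unknown effect category {self.category!r}")


@dataclass
class SyntheticTruth:
    """Ground truth: planted motifs, per-peak effects, realized random effects."""

    motif_positions: list[tuple[str, int, int]] = field(default_factory=list)
    peak_effects: dict[str, EffectSpec] = field(default_factory=dict)
    culture_effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    motif_peak_ids: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        obj = {
            "motif_positions": [list(m) for m in self.motif_positions],
            "peak_effects": {k: asdict(v) for k, v in self.peak_effects.items()},
            "culture_effects": {
                "|".join(k): v for k, v in self.culture_effects.items()
            },
            "motif_peak_ids": self.motif_peak_ids,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SyntheticTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            motif_positions=[tuple(m) for m in obj["motif_positions"]],
            peak_effects={
                k: EffectSpec(**v) for k, v in obj["peak_effects"].items()
            },
            culture_effects={
                tuple(k.split("|", 2)): v
                for k, v in obj["culture_effects"].items()
            },
            motif_peak_ids=list(obj.get("motif_peak_ids", [])),
            params=obj["params"],
        )


def default_samples(ages=DEFAULT_AGES, replicates: int = 2,
                    condition: str = "none") -> list[SampleMeta]:
    """The default study design: one culture per donor age, n replicates each."""
    samples = []
    for i, age in enumerate(ages, start=1):
        cid = f"cult{i}"
        for r in range(1, replicates + 1):
            samples.append(SampleMeta(f"{cid}_rep{r}", cid, int(age), condition))
    return samples


def random_g4_motif(rng: np.random.Generator) -> str:
    """A random canonical G4 instance: four runs of 3-5 G, loops of 1-7 non-G."""
    parts = []
    for i in range(4):
        parts.append("G" * int(rng.integers(3, 6)))
        if i < 3:
            loop_len = int(rng.integers(1, 8))
            parts.append("".join(rng.choice(list("ACT"), size=loop_len)))
    motif = "".join(parts)
    assert G4_PATTERN.fullmatch(motif)
    return motif


def simulate_genome(n_chrom: int = 2, chrom_length: int = 300_000,
                    gc_fraction: float = 0.41, planted_motifs: int = 100,
                    seed: int = 0) -> tuple[dict[str, str], SyntheticTruth]:
    """Random genome with planted, non-overlapping canonical G4 motifs.

    Background bases are i.i.d. at the stated GC fraction. Planted motif
    positions are recorded in the returned truth; byte-identical output for
    a given seed.
    """
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10000")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    bases = np.array(list("ACGT"))
    truth = SyntheticTruth(params={
        "n_chrom": n_chrom, "chrom_length": chrom_length,
        "gc_fraction": gc_fraction, "planted_motifs": planted_motifs,
        "genome_seed": int(seed),
    })
    genome: dict[str, str] = {}
    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        seq = rng.choice(bases, size=chrom_length, p=p)
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < planted_motifs:
            attempts += 1
            if attempts > 200 * max(1, planted_motifs):
                raise RuntimeError(
                    f"could not place {planted_motifs} motifs on {chrom} "
                    f"without overlap (placed {len(placed)})"
                )
            motif = random_g4_motif(rng)
            start = int(rng.integers(0, chrom_length - len(motif)))
            end = start + len(motif)
            # keep a 30 bp guard band so planted motifs never merge
            if any(start < e + 30 and s - 30 < end for s, e in placed):
                continue
            seq[start:end] = list(motif)
            placed.append((start, end))
        for s, e in sorted(placed):
            truth.motif_positions.append((chrom, s, e))
        genome[chrom] = "".join(seq)
    return genome, truth


def write_fasta(genome: dict[str, str], path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _gene_layout(slot_start: int, strand: str, n_exons: int) -> TranscriptModel:
    """One gene inside its slot: fixed exon/intron geometry, strand mirrored."""
    tx_len = n_exons * _EXON_LEN + (n_exons - 1) * _INTRON_LEN
    tx_start = slot_start + (2500 if strand == "+" else 3000)
    exons = []
    pos = tx_start
    for _ in range(n_exons):
        exons.append((pos, pos + _EXON_LEN))
        pos += _EXON_LEN + _INTRON_LEN
    tx_end = tx_start + tx_len
    return TranscriptModel(
        transcript_id="", gene_name="", chrom="", strand=strand,
        tx_start=tx_start, tx_end=tx_end, exons=tuple(exons),
        cds_start=exons[0][0] + 200, cds_end=exons[-1][1] - 200,
    )


def _category_span(t: TranscriptModel, category: str,
                   slot_start: int) -> tuple[int, int]:
    """Placement window inside one gene slot guaranteeing the target category."""
    if category == "intergenic":
        return slot_start + 17_000, slot_start + 21_500
    plus = t.strand == "+"
    first = t.exons[0] if plus else t.exons[-1]
    second = t.exons[1] if plus else t.exons[-2]
    if category == "promoter":
        return ((t.tx_start - 2450, t.tx_start - 150) if plus
                else (t.tx_end + 150, t.tx_end + 2450))
    if category == "first_exon":
        return first[0] + 50, first[1] - 50
    if category == "exon":
        lo, hi = second
        # stay inside the coding portion when the second exon abuts CDS ends
        lo, hi = max(lo, t.cds_start), min(hi, t.cds_end)
        return lo + 50, hi - 50
    if category == "intron":
        lo = min(first[1], second[1]) if not plus else first[1]
        hi = second[0] if plus else first[0]
        if not plus:
            lo, hi = second[1], first[0]
        return lo + 50, hi - 50
    if category == "downstream":
        return ((t.tx_end + 100, t.tx_end + 2900) if plus
                else (t.tx_start - 2900, t.tx_start - 100))
    raise ValueError(f"unknown category {category!r}")


def plant_effects(peak_ids, null_fraction: float = 0.8,
                  beta_step: float = 0.2,
                  rng: np.random.Generator | int = 0) -> dict[str, EffectSpec]:
    """Assign effect categories: a null majority, quadrants round-robin on a
    seeded shuffle of the rest."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(peak_ids)
    n_nonnull = int(round(n * (1 - null_fraction)))
    positions = np.empty(n, dtype=int)
    positions[rng.permutation(n)] = np.arange(n)
    out = {}
    for rank, pid in enumerate(peak_ids):
        pos = positions[rank]
        if pos < n_nonnull:
            cat = QUADRANT_CATEGORIES[pos % len(QUADRANT_CATEGORIES)]
            ba = beta_step if "ATAC_gain" in cat else -beta_step
            bg = beta_step if "G4_gain" in cat else -beta_step
            out[pid] = EffectSpec(cat, ba, bg)
        else:
            out[pid] = EffectSpec("null", 0.0, 0.0)
    return out


DEFAULT_CATEGORY_WEIGHTS = {
    "promoter": 0.20, "first_exon": 0.08, "exon": 0.08,
    "intron": 0.20, "downstream": 0.14, "intergenic": 0.30,
}


def simulate_peaks_and_transcripts(
    genome: dict[str, str], n_genes: int = 24, n_peaks: int = 600,
    truth: SyntheticTruth | None = None, seed: int = 0,
    peak_width: int = 300, motif_peak_fraction: float = 0.25,
    null_fraction: float = 0.8, beta_step: float = 0.2,
    category_weights: dict[str, float] | None = None,
) -> tuple[dict[str, PeakSet], list[TranscriptModel], SyntheticTruth]:
    """Gene models plus a shared ATAC/G4 peak universe with planted effects.

    Genes are laid out in non-overlapping slots with 2-5 exons, alternating
    strand. Peaks cover every annotation category by construction; a
    ``motif_peak_fraction`` of peaks is centered on planted motifs. Effect
    categories (four gain/loss quadrants) are assigned round-robin to a
    ``1 - null_fraction`` share of peaks with |beta| = ``beta_step`` log2
    per ordinal-age step.
    """
    if truth is None:
        truth = SyntheticTruth()
    if n_peaks < 8 * (len(QUADRANT_CATEGORIES) + 1):
        raise ValueError("n_peaks must be >= 8 x number of effect categories")
    rng = np.random.default_rng(seed)
    weights = dict(category_weights or DEFAULT_CATEGORY_WEIGHTS)

    chroms = list(genome)
    chrom_sizes = {c: len(genome[c]) for c in chroms}
    per_chrom = int(np.ceil(n_genes / len(chroms)))
    if per_chrom * _SLOT + 2000 > min(chrom_sizes.values()):
        raise ValueError(
            f"genome too small for {n_genes} genes "
            f"(need >= {per_chrom * _SLOT + 2000} bp per chromosome)"
        )

    transcripts: list[TranscriptModel] = []
    slots: list[tuple[str, int, TranscriptModel]] = []
    g = 0
    for c_i, chrom in enumerate(chroms):
        for s_i in range(per_chrom):
            if g >= n_genes:
                break
            slot_start = 1000 + s_i * _SLOT
            strand = "+" if g % 2 == 0 else "-"
            n_exons = int(rng.integers(2, 6))
            t = _gene_layout(slot_start, strand, n_exons)
            t = TranscriptModel(
                transcript_id=f"tx{g + 1:03d}", gene_name=f"GENE{g + 1:03d}",
                chrom=chrom, strand=strand, tx_start=t.tx_start,
                tx_end=t.tx_end, exons=t.exons,
                cds_start=t.cds_start, cds_end=t.cds_end,
            )
            transcripts.append(t)
            slots.append((chrom, slot_start, t))
            g += 1

    # motif-centered peaks first, then category-targeted peaks round-robin
    n_motif_peaks = min(int(round(n_peaks * motif_peak_fraction)),
                        len(truth.motif_positions))
    half = peak_width // 2
    intervals: list[tuple[str, int, int, str]] = []  # chrom, start, end, tag
    motif_order = rng.permutation(len(truth.motif_positions))
    for k in range(n_motif_peaks):
        chrom, ms, me = truth.motif_positions[int(motif_order[k])]
        mid = (ms + me) // 2
        start = max(0, mid - half)
        intervals.append((chrom, start, start + peak_width, "motif"))

    n_rest = n_peaks - n_motif_peaks
    cats = list(weights)
    counts = {c: int(round(weights[c] * n_rest)) for c in cats}
    # rounding drift goes to the intergenic pool
    counts["intergenic"] += n_rest - sum(counts.values())
    placed_per: dict[tuple[int, str], int] = {}
    if n_genes == 0:
        # no genes: everything is intergenic, spread uniformly
        for k in range(n_rest):
            chrom = chroms[k % len(chroms)]
            lo = 1000 + (k // len(chroms)) * (peak_width + _PEAK_SPACING)
            if lo + peak_width > chrom_sizes[chrom] - 1000:
                raise ValueError("genome too small for requested peak count")
            intervals.append((chrom, lo, lo + peak_width, "intergenic"))
    else:
        for cat in cats:
            for k in range(counts[cat]):
                gi = (k + hash(cat) % n_genes) % len(slots)
                placed = None
                for attempt in range(len(slots)):
                    gj = (gi + attempt) % len(slots)
                    chrom, slot_start, t = slots[gj]
                    lo, hi = _category_span(t, cat, slot_start)
                    j = placed_per.get((gj, cat), 0)
                    start = lo + j * (peak_width + _PEAK_SPACING)
                    if start + peak_width <= hi:
                        placed_per[(gj, cat)] = j + 1
                        placed = (chrom, start, start + peak_width, cat)
                        break
                if placed is None:
                    raise ValueError(
                        f"genome too small: no room left for a {cat} peak"
                    )
                intervals.append(placed)

    order = sorted(range(len(intervals)),
                   key=lambda i: (intervals[i][0], intervals[i][1]))
    peaks_by_assay: dict[str, PeakSet] = {}
    peak_ids = [f"peak_{i + 1:05d}" for i in range(len(intervals))]
    for assay in ("ATAC", "G4Q"):
        plist = [
            Peak(GenomicInterval(intervals[i][0], intervals[i][1],
                                 intervals[i][2]),
                 peak_ids[rank], assay)
            for rank, i in enumerate(order)
        ]
        peaks_by_assay[assay] = PeakSet(plist, genome_id="synthetic")
    truth.motif_peak_ids = [
        peak_ids[rank] for rank, i in enumerate(order)
        if intervals[i][3] == "motif"
    ]

    truth.peak_effects.update(
        plant_effects(peak_ids, null_fraction, beta_step, rng)
    )

    truth.params.update({
        "n_genes": n_genes, "n_peaks": n_peaks, "peak_width": peak_width,
        "motif_peak_fraction": motif_peak_fraction,
        "null_fraction": null_fraction, "beta_step": beta_step,
        "peaks_seed": int(seed),
    })
    return peaks_by_assay, transcripts, truth


def ordinal_ranks(samples: list[SampleMeta]) -> np.ndarray:
    """Ordinal age rank (1..K over sorted distinct ages) per sample."""
    ages = sorted({s.age_years for s in samples})
    amap = {a: i + 1 for i, a in enumerate(ages)}
    return np.array([amap[s.age_years] for s in samples], dtype=float)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean, size) draw; infinite size is the Poisson limit."""
    if np.isinf(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_coverage(
    peaks: dict[str, PeakSet], samples: list[SampleMeta],
    truth: SyntheticTruth, base_mean: float = 50.0, dispersion: float = 10.0,
    culture_sd: float = 0.25, seed: int = 0, depth_factor_sd: float = 0.3,
    bg_mean: float = 4.0, n_bg_values: int = 2000,
    peak_mean_sd: float = 0.5, motif_g4_boost: float = 1.0,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame],
           dict[str, pd.DataFrame], SyntheticTruth]:
    """Per-assay depth matrices (peaks x samples) plus background coverage.

    Depth ~ NegativeBinomial with mean
    ``base_mean_peak * depth_factor_sample * 2^(beta * (ordinal - mean) + u)``
    where ``u ~ Normal(0, culture_sd^2)`` is shared by all replicates of a
    culture (recorded in the truth) and ``dispersion`` is the NB size
    (infinite = Poisson). ``motif_g4_boost`` multiplies the G4 base mean at
    motif-centered peaks (occupied G4 structures carry more CUT&Tag signal).
    Returns (max_depth, avg_depth, background) frames per assay and the
    updated truth.
    """
    if base_mean <= 0 or dispersion <= 0:
        raise ValueError("base_mean and dispersion must be positive")
    cultures = sorted({s.culture_id for s in samples})
    if not all(any(s.culture_id == c for s in samples) for c in cultures):
        raise ValueError("every culture needs >= 1 sample")
    rng = np.random.default_rng(seed)
    sample_ids = [s.sample_id for s in samples]
    ords = ordinal_ranks(samples)
    ords = ords - ords.mean()
    depth_factors = np.exp(rng.normal(0.0, depth_factor_sd, size=len(samples)))

    max_mats: dict[str, pd.DataFrame] = {}
    avg_mats: dict[str, pd.DataFrame] = {}
    bg: dict[str, pd.DataFrame] = {}
    for assay in sorted(peaks):
        pset = peaks[assay]
        ids = pset.ids
        n_p, n_s = len(ids), len(samples)
        betas = np.array([
            (truth.peak_effects[pid].beta_atac if assay == "ATAC"
             else truth.peak_effects[pid].beta_g4)
            if pid in truth.peak_effects else 0.0
            for pid in ids
        ])
        base = base_mean * np.exp2(rng.normal(0.0, peak_mean_sd, size=n_p))
        if assay == "G4Q" and motif_g4_boost != 1.0:
            motif_set = set(truth.motif_peak_ids)
            boost = np.array([motif_g4_boost if pid in motif_set else 1.0
                              for pid in ids])
            base = base * boost
        u = np.zeros((n_p, n_s))
        if culture_sd > 0:
            u_culture = {c: rng.normal(0.0, culture_sd, size=n_p)
                         for c in cultures}
            for j, s in enumerate(samples):
                u[:, j] = u_culture[s.culture_id]
            for c in cultures:
                for i, pid in enumerate(ids):
                    truth.culture_effects[(c, pid, assay)] = float(
                        u_culture[c][i]
                    )
        mean = (base[:, None] * depth_factors[None, :]
                * np.exp2(betas[:, None] * ords[None, :] + u))
        counts = _nb_draw(rng, mean, dispersion)
        max_mats[assay] = pd.DataFrame(counts, index=ids, columns=sample_ids)
        frac = rng.uniform(0.2, 0.8, size=(n_p, n_s))
        avg_mats[assay] = pd.DataFrame(counts * frac, index=ids,
                                       columns=sample_ids)
        bg_vals = _nb_draw(
            rng, bg_mean * np.tile(depth_factors, (n_bg_values, 1)), dispersion
        )
        bg[assay] = pd.DataFrame(bg_vals, columns=sample_ids)

    truth.params.update({
        "base_mean": base_mean, "dispersion": dispersion,
        "culture_sd": culture_sd, "depth_factor_sd": depth_factor_sd,
        "bg_mean": bg_mean, "n_bg_values": n_bg_values,
        "peak_mean_sd": peak_mean_sd, "motif_g4_boost": motif_g4_boost,
        "coverage_seed": int(seed),
        "sample_ids": sample_ids,
    })
    return max_mats, avg_mats, bg, truth


@dataclass
class StudyData:
    """Everything one synthetic run produces, in memory."""

    genome: dict[str, str]
    peaks: dict[str, PeakSet]
    transcripts: list[TranscriptModel]
    samples: list[SampleMeta]
    max_depth: dict[str, pd.DataFrame]
    avg_depth: dict[str, pd.DataFrame]
    background: dict[str, pd.DataFrame]
    truth: SyntheticTruth


def simulate_study(seed: int = 0, n_chrom: int = 2,
                   chrom_length: int = 1_400_000, planted_motifs: int = 100,
                   n_genes: int = 120, n_peaks: int = 600,
                   replicates: int = 2, ages=DEFAULT_AGES,
                   **coverage_kwargs) -> StudyData:
    """One-call synthetic study under the default design."""
    ss = np.random.SeedSequence(seed)
    s_genome, s_peaks, s_cov = (int(c.generate_state(1)[0] % (2**31))
                                for c in ss.spawn(3))
    genome, truth = simulate_genome(
        n_chrom=n_chrom, chrom_length=chrom_length,
        planted_motifs=planted_motifs, seed=s_genome,
    )
    peaks, transcripts, truth = simulate_peaks_and_transcripts(
        genome, n_genes=n_genes, n_peaks=n_peaks, truth=truth, seed=s_peaks,
    )
    samples = default_samples(ages=ages, replicates=replicates)
    max_d, avg_d, bg, truth = simulate_coverage(
        peaks, samples, truth, seed=s_cov, **coverage_kwargs,
    )
    truth.params["seed"] = int(seed)
    return StudyData(genome, peaks, transcripts, samples, max_d, avg_d, bg,
                     truth)
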