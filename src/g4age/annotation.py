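"""Hierarchical genomic annotation of peaks and canonical G4 motif detection.

Peaks are assigned a single category from a fixed precedence hierarchy
(first_exon > promoter > exon > utr5 > utr3 > intron > downstream >
intergenic) over strand-aware features built from transcript models. G4
motif scanning uses the canonical pattern of four runs of >=3 guanines
separated by loops of 1-7 arbitrary nucleotides; peaks are expanded
(slopped) by 15 bp on each side before sequence extraction so motifs
straddling a peak edge are still detected.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .io_model import Genome, Peak, PeakSet, TranscriptModel

CATEGORIES = (
    "first_exon", "promoter", "exon", "utr5", "utr3",
    "intron", "downstream", "intergenic",
)
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}

G4_PATTERN = re.compile(r"G{3,}[ATGC]{1,7}G{3,}[ATGC]{1,7}G{3,}[ATGC]{1,7}G{3,}")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int
    end: int
    category: str
    gene_name: str
    transcript_id: str


@dataclass
class FeatureIndex:
    """Per-chromosome sorted feature lists with a max-end prefix for lookup."""

    features: dict[str, list[Feature]] = field(default_factory=dict)
    tss: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    promoter_up: int = 2500
    promoter_down: int = 250
    downstream_len: int = 3000

    def overlapping(self, chrom: str, start: int, end: int) -> list[Feature]:
        feats = self.features.get(chrom, [])
        # features sorted by start; linear scan bounded by binary search on start
        hi = bisect_left([f.start for f in feats], end)
        return [f for f in feats[:hi] if f.end > start]


def transcript_features(t: TranscriptModel, chrom_length: int | None = None,
                        promoter_up: int = 2500, promoter_down: int = 250,
                        downstream_len: int = 3000) -> list[Feature]:
    """Strand-aware features of one transcript, clipped at chromosome bounds.

    The promoter spans promoter_up bp upstream through promoter_down bp
    downstream of the TSS; first_exon is the 5'-most exon; when CDS bounds
    are present, exon features cover only coding exon portions and the UTR
    features the non-coding exon portions (otherwise full exons and no
    UTRs); introns are the gaps between exons; downstream extends
    downstream_len bp past the 3' end.
    """
    feats: list[tuple[int, int, str]] = []
    if t.strand == "+":
        feats.append((t.tx_start - promoter_up, t.tx_start + promoter_down,
                      "promoter"))
        feats.append((t.tx_end, t.tx_end + downstream_len, "downstream"))
        first = t.exons[0]
    else:
        feats.append((t.tx_end - promoter_down, t.tx_end + promoter_up,
                      "promoter"))
        feats.append((t.tx_start - downstream_len, t.tx_start, "downstream"))
        first = t.exons[-1]
    feats.append((first[0], first[1], "first_exon"))

    if t.coding:
        cs, ce = t.cds_start, t.cds_end
        left_utr = "utr5" if t.strand == "+" else "utr3"
        right_utr = "utr3" if t.strand == "+" else "utr5"
        for s, e in t.exons:
            if s < cs:
                feats.append((s, min(e, cs), left_utr))
            if e > ce:
                feats.append((max(s, ce), e, right_utr))
            cods, code = max(s, cs), min(e, ce)
            if cods < code:
                feats.append((cods, code, "exon"))
    else:
        for s, e in t.exons:
            feats.append((s, e, "exon"))

    for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
        if e1 < s2:
            feats.append((e1, s2, "intron"))

    out = []
    for s, e, cat in feats:
        s = max(0, s)
        if chrom_length is not None:
            e = min(e, chrom_length)
        if s < e:
            out.append(Feature(t.chrom, s, e, cat, t.gene_name, t.transcript_id))
    return out


def build_feature_index(transcripts: Iterable[TranscriptModel],
                        chrom_sizes: dict[str, int] | None = None,
                        promoter_up: int = 2500, promoter_down: int = 250,
                        downstream_len: int = 3000) -> FeatureIndex:
    idx = FeatureIndex(promoter_up=promoter_up, promoter_down=promoter_down,
                       downstream_len=downstream_len)
    for t in transcripts:
        clen = chrom_sizes.get(t.chrom) if chrom_sizes else None
        for f in transcript_features(t, clen, promoter_up, promoter_down,
                                     downstream_len):
            idx.features.setdefault(f.chrom, []).append(f)
        idx.tss.setdefault(t.chrom, []).append((t.tss, t.gene_name))
    for chrom in idx.features:
        idx.features[chrom].sort(key=lambda f: (f.start, f.end))
    for chrom in idx.tss:
        idx.tss[chrom].sort()
    return idx


def annotate_peak(peak: Peak, index: FeatureIndex) -> str:
    """Single highest-priority category among all overlapped features."""
    best = "intergenic"
    for f in index.overlapping(peak.chrom, peak.start, peak.end):
        if _PRIORITY[f.category] < _PRIORITY[best]:
            best = f.category
    return best


def _overlapping_genes(peak: Peak, index: FeatureIndex) -> str | None:
    """Gene of the highest-priority overlapped feature (ties: lexicographic)."""
    best: tuple[int, str] | None = None
    for f in index.overlapping(peak.chrom, peak.start, peak.end):
        key = (_PRIORITY[f.category], f.gene_name)
        if best is None or key < best:
            best = key
    return None if best is None else best[1]


def tss_context(peak: Peak, index: FeatureIndex) -> dict:
    """Distances and gene names of the nearest TSS left and right of the peak.

    Upstream/downstream are genomic left/right, not strand-relative. A TSS
    inside the peak gives distance 0 on both sides. Ties between equidistant
    genes are broken lexicographically by gene name.
    """
    out = {
        "tss_distance_upstream": None, "tss_distance_downstream": None,
        "gene_upstream": None, "gene_downstream": None,
    }
    tss_list = index.tss.get(peak.chrom)
    if not tss_list:
        return out

    inside = sorted(
        (g for pos, g in tss_list if peak.start <= pos < peak.end)
    )
    if inside:
        out.update(
            tss_distance_upstream=0, tss_distance_downstream=0,
            gene_upstream=inside[0], gene_downstream=inside[0],
        )
        return out

    left = [(peak.start - pos, g) for pos, g in tss_list if pos < peak.start]
    right = [(pos - peak.end, g) for pos, g in tss_list if pos >= peak.end]
    if left:
        d, g = min(left)
        out["tss_distance_upstream"], out["gene_upstream"] = d, g
    if right:
        d, g = min(right)
        out["tss_distance_downstream"], out["gene_downstream"] = d, g
    return out


def enrichment_gene(category: str, ctx: dict, overlapped: str | None) -> str | None:
    """Gene assigned for enrichment: the overlapped gene for genic peaks,
    else the nearer of the flanking genes (lexicographic tie-break)."""
    if category != "intergenic" and overlapped is not None:
        return overlapped
    du, dd = ctx["tss_distance_upstream"], ctx["tss_distance_downstream"]
    gu, gd = ctx["gene_upstream"], ctx["gene_downstream"]
    cand = [(d, g) for d, g in ((du, gu), (dd, gd)) if d is not None]
    return min(cand)[1] if cand else None


def slop(start: int, end: int, pad: int = 15,
         chrom_length: int | None = None) -> tuple[int, int]:
    """Expand an interval by pad bp on each side, clipped to [0, chrom_length)."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    s = max(0, start - pad)
    e = end + pad
    if chrom_length is not None:
        e = min(e, chrom_length)
    return s, e


def scan_g4_motifs(sequence: str) -> tuple[int, list[tuple[int, int]]]:
    """Count non-overlapping canonical G4 motif matches, left to right.

    Matches use greedy quantifier semantics of the canonical pattern
    ``G{3,}[ATGC]{1,7}G{3,}[ATGC]{1,7}G{3,}[ATGC]{1,7}G{3,}``; N never
    matches. Spans are 0-based half-open in local coordinates.
    """
    spans = [m.span() for m in G4_PATTERN.finditer(sequence.upper())]
    return len(spans), spans


def annotate_canonical_g4(peaks: PeakSet, genome: Genome, pad: int = 15,
                          both_strands: bool = True) -> pd.DataFrame:
    """Flag peaks containing >=1 canonical G4 motif in their slopped sequence.

    By default both the given strand and its reverse complement are scanned
    and the counts summed; ``both_strands=False`` restricts to the forward
    strand as given.
    """
    sizes = genome.chrom_sizes
    rows = []
    for p in peaks:
        s, e = slop(p.start, p.end, pad, sizes.get(p.chrom))
        seq = genome.fetch(p.chrom, s, e)
        n, _ = scan_g4_motifs(seq)
        if both_strands:
            n_rc, _ = scan_g4_motifs(reverse_complement(seq))
            n += n_rc
        rows.append((p.peak_id, n >= 1, n))
    return pd.DataFrame(rows, columns=["peak_id", "canonical_g4", "motif_count"])


def annotate_peaks(peaks: PeakSet, index: FeatureIndex,
                   genome: Genome | None = None, pad: int = 15,
                   both_strands: bool = True) -> pd.DataFrame:
    """Full annotation table: category, TSS context, enrichment gene and,
    when a genome is supplied, canonical G4 flags."""
    rows = []
    for p in peaks:
        cat = annotate_peak(p, index)
        ctx = tss_context(p, index)
        gene = enrichment_gene(cat, ctx, _overlapping_genes(p, index))
        rows.append(
            {
                "peak_id": p.peak_id, "category": cat,
                "tss_distance_upstream": ctx["tss_distance_upstream"],
                "tss_distance_downstream": ctx["tss_distance_downstream"],
                "gene_upstream": ctx["gene_upstream"],
                "gene_downstream": ctx["gene_downstream"],
                "enrichment_gene": gene,
            }
        )
    df = pd.DataFrame(rows)
    if genome is not None:
        g4 = annotate_canonical_g4(peaks, genome, pad, both_strands)
        df = df.merge(g4, on="peak_id")
    return df
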