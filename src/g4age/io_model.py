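"""Core domain types and readers/writers for the genomic formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) everywhere in the
package. Peaks are unstranded; transcripts require a strand. Exons are stored
in ascending genomic order regardless of strand; strand-aware notions such as
"first exon" are resolved at annotation time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
from pyfaidx import Fasta

ASSAYS = ("ATAC", "G4Q")
CONDITIONS = ("none", "control", "DDX5_KD")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak with assay provenance and optional summit offset."""

    interval: GenomicInterval
    peak_id: str
    assay: str = "ATAC"
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak {self.peak_id}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class PeakSet:
    """An ordered, id-unique collection of peaks (sorted by chrom, start)."""

    peaks: list[Peak] = field(default_factory=list)
    genome_id: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate peak_id {dup!r} in PeakSet")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    @property
    def ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]

    def by_id(self) -> dict[str, Peak]:
        return {p.peak_id: p for p in self.peaks}


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with exon structure and optional CDS bounds.

    ``exons`` are (start, end) pairs in ascending genomic order, each within
    [tx_start, tx_end) and pairwise non-overlapping. ``cds_start``/``cds_end``
    equal to each other signals a non-coding transcript (no UTR features).
    """

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"transcript {self.transcript_id}: invalid tx bounds")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(
                    f"transcript {self.transcript_id}: exon ({s},{e}) outside "
                    f"[{self.tx_start},{self.tx_end})"
                )
            if s < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons unsorted/overlapping"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def coding(self) -> bool:
        return (
            self.cds_start is not None
            and self.cds_end is not None
            and self.cds_start < self.cds_end
        )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    culture_id: str
    age_years: int
    condition: str = "none"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")


def validate_samples(samples: Sequence[SampleMeta]) -> None:
    """Check sample-table invariants: unique ids, one age per culture."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample table")
    ages: dict[str, int] = {}
    for s in samples:
        if ages.setdefault(s.culture_id, s.age_years) != s.age_years:
            raise ValueError(
                f"culture {s.culture_id} has inconsistent ages"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_intervals(path: str | os.PathLike, format: str = "BED",
                   assay: str = "ATAC", genome_id: str = "") -> PeakSet:
    """Read a BED (>=3 columns) or MACS2 narrowPeak (10 columns) file.

    narrowPeak column 10 (0-based summit offset; -1 = absent) becomes
    ``summit_offset``. Ids are taken from column 4 when present, otherwise
    auto-generated as ``peak_<n>`` in file order.
    """
    if format not in ("BED", "narrowPeak"):
        raise ValueError(f"unknown format {format!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            min_cols = 10 if format == "narrowPeak" else 3
            if len(fields) < min_cols:
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected >= {min_cols} "
                    f"columns, got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed line {lineno}: {exc}"
                ) from None
            if start >= end:
                raise ValueError(f"{path}: start >= end at line {lineno}")
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") \
                else f"peak_{len(peaks) + 1}"
            summit: int | None = None
            if format == "narrowPeak":
                summit = int(fields[9])
                if summit == -1:
                    summit = None
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), name, assay, summit)
            )
    return PeakSet(peaks, genome_id=genome_id)


def write_intervals(peakset: PeakSet, path: str | os.PathLike,
                    format: str = "BED") -> None:
    """Write a PeakSet as BED4 or 10-column narrowPeak (round-trip safe)."""
    with open(path, "w") as fh:
        for p in peakset:
            if format == "BED":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")
            elif format == "narrowPeak":
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t"
                    f"0\t-1\t-1\t{summit}\n"
                )
            else:
                raise ValueError(f"unknown format {format!r}")


_REFFLAT_COLS = [
    "gene_name", "transcript_id", "chrom", "strand", "tx_start", "tx_end",
    "cds_start", "cds_end", "exon_count", "exon_starts", "exon_ends",
]


def read_transcripts(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read a tab-delimited refFlat-like transcript table.

    Columns: gene_name, transcript_id, chrom, strand, tx_start, tx_end,
    cds_start, cds_end, exon_count, exon_starts, exon_ends (the last two
    comma-separated, trailing comma tolerated).
    """
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: line {lineno}: expected 11 columns, got {len(fields)}"
                )
            gene, tid, chrom, strand = fields[:4]
            tx_start, tx_end = int(fields[4]), int(fields[5])
            cds_start, cds_end = int(fields[6]), int(fields[7])
            n_exon = int(fields[8])
            starts = [int(x) for x in fields[9].split(",") if x != ""]
            ends = [int(x) for x in fields[10].split(",") if x != ""]
            if len(starts) != n_exon or len(ends) != n_exon:
                raise ValueError(
                    f"{path}: line {lineno}: exon_count={n_exon} but "
                    f"{len(starts)} starts / {len(ends)} ends listed"
                )
            exons = tuple(zip(starts, ends))
            try:
                out.append(
                    TranscriptModel(
                        tid, gene, chrom, strand, tx_start, tx_end, exons,
                        cds_start=cds_start, cds_end=cds_end,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return out


def write_transcripts(transcripts: Iterable[TranscriptModel],
                      path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            cs = t.cds_start if t.cds_start is not None else t.tx_start
            ce = t.cds_end if t.cds_end is not None else t.tx_start
            starts = ",".join(str(s) for s, _ in t.exons) + ","
            ends = ",".join(str(e) for _, e in t.exons) + ","
            fh.write(
                f"{t.gene_name}\t{t.transcript_id}\t{t.chrom}\t{t.strand}\t"
                f"{t.tx_start}\t{t.tx_end}\t{cs}\t{ce}\t{len(t.exons)}\t"
                f"{starts}\t{ends}\n"
            )


class Genome:
    """FASTA-backed genome accessor returning uppercased sequence.

    Out-of-range requests are clipped to the chromosome bounds; an unknown
    chromosome raises ``KeyError``.
    """

    def __init__(self, path: str | os.PathLike):
        self._fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(self._fa[name]) for name in self._fa.keys()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fa:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self._fa[chrom])
        start = max(0, min(start, n))
        end = max(start, min(end, n))
        return str(self._fa[chrom][start:end])

    def close(self) -> None:
        self._fa.close()


def read_genome(path: str | os.PathLike) -> Genome:
    return Genome(path)


def read_sample_table(path: str | os.PathLike) -> list[SampleMeta]:
    """Read a CSV/TSV sample table (sample_id, culture_id, age_years, condition)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "culture_id": str})
    samples = [
        SampleMeta(
            str(r.sample_id), str(r.culture_id), int(r.age_years),
            str(getattr(r, "condition", "none")),
        )
        for r in df.itertuples(index=False)
    ]
    validate_samples(samples)
    return samples


def write_sample_table(samples: Sequence[SampleMeta],
                       path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "culture_id": [s.culture_id for s in samples],
            "age_years": [s.age_years for s in samples],
            "condition": [s.condition for s in samples],
        }
    ).to_csv(path, index=False)


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a peaks x samples matrix (first column peak_id, header = sample ids)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index_label="peak_id")
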