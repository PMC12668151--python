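"""Pipeline configuration: every tunable with its default, strict round trip.

Defaults mirror the analysis conventions the pipeline implements: log
offset 0.1, 20% trimmed-mean normalization, 15 bp slop before motif
scanning, promoters -2500/+250 around the TSS, 3 kb downstream windows,
refinement thresholds 0.5 / M >= 1.0 / A >= 0.25 / log2(G4Q) >= 3.0,
moderate-abundance presence cutoffs 5 (ATAC, normalized) and 2 (G4, raw),
70% shrinkage confidence, quadrant thresholds 0.25 (knockdown) and 0.05
(age), ORA set sizes 50-200 and GSEA set sizes 40-350, FDR ladder 0.1-0.001.
Unknown keys are rejected; ``to_dict``/``from_dict`` round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0

    # synthetic study
    n_chrom: int = 2
    chrom_length: int = 1_400_000
    gc_fraction: float = 0.41
    planted_motifs: int = 100
    n_genes: int = 120
    n_peaks: int = 600
    peak_width: int = 300
    motif_peak_fraction: float = 0.25
    null_fraction: float = 0.8
    beta_step: float = 0.2
    replicates: int = 2
    base_mean: float = 50.0
    dispersion: float = 10.0
    culture_sd: float = 0.25
    depth_factor_sd: float = 0.3
    bg_mean: float = 4.0
    n_bg_values: int = 2000
    peak_mean_sd: float = 0.5
    motif_g4_boost: float = 1.0
    n_gene_sets: int = 25
    gene_set_size: int = 60

    # coverage / normalization / presence
    trim_fraction: float = 0.20
    atac_presence_threshold: float = 5.0
    g4_presence_threshold: float = 2.0
    bg_region_count: int = 5000
    bg_region_length: int = 1000

    # annotation
    promoter_up: int = 2500
    promoter_down: int = 250
    downstream_len: int = 3000
    slop_pad: int = 15
    scan_both_strands: bool = True

    # refinement
    signal_min: float = 0.5
    m_min: float = 1.0
    a_min: float = 0.25
    hc_log2_g4: float = 3.0

    # differential
    offset: float = 0.1
    span: float = 0.5
    use_weights: bool = True
    use_block_correlation: bool = True

    # integration
    confidence: float = 0.70
    quadrant_threshold_age: float = 0.05
    quadrant_threshold_kd: float = 0.25
    fdr_cutoffs: tuple[float, ...] = (0.1, 0.05, 0.01, 0.005, 0.001)
    fdr_max: float = 0.10

    # enrichment
    enrich_p_cut: float = 0.05
    ora_min_size: int = 50
    ora_max_size: int = 200
    gsea_min_size: int = 40
    gsea_max_size: int = 350
    n_perm: int = 1000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fdr_cutoffs"] = list(d["fdr_cutoffs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        d = dict(d)
        if "fdr_cutoffs" in d:
            d["fdr_cutoffs"] = tuple(d["fdr_cutoffs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
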