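"""End-to-end pipeline stages over a working directory.

Each stage reads the files earlier stages wrote under one working
directory, computes its module's outputs, writes them as CSV/JSON, and
records them (with checksums) in a run manifest. The stages are thin
orchestration over the library modules; the CLI and the analysis scripts
both drive these functions. All outputs are deterministic given the
configured seed (the manifest carries no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import annotate_peaks, build_feature_index
from .config import PipelineConfig
from .coverage import (
    compute_normalization, filter_peaks, intersection_counts,
    presence_matrix, replicate_summary, summarize_study_coverage,
)
from .differential import run_differential
from .enrichment import (
    GeneSetCollection, gsea_by_context, ora, read_gmt, split_contexts,
    write_gmt,
)
from .integration import (
    classify_quadrant, count_by_fdr, select_top_and_zscore, shrink_table,
)
from .io_model import (
    read_genome, read_intervals, read_matrix, read_sample_table,
    read_transcripts, write_intervals, write_matrix, write_sample_table,
    write_transcripts,
)
from .refinement import motif_enrichment_fold, refine_g4_peaks
from .synthetic import simulate_study

ASSAYS = ("ATAC", "G4Q")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def update_manifest(workdir: Path, stage: str, files: list[Path],
                    cfg: PipelineConfig) -> None:
    mpath = workdir / "manifest.json"
    manifest = {}
    if mpath.exists():
        with open(mpath) as fh:
            manifest = json.load(fh)
    manifest.update(
        version=__version__, seed=cfg.seed, config=cfg.to_dict(),
        config_hash=_config_hash(cfg),
    )
    stages = manifest.setdefault("stages", {})
    stages[stage] = {
        "outputs": {p.name: _sha256(p) for p in sorted(files)},
    }
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _float_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, index=False, float_format="%.10g", **kw)


def stage_simulate(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    """Generate the synthetic study and write all its inputs + truth."""
    workdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(
        seed=cfg.seed, n_chrom=cfg.n_chrom, chrom_length=cfg.chrom_length,
        planted_motifs=cfg.planted_motifs, n_genes=cfg.n_genes,
        n_peaks=cfg.n_peaks, replicates=cfg.replicates,
        base_mean=cfg.base_mean, dispersion=cfg.dispersion,
        culture_sd=cfg.culture_sd, depth_factor_sd=cfg.depth_factor_sd,
        bg_mean=cfg.bg_mean, n_bg_values=cfg.n_bg_values,
        peak_mean_sd=cfg.peak_mean_sd, motif_g4_boost=cfg.motif_g4_boost,
    )
    from .synthetic import write_fasta

    files: list[Path] = []

    def _reg(p: Path) -> Path:
        files.append(p)
        return p

    write_fasta(study.genome, _reg(workdir / "genome.fa"))
    write_transcripts(study.transcripts,
                      _reg(workdir / "transcripts.refflat"))
    write_sample_table(study.samples, _reg(workdir / "samples.csv"))
    for assay in ASSAYS:
        write_intervals(study.peaks[assay],
                        _reg(workdir / f"peaks_{assay}.bed"))
        write_matrix(study.max_depth[assay],
                     _reg(workdir / f"max_depth_{assay}.csv"))
        write_matrix(study.avg_depth[assay],
                     _reg(workdir / f"avg_depth_{assay}.csv"))
        study.background[assay].to_csv(
            _reg(workdir / f"background_{assay}.csv"), index=False
        )
    study.truth.to_json(_reg(workdir / "truth.json"))

    # decoy gene sets drawn from the simulated gene universe
    rng = np.random.default_rng(cfg.seed + 17)
    genes = sorted({t.gene_name for t in study.transcripts})
    sets = {}
    for i in range(cfg.n_gene_sets):
        size = min(cfg.gene_set_size, len(genes))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"SET_{i + 1:03d}"] = frozenset(members.tolist())
    write_gmt(GeneSetCollection(sets), _reg(workdir / "gene_sets.gmt"))

    update_manifest(workdir, "simulate", files, cfg)
    return files


def stage_coverage(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    """Normalization factors, coverage summaries, presence, intersections."""
    samples = read_sample_table(workdir / "samples.csv")
    files: list[Path] = []
    summaries = []
    for assay in ASSAYS:
        peaks = read_intervals(workdir / f"peaks_{assay}.bed", assay=assay)
        peaks = filter_peaks(
            peaks, allowed_chroms={p.chrom for p in peaks}
        )
        max_d = read_matrix(workdir / f"max_depth_{assay}.csv")
        avg_d = read_matrix(workdir / f"avg_depth_{assay}.csv")
        bg = pd.read_csv(workdir / f"background_{assay}.csv")
        bg_values = {
            (sid, assay): bg[sid].to_numpy(dtype=float) for sid in bg.columns
        }
        factors = compute_normalization(bg_values, cfg.trim_fraction)
        summary = summarize_study_coverage(peaks, assay, samples, max_d,
                                           avg_d, factors)
        summaries.append(summary)
        norm = summary.pivot(index="peak_id", columns="sample_id",
                             values="norm_depth")
        norm = norm[[s.sample_id for s in samples]]
        p = workdir / f"norm_{assay}.csv"
        norm.to_csv(p, index_label="peak_id", float_format="%.10g")
        files.append(p)

    all_summary = pd.concat(summaries, ignore_index=True)
    p = workdir / "coverage_summary.csv"
    _float_csv(all_summary, p)
    files.append(p)

    rep = replicate_summary(all_summary, samples)
    p = workdir / "replicate_summary.csv"
    _float_csv(rep, p)
    files.append(p)

    presence = presence_matrix(rep, cfg.atac_presence_threshold,
                               cfg.g4_presence_threshold)
    for assay, mat in presence.items():
        p = workdir / f"presence_{assay}.csv"
        mat.to_csv(p, index_label="peak_id")
        files.append(p)
        p = workdir / f"intersections_{assay}.csv"
        _float_csv(intersection_counts(mat), p)
        files.append(p)

    update_manifest(workdir, "coverage", files, cfg)
    return files


def stage_annotate(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    """Hierarchical annotation + canonical G4 flags over the shared universe."""
    genome = read_genome(workdir / "genome.fa")
    transcripts = read_transcripts(workdir / "transcripts.refflat")
    index = build_feature_index(
        transcripts, genome.chrom_sizes, promoter_up=cfg.promoter_up,
        promoter_down=cfg.promoter_down, downstream_len=cfg.downstream_len,
    )
    peaks = read_intervals(workdir / "peaks_ATAC.bed", assay="ATAC")
    ann = annotate_peaks(peaks, index, genome, pad=cfg.slop_pad,
                         both_strands=cfg.scan_both_strands)
    p = workdir / "annotation.csv"
    _float_csv(ann, p)
    update_manifest(workdir, "annotate", [p], cfg)
    return [p]


def stage_refine(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    """M/A refinement of the G4 peak calls and the motif-enrichment readout."""
    rep = pd.read_csv(workdir / "replicate_summary.csv")
    global_rep = rep.drop_duplicates(["peak_id", "assay"])
    wide = global_rep.pivot(index="peak_id", columns="assay",
                            values="mean_norm")
    summary = pd.DataFrame({
        "peak_id": wide.index,
        "atac_mean_norm": wide["ATAC"].to_numpy(),
        "g4_mean_norm": wide["G4Q"].to_numpy(),
    }).reset_index(drop=True)
    refined = refine_g4_peaks(summary, m_min=cfg.m_min, a_min=cfg.a_min,
                              signal_min=cfg.signal_min,
                              hc_log2_g4=cfg.hc_log2_g4)
    p = workdir / "refinement.csv"
    _float_csv(refined, p)
    files = [p]

    ann = pd.read_csv(workdir / "annotation.csv")
    stats = {
        "n_peaks": int(len(refined)),
        "n_signal_pass": int((refined["tier"] == "signal_pass").sum()),
        "n_ma_pass": int((refined["tier"] == "ma_pass").sum()),
        "n_excluded": int((refined["tier"] == "excluded").sum()),
        "n_high_confidence": int(refined["high_confidence"].sum()),
    }
    fold = motif_enrichment_fold(refined,
                                 ann[["peak_id", "canonical_g4"]])
    stats["motif_enrichment_fold"] = None if np.isnan(fold) else float(fold)
    p = workdir / "refinement_stats.json"
    with open(p, "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
    files.append(p)
    update_manifest(workdir, "refine", files, cfg)
    return files


def stage_diff(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    """Ordinal-age moderated regression per assay."""
    samples = read_sample_table(workdir / "samples.csv")
    files: list[Path] = []
    for assay in ASSAYS:
        norm = read_matrix(workdir / f"norm_{assay}.csv")
        res, info = run_differential(
            norm, samples, offset=cfg.offset, span=cfg.span,
            use_weights=cfg.use_weights,
            use_block_correlation=cfg.use_block_correlation,
        )
        p = workdir / f"diff_{assay}.csv"
        _float_csv(res, p)
        files.append(p)
        p = workdir / f"diff_{assay}_info.json"
        with open(p, "w") as fh:
            json.dump(info, fh, indent=1, sort_keys=True, default=str)
        files.append(p)
    update_manifest(workdir, "diff", files, cfg)
    return files


def stage_integrate(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    """Shrinkage, quadrant classification, FDR-ladder counts, top-peak z-scores."""
    files: list[Path] = []
    shrunk = {}
    for assay in ASSAYS:
        res = pd.read_csv(workdir / f"diff_{assay}.csv")
        sh = shrink_table(res, confidence=cfg.confidence)
        shrunk[assay] = sh
        p = workdir / f"shrunk_{assay}.csv"
        _float_csv(sh, p)
        files.append(p)
        p = workdir / f"fdr_counts_{assay}.csv"
        _float_csv(count_by_fdr(res, cfg.fdr_cutoffs), p)
        files.append(p)

        norm = read_matrix(workdir / f"norm_{assay}.csv")
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            z = select_top_and_zscore(res, norm, fdr_max=cfg.fdr_max)
        p = workdir / f"zscore_top_{assay}.csv"
        z.to_csv(p, index_label="peak_id", float_format="%.10g")
        files.append(p)

    merged = shrunk["ATAC"].merge(
        shrunk["G4Q"], on="peak_id", suffixes=("_atac", "_g4")
    )
    quad = classify_quadrant(
        merged["shrunk_logfc_atac"], merged["shrunk_logfc_g4"],
        threshold=cfg.quadrant_threshold_age, label_prefix="Age",
    )
    quad.insert(0, "peak_id", merged["peak_id"].to_numpy())
    quad["shrunk_atac"] = merged["shrunk_logfc_atac"].to_numpy()
    quad["shrunk_g4"] = merged["shrunk_logfc_g4"].to_numpy()
    p = workdir / "quadrants.csv"
    _float_csv(quad, p)
    files.append(p)
    update_manifest(workdir, "integrate", files, cfg)
    return files


def stage_enrich(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    """Context-split ORA and preranked GSEA with Fisher combination."""
    ann = pd.read_csv(workdir / "annotation.csv")
    collection = read_gmt(workdir / "gene_sets.gmt")
    files: list[Path] = []
    for assay in ASSAYS:
        res = pd.read_csv(workdir / f"diff_{assay}.csv")
        lists = split_contexts(res, ann, p_cut=cfg.enrich_p_cut)
        ora_df = ora(lists, collection,
                     size_limits=(cfg.ora_min_size, cfg.ora_max_size))
        p = workdir / f"ora_{assay}.csv"
        _float_csv(ora_df, p)
        files.append(p)
        gsea_df = gsea_by_context(
            lists, collection, n_perm=cfg.n_perm, seed=cfg.seed + 29,
            size_limits=(cfg.gsea_min_size, cfg.gsea_max_size),
        )
        p = workdir / f"gsea_{assay}.csv"
        _float_csv(gsea_df, p)
        files.append(p)
    update_manifest(workdir, "enrich", files, cfg)
    return files


STAGES = {
    "simulate": stage_simulate,
    "coverage": stage_coverage,
    "annotate": stage_annotate,
    "refine": stage_refine,
    "diff": stage_diff,
    "integrate": stage_integrate,
    "enrich": stage_enrich,
}

STAGE_ORDER = ["simulate", "coverage", "annotate", "refine", "diff",
               "integrate", "enrich"]


def run_all(cfg: PipelineConfig, workdir: Path) -> list[Path]:
    """Chain every stage on the synthetic study under one seed."""
    files: list[Path] = []
    for name in STAGE_ORDER:
        files.extend(STAGES[name](cfg, Path(workdir)))
    return files
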