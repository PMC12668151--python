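"""Reusable synthetic-study experiments: calibration, recovery, enrichment.

These drivers wire the generator to the analysis modules under the default
study design (8 cultures aged 22-73, 2 replicates, two assays) and measure
the quantities the pipeline's validity rests on: type-I error calibration,
planted-slope recovery, false-discovery control, quadrant-label recovery,
and the motif-enrichment readout of G4 peak refinement. The analysis
scripts, the test suite and the acceptance script all run these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import annotate_canonical_g4
from .differential import run_differential
from .integration import classify_quadrant, shrink_table
from .io_model import Genome, GenomicInterval, Peak, PeakSet
from .refinement import motif_enrichment_fold, refine_g4_peaks
from .synthetic import (
    SyntheticTruth, default_samples, plant_effects, simulate_coverage,
    simulate_study,
)

STATE_TO_CATEGORY = {
    ("gain", "gain"): "ATAC_gain|G4_gain",
    ("gain", "loss"): "ATAC_gain|G4_loss",
    ("loss", "gain"): "ATAC_loss|G4_gain",
    ("loss", "loss"): "ATAC_loss|G4_loss",
}


def _toy_peaks(n: int, assays=("ATAC", "G4Q")) -> dict[str, PeakSet]:
    return {a: PeakSet([
        Peak(GenomicInterval("chr1", 1000 * i, 1000 * i + 300),
             f"pk{i:05d}", a) for i in range(n)
    ]) for a in assays}


def _norm_matrix(max_depth: pd.DataFrame, bg: pd.DataFrame) -> pd.DataFrame:
    """Quick per-sample normalization by the reciprocal mean background."""
    return max_depth * (1.0 / bg.mean())


def null_calibration(n_peaks: int = 5000, seed: int = 0) -> dict:
    """Fraction of null peaks with p < 0.05 under the fully null design
    (no planted effects, no culture random effect)."""
    ids = [f"pk{i:05d}" for i in range(n_peaks)]
    peaks = _toy_peaks(n_peaks, assays=("ATAC",))
    truth = SyntheticTruth(peak_effects=plant_effects(ids, null_fraction=1.0))
    samples = default_samples()
    mx, _, bg, _ = simulate_coverage(peaks, samples, truth, culture_sd=0.0,
                                     seed=seed)
    res, info = run_differential(_norm_matrix(mx["ATAC"], bg["ATAC"]),
                                 samples)
    return {
        "fraction_p_lt_05": float((res["p_value"] < 0.05).mean()),
        "consensus_correlation": info["consensus_correlation"],
        "n": n_peaks,
    }


def slope_recovery(n_peaks: int = 2000, beta_step: float = 0.2,
                   null_fraction: float = 0.8, seed: int = 0) -> dict:
    """Mean bias of recovered ordinal-age slopes at planted peaks (percent
    of the planted effect size) plus within-2-SE coverage."""
    ids = [f"pk{i:05d}" for i in range(n_peaks)]
    peaks = _toy_peaks(n_peaks, assays=("ATAC",))
    truth = SyntheticTruth(peak_effects=plant_effects(
        ids, null_fraction=null_fraction, beta_step=beta_step, rng=seed + 1
    ))
    samples = default_samples()
    mx, _, bg, _ = simulate_coverage(peaks, samples, truth, seed=seed)
    res, _ = run_differential(_norm_matrix(mx["ATAC"], bg["ATAC"]), samples)
    res = res.set_index("peak_id")
    planted = [pid for pid in ids
               if truth.peak_effects[pid].category != "null"]
    signed = np.array([
        res.loc[pid, "logFC"] * np.sign(truth.peak_effects[pid].beta_atac)
        for pid in planted
    ])
    se = res.loc[planted, "ordinary_se"].to_numpy()
    truth_beta = np.array([abs(truth.peak_effects[pid].beta_atac)
                           for pid in planted])
    within = np.abs(signed - truth_beta) <= 2 * se
    return {
        "mean_bias_pct": float(100 * (signed.mean() - beta_step) / beta_step),
        "within_2se_fraction": float(within.mean()),
        "n": len(planted),
    }


def fdr_control(n_seeds: int = 20, n_peaks: int = 2000,
                fdr_cut: float = 0.10, seed: int = 0) -> dict:
    """Observed false-discovery proportion at BH 10%, averaged over seeds,
    with 20% of peaks carrying planted effects."""
    samples = default_samples()
    fdps, n_disc = [], 0
    for s in range(n_seeds):
        ids = [f"pk{i:05d}" for i in range(n_peaks)]
        peaks = _toy_peaks(n_peaks, assays=("ATAC",))
        truth = SyntheticTruth(peak_effects=plant_effects(
            ids, null_fraction=0.8, beta_step=0.2, rng=seed + 1000 + s
        ))
        mx, _, bg, _ = simulate_coverage(peaks, samples, truth,
                                         seed=seed + 2000 + s)
        res, _ = run_differential(_norm_matrix(mx["ATAC"], bg["ATAC"]),
                                  samples)
        res = res.set_index("peak_id")
        disc = res.index[res["fdr"] <= fdr_cut]
        if len(disc) == 0:
            continue
        false = sum(truth.peak_effects[pid].category == "null"
                    for pid in disc)
        fdps.append(false / len(disc))
        n_disc += len(disc)
    return {
        "mean_fdp": float(np.mean(fdps)) if fdps else float("nan"),
        "n_seeds": n_seeds,
        "n": n_disc,
    }


def quadrant_recovery(n_peaks: int = 2000, beta_step: float = 0.2,
                      threshold: float = 0.05, fdr_cut: float = 0.10,
                      confidence: float = 0.70, seed: int = 0) -> dict:
    """Fraction of planted non-null peaks, significant in both assays at
    the FDR cut, whose shrunk-effect quadrant label matches the truth."""
    ids = [f"pk{i:05d}" for i in range(n_peaks)]
    peaks = _toy_peaks(n_peaks)
    truth = SyntheticTruth(peak_effects=plant_effects(
        ids, null_fraction=0.8, beta_step=beta_step, rng=seed + 1
    ))
    samples = default_samples()
    mx, _, bg, _ = simulate_coverage(peaks, samples, truth, seed=seed)
    per_assay = {}
    for assay in ("ATAC", "G4Q"):
        res, _ = run_differential(_norm_matrix(mx[assay], bg[assay]),
                                  samples)
        sh = shrink_table(res, confidence=confidence).set_index("peak_id")
        per_assay[assay] = (res.set_index("peak_id"), sh)
    quad = classify_quadrant(
        per_assay["ATAC"][1]["shrunk_logfc"].loc[ids],
        per_assay["G4Q"][1]["shrunk_logfc"].loc[ids],
        threshold=threshold,
    )
    quad.index = ids
    selected = [
        pid for pid in ids
        if truth.peak_effects[pid].category != "null"
        and per_assay["ATAC"][0].loc[pid, "fdr"] <= fdr_cut
        and per_assay["G4Q"][0].loc[pid, "fdr"] <= fdr_cut
    ]
    if not selected:
        return {"recovery_rate": float("nan"), "n": 0}
    correct = sum(
        STATE_TO_CATEGORY.get(
            (quad.loc[pid, "atac_state"], quad.loc[pid, "g4_state"])
        ) == truth.peak_effects[pid].category
        for pid in selected
    )
    return {"recovery_rate": float(correct / len(selected)),
            "n": len(selected)}


def motif_fold_experiment(seed: int = 0, motif_g4_boost: float = 8.0,
                          base_mean: float = 6.0,
                          tmp_fasta: str | None = None) -> dict:
    """Motif-enrichment fold of refinement on a study where G4 signal is
    boosted at motif-centered peaks (compact genome for speed)."""
    import tempfile

    study = simulate_study(
        seed=seed, n_chrom=1, chrom_length=200_000, planted_motifs=60,
        n_genes=8, n_peaks=200, base_mean=base_mean,
        motif_g4_boost=motif_g4_boost,
    )
    from .synthetic import write_fasta

    if tmp_fasta is None:
        with tempfile.TemporaryDirectory() as td:
            fa = f"{td}/genome.fa"
            write_fasta(study.genome, fa)
            ann = annotate_canonical_g4(study.peaks["G4Q"], Genome(fa))
    else:
        write_fasta(study.genome, tmp_fasta)
        ann = annotate_canonical_g4(study.peaks["G4Q"], Genome(tmp_fasta))
    mean_norm = {
        a: _norm_matrix(study.max_depth[a], study.background[a]).mean(axis=1)
        for a in ("ATAC", "G4Q")
    }
    summary = pd.DataFrame({
        "peak_id": mean_norm["ATAC"].index,
        "atac_mean_norm": mean_norm["ATAC"].to_numpy(),
        "g4_mean_norm": mean_norm["G4Q"].to_numpy(),
    })
    refined = refine_g4_peaks(summary)
    fold = motif_enrichment_fold(refined, ann)
    return {"fold": float(fold),
            "n_high_confidence": int(refined["high_confidence"].sum()),
            "n": len(summary)}


def gsea_null_calibration(n_sets: int = 1000, n_genes: int = 200,
                          set_size: int = 20, n_perm: int = 200,
                          seed: int = 0) -> dict:
    """Fraction of random decoy sets with empirical GSEA p < 0.05 under a
    random ranking (should sit near the nominal 0.05)."""
    from .enrichment import GeneSetCollection, preranked_gsea

    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    ranks = pd.Series(rng.normal(size=n_genes), index=genes)
    sets = {
        f"decoy{i:04d}": frozenset(
            rng.choice(genes, size=set_size, replace=False)
        )
        for i in range(n_sets)
    }
    out = preranked_gsea(ranks, GeneSetCollection(sets), n_perm=n_perm,
                         seed=seed + 1, size_limits=(2, n_genes - 1))
    return {"fraction_p_lt_05": float((out["p_gsea"] < 0.05).mean()),
            "n": int(len(out))}
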