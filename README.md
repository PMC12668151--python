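# g4age

Integrative analysis of chromatin accessibility (ATAC-seq) and
G-quadruplex occupancy (G4 CUT&Tag) across a donor-age series.

G-quadruplexes (G4s) are four-stranded DNA structures that form in G-rich
sequence and accumulate in aging cells; their occupancy can be mapped by
CUT&Tag with a structure-specific antibody and compared against open
chromatin from ATAC-seq. This package implements, as a tested and reusable
pipeline, the statistical machinery needed to ask how both signals change
with donor age in primary cell cultures (here modeled on human astrocytes
from eight donors aged 22–73): background-anchored coverage normalization,
hierarchical peak annotation, canonical G4 motif scanning, multi-step G4
peak refinement, ordinal-age moderated regression with a culture-level
random effect, conservative effect-size shrinkage with joint ATAC×G4
quadrant classification, and context-split gene-set enrichment. A
first-class synthetic-data generator plants known motifs and effect sizes
so every stage can be validated against ground truth.

It is aimed at computational biologists analyzing paired ATAC / CUT&Tag
peak matrices, and at anyone who wants a transparent, dependency-light
reference for these methods.

## The statistics at the core

* **Normalization.** Per sample, `norm_depth = max_depth × f` where
  `f = 1 / trimmed_mean₀.₂(background per-base coverage)` over sampled
  non-peak regions, making signal comparable across library depths.
* **G4 refinement (M/A filter).** With a = mean normalized ATAC and
  g = mean normalized G4 signal per peak:
  M = ½(log₂a + log₂g), A = ½(log₂g − log₂a). A peak is retained if
  a > 0.5 and g > 0.5, or failing that if M ≥ 1.0 and A ≥ 0.25; a final
  screen log₂(g) ≥ 3.0 defines high-confidence G4 loci. The readout is the
  fold-enrichment of canonical G4 motifs
  (`G{3,}[ATGC]{1,7}G{3,}[ATGC]{1,7}G{3,}[ATGC]{1,7}G{3,}`) among
  high-confidence peaks relative to the unfiltered set.
* **Ordinal-age regression.** y = ln(0.1 + norm_depth) is modeled per peak
  as y = β₀ + β₁·rank(age) + ε with inverse variance-trend (lowess)
  weights, a consensus intra-culture correlation ρ in generalized least
  squares, and empirical-Bayes variance moderation
  s̃² = (d₀s₀² + d·s²)/(d₀ + d) giving moderated t statistics; effects are
  reported as log₂ per ordinal-age step with BH FDR.
* **Shrinkage and quadrants.** z_obs = Φ⁻¹(1 − p/2) implies
  se = |lfc|/z_obs; the shrunk effect is
  sign(lfc)·max(0, |lfc| − z_c·se) with z_c the 70% two-sided normal
  quantile — the zero-clamped confidence bound. Shrunk ATAC and G4 effects
  are jointly labeled gain/loss/neutral against ±0.05 (age) or ±0.25
  (knockdown contrasts).
* **Enrichment.** Peak-level results map to genes, split genic vs
  intergenic and up vs down; each context gets a hypergeometric ORA (set
  sizes 50–200) and a permutation preranked GSEA (sizes 40–350, weighted
  KS running sum); context p-values combine by Fisher's method,
  χ² = −2Σln pᵢ.

## Worked example

```python
from g4age.synthetic import simulate_study
from g4age.differential import run_differential
from g4age.integration import shrink_table, classify_quadrant

study = simulate_study(seed=7, n_chrom=1, chrom_length=200_000,
                       planted_motifs=60, n_genes=8, n_peaks=200)
norm = {a: study.max_depth[a] / study.background[a].mean()
        for a in ("ATAC", "G4Q")}
res_atac, info = run_differential(norm["ATAC"], study.samples)
print(f"consensus correlation rho = {info['consensus_correlation']:.3f}")
print(f"peaks at FDR <= 10%: {(res_atac['fdr'] <= 0.10).sum()} / {len(res_atac)}")

res_g4, _ = run_differential(norm["G4Q"], study.samples)
sa = shrink_table(res_atac).set_index("peak_id")["shrunk_logfc"]
sg = shrink_table(res_g4).set_index("peak_id")["shrunk_logfc"]
quad = classify_quadrant(sa, sg, threshold=0.05, label_prefix="Age")
print(quad["label"].value_counts().head(3).to_string())
```

prints

```
consensus correlation rho = 0.217
peaks at FDR <= 10%: 20 / 200
label
Age ATAC Neutral | Age G4 Neutral    136
Age ATAC Neutral | Age G4 Loss        14
Age ATAC Gain | Age G4 Neutral         9
```

The generated study has 16 samples (8 cultures × 2 replicates); replicates
of one culture share a random intercept, which the consensus correlation
picks up (ρ ≈ 0.2). 20 % of peaks carry planted age effects of
±0.2 log₂ per ordinal step, of which 20 reach FDR ≤ 10 % at this compact
problem size; shrunk effects of the two assays jointly classify each peak
into an age-gain/loss quadrant.

## Command line and analysis scripts

Every stage is a subcommand of `g4age`
(`simulate coverage annotate refine diff integrate enrich all`), operating
on one working directory and recording a checksummed run manifest:

```bash
g4age all --workdir run1 --seed 1
```

The numbered scripts under `analysis/` run the same stages as a narrative
(`01_simulate.py` … `08_validation.py`), writing compact summary tables to
`results/`.

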