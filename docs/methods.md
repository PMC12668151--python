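# Methods

## Scope and data model

The pipeline operates on peak intervals (BED / MACS2 narrowPeak), per-peak
× per-sample depth matrices for two assays (ATAC-seq accessibility and G4
CUT&Tag occupancy), a genome FASTA, refFlat-like transcript models, and a
sample table (sample, culture, age, condition). All coordinates are
0-based half-open; peaks are unstranded; exons are stored in ascending
genomic order with strand resolved at annotation time. Replicates of one
culture form the block structure for the random-effect treatment.

## Coverage normalization and summaries

Paired-end fragments can be reduced to fixed-width (default 50 bp)
cutsite windows centered at each fragment end, standing in for the
transposition events. Per sample and assay, a global normalization factor
is the reciprocal of the 20 % trimmed mean of per-base coverage over
randomly sampled non-peak regions (defaults: 5 000 regions of 1 000 bp;
trimming drops ⌊0.2 n⌋ values from each tail — the symmetric statistical
definition). Per peak we keep `max_depth` (raw maximum per-base depth),
`avg_depth` (mean per-base depth) and `norm_depth = max_depth × factor`;
across replicates we record the mean and SD of `norm_depth` and the
log-space SD `exp(sd(ln(10⁻⁴ + norm_depth)))`. `norm_depth` is invariant
under global rescaling of all depths. No pseudocount enters the
normalization itself; an all-zero background is an error, not an infinite
factor. Peaks overlapping a blacklist interval by ≥1 bp, or lying outside
chr1–chr22/chrX, are removed before analysis.

Moderate-abundance presence per culture uses assay-specific metrics:
ATAC present iff the culture's mean normalized depth ≥ 5; G4 present iff
the culture's mean **raw** depth ≥ 2 (G4 CUT&Tag coverage is lower and
more discrete, so the raw maximum per-base depth is used; the per-peak
mean per-base depth is also computed for users who prefer it). The binary
matrix feeds exact-subset (UpSet-style) intersection counts.

## Annotation and motif scanning

Strand-aware features per transcript: promoter = TSS −2 500/+250 bp;
first exon = the 5′-most exon; introns = inter-exon gaps; downstream =
3 kb past the 3′ end; 5′/3′ UTRs from CDS bounds when present. Each peak
receives the single highest-priority overlapped category:
first_exon > promoter > exon > utr5 > utr3 > intron > downstream >
intergenic. Because UTRs are sub-intervals of exons, a literal "exon"
feature covering whole exons would make the UTR labels unreachable from
this precedence; we therefore define the exon feature as the **coding
portion** of each exon whenever CDS bounds exist (full exons otherwise,
in which case UTR labels are simply skipped). TSS distances are reported
genomically (upstream = left, downstream = right, 0 if a TSS falls inside
the peak), with equidistant ties broken lexicographically by gene name.
Each peak's enrichment gene is its overlapped gene, or for intergenic
peaks the nearer flanking gene.

Canonical G4 motifs match
`G{3,}[ATGC]{1,7}G{3,}[ATGC]{1,7}G{3,}[ATGC]{1,7}G{3,}` — four runs of
≥3 guanines separated by loops of 1–7 nucleotides (loops may themselves be
G, so the minimum match is 15 bp; N never matches). Matching is
non-overlapping and leftmost-greedy. Peaks are slopped by 15 bp per side
before sequence extraction so motifs straddling an edge are found. The
printed pattern only detects the G-rich strand; by default we also scan
the reverse complement and sum counts (a flag restores forward-only
scanning), since a G4 can form on either strand.

## G4 peak refinement

Over the shared peak universe with per-peak mean normalized signals
(a, g): tier 1 retains peaks with a > 0.5 **and** g > 0.5 (strict, as the
thresholds are "greater than"); remaining peaks are retained in tier 2 if
M = ½(log₂a + log₂g) ≥ 1.0 and A = ½(log₂g − log₂a) ≥ 0.25 (inclusive);
a final stringent screen log₂(g + 10⁻⁴) ≥ 3.0 over the union of both
retained tiers defines high-confidence loci (a flag restricts the screen
to tier 2 only). Zeros are replaced by a 10⁻⁴ pseudocount before logs,
mirroring the log-space SD offset. The step-1 mean is taken over all
samples. The refinement's quality readout is the canonical-motif fraction
among high-confidence peaks divided by the fraction in the unfiltered
set; on real data this fold is data-dependent, so the pipeline asserts
only its direction (> 1) under synthetic conditions where motif peaks
carry boosted G4 signal.

## Differential model

Normalized depths are transformed as y = ln(0.1 + norm_depth). Per-peak
means μᵢ and variances vᵢ feed a lowess fit (tricube local linear, span
0.5) of vᵢ on μᵢ; weights are the reciprocal of the fitted trend (floored
at 10⁻⁶). Weights use the fitted trend rather than raw vᵢ — a raw 1/vᵢ
weight would be circular with the residual variance the model is about to
estimate — with a flag restoring raw-vᵢ weights.

Donor age is encoded ordinally: sorted distinct ages map to ranks 1..K
(ties share a rank; replicates inherit their culture's rank) and the rank
enters as a continuous predictor. Replicate non-independence is absorbed
by a single consensus intra-block correlation: per peak, the mean
within-culture cross-product of OLS residuals over the residual variance,
plus a first-order hat-matrix correction for the downward bias the
fixed-effect fit induces (E[e_a e_b] ≈ σ²(ρ − H_ab)); the consensus is
tanh of the 10 %-trimmed mean of atanh of per-peak estimates, clipped to
(−0.99, 0.99). This deliberately simple estimator fulfills the same
contract as a per-peak REML approach (one ρ fed to GLS) at a fraction of
the cost. GLS then whitens with the block-equicorrelation Cholesky factor
(ρ = 0 reduces bit-identically to WLS). A scalar per-peak weight rescales
the residual variance and unscaled coefficient covariance but not the
coefficients or t statistics, as in any weighted least squares.

Residual variances are moderated empirically: hyperparameters (d₀, s₀²)
are moment-matched on log s² via digamma/trigamma identities (with a
Newton trigamma inverse), giving s̃² = (d₀s₀² + d·s²)/(d₀ + d), moderated
t = β̂/(s̃√u), and two-sided p from t with d₀ + d df (normal reference
when d₀ = ∞, which arises when log-variances show no excess spread). The
implementation reproduces the reference R implementation (limma) to
~10⁻¹⁰ on shared inputs; that comparison is kept as a cross-check test,
not used as the implementation. Contrasts c′β̂ (e.g. mean of older
cultures minus mean of younger on a culture-indicator design) use
u = c′(X′X)⁻¹c with the same moderation. Multiplicity is controlled by
Benjamini–Hochberg. Fits are in natural-log units internally; reported
effects divide by ln 2 to give log₂ per ordinal-age step.

## Shrinkage, quadrants, selections

For each peak, z_obs = Φ⁻¹(1 − p/2) (normal, not t, quantiles — the
quantity is defined through the two-sided z-score of the p-value; p
floored at 10⁻³⁰⁰), implied se = |lfc|/z_obs, and the shrunk effect is
sign(lfc)·max(0, |lfc| − z_c·se) with z_c at confidence 0.70: the
confidence bound clamped to zero exactly when the interval contains zero.
The raw (not BH-adjusted) p is used. Shrunk ATAC and G4 effects classify
each peak into gain/loss/neutral per modality by strict comparison to
±0.05 (age trends) or ±0.25 (knockdown contrasts); values exactly at the
threshold are neutral (deterministic and conservative). Gain/loss counts
are tabulated over the FDR ladder {0.1, 0.05, 0.01, 0.005, 0.001}, and
rows passing FDR ≤ 10 % are z-scored across samples for display
(constant rows dropped with a warning).

## Gene-set enrichment

Differential results merge with annotations; genes split by context
(genic vs intergenic) and direction (up/down = effect sign with raw
p < 0.05 — the cut is configurable); a gene hit by several peaks keeps
its best-|t| peak. ORA is an upper-tail hypergeometric against each
context's own assignable-gene universe, sets restricted to 50–200 members
after universe intersection. Preranked GSEA ranks genes by moderated t,
scores sets of 40–350 members with the weighted (|score|) KS running-sum
statistic, and draws its null from seeded gene-label permutations;
one-sided empirical p-values compare the observed ES against the
same-sign half of the null with a +1 correction (floor ≈ 2/n_perm) —
conditioning on the observed sign against the full null would double the
type-I error. A plain permutation null replaces adaptive multilevel
estimation of extreme tails: at this scale the scientific surface is
calibration, not 10⁻⁵⁰ precision. Context p-values combine via Fisher's
method (χ² = −2Σ ln p on 2k df), separately for up- and down-signals,
with BH FDR across sets.

## Synthetic study generator

The generator emulates the target design: 8 cultures at ages
{22, 24, 32, 34, 53, 56, 72, 73}, 2 replicates each (the replicate count
is a generator choice, not a claim about any particular dataset), two
assays over a shared peak universe. A random genome (GC 0.41, the human
genome-wide fraction) carries planted canonical motifs (four runs of 3–5
G, loops of 1–7 non-G bases, non-overlapping with a 30 bp guard band);
gene models occupy non-overlapping slots with 2–5 exons and alternating
strand; peaks are placed to cover every annotation category by
construction, with 25 % centered on planted motifs. Effects are planted
on 20 % of peaks (80 % null so FDR behavior is testable), round-robin
across the four gain/loss quadrant categories at ±0.2 log₂ per
ordinal-age step.

Depths are negative binomial: mean = base_mean_peak × depth_factor_sample
× 2^(β·(ordinal − mean ordinal) + u), with per-peak base means lognormal
around 50 (SD 0.5 log₂), per-sample depth factors lognormal (SD 0.3,
exercising the normalization), culture random intercepts
u ~ N(0, 0.25²) on the log₂ scale shared across replicates, and NB size
10 (moderate overdispersion); infinite size gives the Poisson limit.
Background coverage draws (mean 4 reads/bp, scaled by the same depth
factors) supply the trimmed-mean factors. An optional multiplier boosts
G4 base means at motif-centered peaks, emulating occupied G4 structures.
All randomness flows through one seeded generator; the truth records the
seed, planted motifs, per-peak effects, motif-centered peak ids and every
realized random intercept.

What the generator does **not** emulate: read-level data (no FASTQ/BAM,
no fragment-length or Tn5 insertion bias), spatially structured
background, peak-width variation tied to signal, and real gene-set
structure (decoy sets are random draws from the simulated gene universe).
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under its stated model, not that the model captures every
artifact of real libraries.

## Numerical choices and degenerate inputs

Log offsets: 0.1 for the regression transform, 10⁻⁴ in log-space SD and
M/A logs. p-values floored at 10⁻³⁰⁰ before normal inversion. Lowess
fitted variances floored at 10⁻⁶. Per-peak correlation estimates clipped
to ±0.999 before Fisher-z, consensus to ±0.99. Trigamma inverse by
Newton iteration (50 steps, 10⁻¹⁰ relative tolerance) with asymptotic
endpoints. Ties everywhere break deterministically (lexicographic gene
names, position order for peaks); GSEA rank ties break by gene name.
Degenerate inputs raise informative errors rather than propagating NaN:
empty trimmed-mean input, all-zero background, rank-deficient designs,
single distinct age, no multi-member block, all-zero residual variances,
contrasts of wrong length, inconsistent hypergeometric counts.

## Problem sizes

Default end-to-end runs use a 2 × 1.4 Mb genome, 120 genes, 600 peaks and
16 samples — compact enough that the full pipeline completes in seconds
while every stage has non-trivial input. Validation experiments use
2 000–5 000 peaks and 10–20 seeds, sizes at which the measured
calibration quantities have Monte-Carlo error well inside their asserted
bands.

## Known limitations

The consensus-correlation estimator is first-order bias-corrected, not
REML; it mildly underestimates large ρ. The ordinal encoding treats age
ranks as equally spaced, by design. ORA universes are the per-context
assignable genes (not all annotated genes). The enrichment permutation
null permutes gene labels, not sample labels, so inter-gene correlation
is not modeled. The M/A refinement applies the high-confidence screen to
both retained tiers; the alternative (tier 2 only) is a flag.
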