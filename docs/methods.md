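# Methods notes

This note documents the models, parameter choices, and numerical conventions
behind `sslineage`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED) internally; the GTF import shim
converts at the boundary. Strand is carried but ignored: enhancers and
KAS-seq peaks are treated as strandless regions. "Overlap" means ≥ 1 shared
base throughout — no reciprocal-fraction requirement, since none is part of
the method's definition. Gene–region distance is measured from the gene TSS
to the nearest base of the region (the closed hull `[start, end]`, so a TSS
at the half-open `end` coordinate is at distance 0); the TSS anchor is the
standard enhancer-target convention, and the window default is 500 kb.

## Super-enhancer calling

Stitching joins same-chromosome peaks whose gap is ≤ the stitch distance,
transitively; the default is the classic 12,500 bp, and an `unstitched`
config preset sets 0 (only touching/overlapping peaks join) for workflows
that disable stitching and handle promoters separately. "Signal units" are the
summed column-5 signal of constituent peaks; no reads-per-million rescaling
is applied because the pipeline starts from peak files, not alignments.

The hockey-stick cutoff sorts totals ascending, scales rank to
`x = (i−1)/(N−1)` and signal to `y_i/max(y)`, and takes the point minimizing
`y − x` — the tangency point of a slope-1 diagonal approached from below.
Ties take the lowest rank (deterministic and conservative: more SEs). SEs
are entries strictly above the cutoff signal. The cutoff needs ≥ 3 distinct
values; constant curves are rejected as degenerate. The cutoff is invariant
to rescaling all signals.

The TSS filter discards an H3K27ac peak when the **summed** signal of
overlapping H3K4me3 peaks strictly exceeds the threshold (default 1000).
Summation rather than per-peak maximum is the documented choice where the
rule itself does not say; with typical promoter-concentrated H3K4me3 the two
rarely differ. The amplicon mask defaults to the MYCN locus
(chr2:15,000,000–17,000,000, hg38) and is fully configurable. Pipeline order
is fixed: stitch → score → rank, filter TSS-like peaks, mask, re-stitch →
re-score → cutoff; both passes' sizes are recorded in provenance.

## Differential expression

The two-group MES-vs-ADRN filter is a deliberately simple negative-binomial
Wald test: median-of-ratios size factors (geometric-mean reference over
genes positive in all samples, with an explicit pseudo-reference fallback
for sparse matrices); per-gene method-of-moments dispersion
`alpha = (var − mean)/mean²` from pooled within-group moments; log2 fold
change from pseudocounted (0.5) group means of normalized counts; SE from
the NB delta method; two-sided normal p; Benjamini–Hochberg adjustment
(scipy) with NA passthrough for untestable genes.

Two numerical choices matter at the 3-to-5-replicates design this filter is
used for:

- The dispersion floor is **adaptive**: per-gene alpha is floored at the
  across-gene median MoM dispersion. With few replicates the raw per-gene
  estimate is noisy enough downward (sample variance below the mean) that a
  fixed near-zero floor makes the test sharply anti-conservative. The median
  floor restores calibration (measured null type-I ≈ 0.05 at 4 vs 4,
  dispersion 0.1) while leaving high-dispersion genes their own estimate;
  it is a floor, not per-gene shrinkage.
- A t reference was considered and rejected: its heavy 6-df tails cannot
  reach BH-adjusted significance across thousands of genes, collapsing power
  against real fold changes.

Gene lists from this test approximate, rather than replicate, what a
shrinkage-based NB-GLM package returns. Selection is strict:
`padj < 0.05` and `log2fc > 1` (MES) or `< −1` (ADRN), which makes the two
selections disjoint by construction.

## Signature assembly

An SE is single-stranded iff it overlaps ≥ 1 KAS-seq peak. ssSEs are
union-merged within a lineage across cell lines with **no recurrence
requirement** — identification in a single line suffices. "Lineage-specific"
means derived from that lineage's cell lines; no subtraction of the other
lineage's ssSEs is performed, because lineage specificity is enforced by the
DE intersection (and DE disjointness makes the final signatures disjoint).
The signature is the intersection of window-query hits with the lineage's DE
selection, ordered lexicographically, with per-gene provenance (supporting
ssSE regions). The overlap test against published signatures is the
upper-tail hypergeometric probability including the observed count; the
universe defaults to all annotated genes and is configurable, since the
appropriate universe depends on the comparison signature's derivation.

## Enrichment scoring

`gsva_score` implements the GSVA algorithm: per-gene Gaussian-kernel CDF
across samples with bandwidth `sd/4`, per-sample descending ranking of the
CDF statistics, symmetric rank weight `|rank − G/2|^tau` with `tau = 1`, and
a weighted KS random walk whose score is the largest positive plus the
largest negative deviation (the magnitude-difference variant). These are the
original tool's expression-data defaults. Cohort TPM input is transformed to
`log2(TPM+1)` before the kernel.

Conventions worth noting:

- The bandwidth uses the **population** (ddof = 0) standard deviation, so
  duplicating every sample leaves every score exactly unchanged; a floor of
  1e-8 handles constant genes.
- Scores are exactly invariant under per-gene positive affine transforms
  (the bandwidth scales out) and bounded in [−1, 1]. They are **not**
  exactly invariant under arbitrary monotone per-gene transforms: a
  nonlinear transform perturbs the kernel CDF values and can swap
  cross-gene ranks that are nearly tied. The rank-based core means such
  swaps are rare and small, but the package does not claim exact
  monotone invariance.
- Ranking ties break by gene order (stable sort), making scores
  deterministic.
- `MES_adj = MES − ADRN` exactly; swapping the two signatures negates it.

The TCI score requires a user-supplied gene set (GMT). The generator emits a
synthetic T-cell program, clearly labeled non-canonical, for tests and
examples only; real analyses should supply a published CD8+ T-cell
signature.

## Classification

Extreme tertiles with `k = ceil(n/3)`: top k of `MES_adj` → MES, bottom k →
ADRN, rest intermediate — the only arithmetic consistent with the published
59/59/58 split at n = 176. Two inflammation rules exist in the literature
this method draws on (top third inflamed, vs bottom third non-inflamed);
the library makes the rule a **mandatory** parameter, and the CLI requires
it explicitly. Ties break by stable input order, so classification is
invariant under strictly increasing score transforms. The "biserial"
association of inflammation with MYCN amplification is computed as a
point-biserial correlation, since amplification is observed binary. The
rank-sum comparison uses scipy's auto rule (exact for small untied samples,
normal approximation with tie correction otherwise).

## Survival

Estimation is delegated to lifelines. 3-year OS is `S(36)` on the months
scale with a complementary-log-log Greenwood CI (respects [0, 1]; the CI
collapses to the point at S = 0 or 1). A `t0` beyond the last follow-up
returns the carried-forward estimate with an explicit flag. Log-rank is the
standard O−E statistic with hypergeometric variance, k−1 df. Cox models use
lifelines' Newton–Raphson with **Efron** tie handling — simulated and
clinical times here are effectively continuous, so the difference from
Breslow is negligible, and a bespoke fitter solely to change the tie rule
was not justified. The interaction term is the product of the 0/1 NI and
MYCN-amplified indicators. Complete separation and rank-deficient designs
raise informative errors; the pipeline-level report skips empty arms with a
warning instead of crashing.

## Synthetic data: what it emulates, and what it does not

The generator's defaults define the test conditions:

- Epigenome: 2 chromosomes × 10 Mb; 5 planted SEs per lineage (clusters of
  5 × 2 kb peaks at 10× the background mean signal of 50), 60% of them
  covered by KAS-seq peaks; 200 isolated background peaks per cell line
  (CV 0.1, spaced beyond the stitch distance so no background cluster can
  masquerade as an SE — this keeps the hockey-stick elbow geometry
  unambiguous at desk scale); 10 decoy promoter peaks with H3K27ac signal
  5000 and H3K4me3 signal 1500 that a correct TSS filter must remove;
  3 MES and 5 ADRN cell lines.
- Genes: 300 total; 40 signature genes per lineage placed within 500 kb of
  a single-stranded SE of their lineage with true log2FC ±2; 20 decoy
  differential genes per lineage near double-stranded SEs only (these must
  be excluded by the ssSE requirement); background genes kept out of every
  ssSE window.
- Cell-line counts: NB with mean 100 and dispersion 0.1.
- Tumors: expression = `f_mes·MES-program + (1−f_mes)·ADRN-program +
  inflammation·TCI-program`, program genes elevated 8×, lognormal noise
  σ = 0.25, columns rescaled to TPM (sum 1e6); `f_mes` and inflammation are
  probit-transformed correlated Gaussians (ρ = 0.5); MYCN amplification
  probability decreases with inflammation; survival is exponential with
  baseline median 60 months, an extra log-hazard of log 2.5 for non-inflamed
  tumors within the planted-ADRN class, and independent uniform censoring on
  24–120 months.
- All streams split from one integer seed via named `SeedSequence` spawn
  keys, so adding a stage never perturbs earlier streams; repeated runs are
  byte-identical.

Passing tests on this generator show the pipeline's *logic* recovers planted
structure under the stated effect sizes. They do not show performance on
real cohorts: real peak files have promoter/enhancer signal continua rather
than a clean 10× separation, real expression has correlated gene programs,
batch structure and dropout the mixture model lacks, and real survival has
non-proportional hazards and informative censoring. The published cohort
quantities (SE counts per lineage, the 159/373-gene signatures, cohort TPM
means, hazard ratios) derive from controlled-access datasets and are not
reproducible at desk scale; the published MES/ADRN signature gene lists
themselves are distributed only as journal supplementary tables and are not
redistributed here.

## Problem sizes

The default test and acceptance runs use the generator defaults above
(200-peak cell lines, 300-gene annotations, 300-tumor cohorts), 2,000-gene
DE simulations with 200 repetitions, and 200-repetition survival
simulations — sizes chosen so the full suite completes in well under a
minute per stage while keeping every recovery criterion's power ≥ 0.8.
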