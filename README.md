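# sslineage

Neuroblastoma tumors mix two interconvertible cell lineages — adrenergic
(ADRN) and mesenchymal (MES) — defined by distinct super-enhancer (SE)
landscapes, and the MES state is linked to a T-cell-inflamed (TCI) tumor
microenvironment. `sslineage` implements, as a tested pipeline, the
derivation of ADRN/MES gene signatures from *single-stranded*
super-enhancers (ssSEs: SEs that overlap KAS-seq peaks and are therefore
transcriptionally engaged), single-sample scoring of tumor cohorts for
lineage and T-cell inflammation, tertile classification, and the survival
analysis relating inflammation class to overall survival within lineage
classes. It is written for computational biologists who start from called
peaks and expression matrices, not raw reads.

## Method

1. **SE calling (ROSE-style).** H3K27ac peaks are stitched (gap ≤ 12.5 kb by
   default), ranked by total signal, and the hockey-stick elbow — the point
   minimizing `y/max(y) − rank/(N−1)`, i.e. the tangent of the unit-slope
   diagonal — separates SEs from typical enhancers. Before the final call,
   peaks whose overlapping H3K4me3 signal exceeds 1000 signal units are
   discarded as transcription-start sites, and a configurable amplicon mask
   (default: the MYCN locus) is removed; the ranking is then re-run.
2. **ssSEs and signatures.** SEs overlapping ≥ 1 KAS-seq peak are
   single-stranded. ssSEs are union-merged per lineage across cell lines
   (one supporting line suffices). Genes with a TSS within 500 kb of a
   lineage ssSE enter that lineage's signature iff they are also
   differentially expressed toward that lineage (NB Wald test,
   `padj < 0.05` and `|log2FC| > 1`, MES-minus-ADRN orientation).
3. **Tumor scoring (GSVA).** Each tumor gets MES, ADRN and TCI enrichment
   scores from the Gene Set Variation Analysis algorithm (Gaussian-kernel
   CDF, bandwidth sd/4, weighted KS walk with `tau = 1`, magnitude-difference
   statistic), and `MES_adj = MES − ADRN`.
4. **Classification.** With `k = ceil(n/3)`: the top k tumors by `MES_adj`
   are MES, the bottom k ADRN. Inflammation supports both published rules —
   `top_third_tci` and `bottom_third_ni` (NI = bottom third; at n = 176 this
   yields TCI = 117, NI = 59, MES = 59, ADRN = 59).
5. **Survival.** Kaplan–Meier 3-year OS with complementary-log-log Greenwood
   CIs, log-rank tests of TCI vs NI within each lineage class, and Cox
   models (univariate inflammation and MYCN; multivariate with the
   NI × MYCN interaction), via lifelines.

A synthetic-data module generates every pipeline input with planted ground
truth (SE clusters, decoy promoter peaks, signature genes with known fold
changes, tumors as lineage-program mixtures with an inflammation gradient
and a planted survival effect), so the whole pipeline is testable offline.

## Worked example

Simulate inputs, derive signatures, score the cohort, and analyze survival:

```sh
sslineage simulate --preset epigenome --seed 1 --out fix/epi
sslineage simulate --preset celllines --seed 1 --out fix/cl
sslineage simulate --preset cohort    --seed 1 --out fix/cohort

sslineage derive \
  --h3k27ac fix/epi/MES1_h3k27ac.bed --h3k4me3 fix/epi/MES1_h3k4me3.bed \
  --kas fix/epi/MES1_kas.bed --lineage MES \
  ... one triple + --lineage per cell line (3 MES, 5 ADRN) ... \
  --counts fix/cl/counts.tsv --groups fix/cl/groups.tsv \
  --annotation fix/epi/annotation.tsv --out derived

sslineage score --tpm fix/cohort/tpm.tsv --signatures derived/signatures.gmt \
  --tci fix/cohort/tci_synthetic.gmt --tci-rule bottom_third_ni --out scored

sslineage survive --classes scored/classes.tsv \
  --clinical fix/cohort/clinical.tsv --out survival.json
```

The run prints, per cell line, the SE and ssSE counts, then the signature
sizes and classification table:

```
CL1_MES (MES): 5 SEs, 3 single-stranded
...
MES: 3 merged ssSEs, 60 DE genes, 40 signature genes
ADRN: 3 merged ssSEs, 60 DE genes, 40 signature genes
MES signature: 40 genes; ADRN signature: 40 genes -> derived
{"n_samples": 300, "tci_rule": "bottom_third_ni", "MES": 100,
 "INTERMEDIATE": 100, "ADRN": 100, "TCI": 200, "NI": 100}
```

The generator plants 5 SEs per lineage of which 3 are single-stranded, and
40 signature genes per lineage; the derived signatures recover exactly the
planted gene sets here. In `survival.json`, the planted extra hazard for
non-inflamed ADRN tumors is visible where it was planted and nowhere else:

```
ADRN TCI vs NI: log-rank p = 0.00055
  TCI 3-year OS 71.1% (n = 46) vs NI 43.4% (n = 54)
MES  TCI vs NI: log-rank p = 0.79
Cox univariate NI: HR 1.55 (95% CI 1.14-2.10), p = 0.0056
```

i.e. inflamed ADRN-class tumors survive longer, MES-class tumors show no
inflammation effect, and the univariate Cox model attributes elevated hazard
to the NI class.

## Layout

- `src/sslineage/intervals.py` — interval model, BED/annotation I/O, algebra
- `src/sslineage/rose.py` — SE calling and the hockey-stick cutoff
- `src/sslineage/diffexpr.py` — NB Wald differential expression
- `src/sslineage/signatures.py` — ssSE overlap, signature assembly,
  hypergeometric overlap test
- `src/sslineage/scoring.py` — GSVA scores, `MES_adj`
- `src/sslineage/classify.py` — tertile classification, association stats
- `src/sslineage/surv.py` — Kaplan–Meier / log-rank / Cox
- `src/sslineage/synth.py` — synthetic inputs with planted truth
- `src/sslineage/pipeline.py`, `cli.py`, `config.py`, `io.py` — orchestration

See `docs/methods.md` for modeling choices, parameter defaults, and
limitations.
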