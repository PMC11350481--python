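"""Synthetic pipeline inputs with planted ground truth.

Every input the pipeline consumes (peak files per histone mark and cell
line, KAS-seq peaks, gene annotation, cell-line count matrix, tumor TPM
matrix, clinical table, gene sets) can be generated deterministically from a
single integer seed, with the planted truth serialized alongside:

* per-lineage super-enhancers = clusters of high-signal H3K27ac peaks
  (constituent signal >= 10x the background mean by default) shared by all
  cell lines of that lineage, a configurable subset of which is covered by
  KAS-seq peaks (single-stranded);
* decoy promoter peaks with high H3K27ac *and* high H3K4me3 signal, which a
  correct TSS filter must remove;
* signature genes placed within the gene window of a single-stranded SE of
  their lineage and given a true log2 fold change (default +/-2) in the
  cell-line counts; decoy differential genes sit near double-stranded SEs
  only;
* tumors as mixtures f_mes * MES-program + (1 - f_mes) * ADRN-program plus
  an inflammation gradient on a separate T-cell gene program and lognormal
  noise, rescaled to TPM; inflammation correlates with f_mes (rho = 0.5 by
  default); MYCN amplification is assigned preferentially to low-inflammation
  tumors; survival times are exponential with an extra log-hazard (default
  log 2.5) for non-inflamed tumors within the planted-adrenergic class, with
  independent censoring.

Random streams are split per stage from the master seed, so adding a stage
never perturbs earlier streams and repeated calls are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, GenomicInterval, SignalPeak
from .diffexpr import ADRN, MES

__all__ = [
    "EpigenomeConfig",
    "CohortConfig",
    "SyntheticTruth",
    "EpigenomeData",
    "gen_epigenome",
    "gen_cellline_counts",
    "gen_tumor_cohort",
]

_STREAMS = {"placement": 0, "signals": 1, "genes": 2, "counts": 3,
            "cohort": 4, "survival": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class EpigenomeConfig:
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_se_per_lineage: int = 5
    n_background_peaks: int = 200          # per cell line
    n_decoy_tss: int = 10                  # high-K27ac promoter peaks per line
    se_n_constituents: int = 5
    background_signal_mean: float = 50.0
    background_signal_cv: float = 0.1      # tight tail keeps the elbow sharp
    signal_ratio: float = 10.0             # SE constituent / background mean
    frac_single_stranded: float = 0.6
    peak_width: int = 1_000
    se_constituent_width: int = 2_000
    se_constituent_gap: int = 500
    stitch_distance: int = 12_500          # used only to space planted SEs
    mes_cell_lines: tuple[str, ...] = ("MES1", "MES2", "MES3")
    adrn_cell_lines: tuple[str, ...] = ("ADRN1", "ADRN2", "ADRN3", "ADRN4", "ADRN5")
    n_genes: int = 300
    n_signature_genes: int = 40            # per lineage
    n_decoy_de_genes: int = 20             # per lineage, near double-stranded SEs
    gene_window: int = 500_000
    true_log2fc: float = 2.0
    decoy_tss_signal: float = 5_000.0
    decoy_k4_signal: float = 1_500.0


@dataclass(frozen=True)
class CohortConfig:
    n_tumors: int = 300
    rho: float = 0.5                       # corr(f_mes, inflammation)
    program_amplitude: float = 8.0         # fold elevation of program genes
    tci_amplitude: float = 8.0
    noise_sigma: float = 0.25              # lognormal noise on log scale
    n_tci_genes: int = 30
    beta_ni: float = math.log(2.5)         # extra log-hazard, NI within ADRN
    baseline_hazard: float = math.log(2) / 60.0   # median 60 months
    censor_min_months: float = 24.0
    censor_max_months: float = 120.0
    frac_stage4: float = 0.85


@dataclass
class SyntheticTruth:
    seed: int
    planted_se: dict          # lineage -> list of "chrom:start-end"
    ss_subset: dict           # lineage -> list of indices into planted_se
    signature_genes: dict     # lineage -> {gene_id: true log2fc}
    decoy_de_genes: dict      # lineage -> {gene_id: true log2fc}
    tci_genes: list = field(default_factory=list)
    f_mes: dict = field(default_factory=dict)        # sample -> mixing fraction
    inflammation: dict = field(default_factory=dict)  # sample -> level in [0,1]
    lineage_truth: dict = field(default_factory=dict)
    ni_truth: dict = field(default_factory=dict)
    beta_ni: float = float("nan")

    def ss_intervals(self, lineage: str) -> list[GenomicInterval]:
        return [_parse_region(self.planted_se[lineage][i])
                for i in self.ss_subset[lineage]]

    def ds_intervals(self, lineage: str) -> list[GenomicInterval]:
        ss = set(self.ss_subset[lineage])
        return [_parse_region(r) for i, r in enumerate(self.planted_se[lineage])
                if i not in ss]

    def se_intervals(self, lineage: str) -> list[GenomicInterval]:
        return [_parse_region(r) for r in self.planted_se[lineage]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _region_str(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def _parse_region(s: str) -> GenomicInterval:
    chrom, _, span = s.partition(":")
    start, _, end = span.partition("-")
    return GenomicInterval(chrom, int(start), int(end))


@dataclass
class EpigenomeData:
    config: EpigenomeConfig
    annotation: list
    cell_lines: dict          # name -> {"lineage", "h3k27ac", "h3k4me3", "kas"}
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Epigenome
# ---------------------------------------------------------------------------

def _place_se_regions(cfg: EpigenomeConfig, rng: np.random.Generator) -> dict:
    """Plant non-overlapping SE footprints per lineage, separated by more
    than the stitch distance so planted regions never merge."""
    se_len = (cfg.se_n_constituents * cfg.se_constituent_width
              + (cfg.se_n_constituents - 1) * cfg.se_constituent_gap)
    min_sep = 2 * cfg.stitch_distance + se_len
    placed: list[GenomicInterval] = []
    out: dict[str, list[GenomicInterval]] = {}
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    for lineage in (MES, ADRN):
        regions = []
        attempts = 0
        while len(regions) < cfg.n_se_per_lineage:
            attempts += 1
            if attempts > 10_000:
                raise ValueError("cannot place SE regions: chromosome too small")
            chrom = chroms[int(rng.integers(cfg.n_chroms))]
            start = int(rng.integers(0, cfg.chrom_length - se_len))
            iv = GenomicInterval(chrom, start, start + se_len)
            if all(iv.chrom != o.chrom
                   or iv.start - o.end > min_sep or o.start - iv.end > min_sep
                   for o in placed):
                regions.append(iv)
                placed.append(iv)
        out[lineage] = regions
    return out


def _se_constituents(region: GenomicInterval, cfg: EpigenomeConfig,
                     rng: np.random.Generator) -> list[SignalPeak]:
    peaks = []
    pos = region.start
    level = cfg.signal_ratio * cfg.background_signal_mean
    for _ in range(cfg.se_n_constituents):
        signal = level * float(rng.uniform(0.8, 1.2))
        peaks.append(SignalPeak(
            GenomicInterval(region.chrom, pos, pos + cfg.se_constituent_width),
            signal))
        pos += cfg.se_constituent_width + cfg.se_constituent_gap
    return peaks


def _background_peaks(cfg: EpigenomeConfig, rng: np.random.Generator,
                      avoid: Sequence[GenomicInterval],
                      n_peaks: int | None = None) -> list[SignalPeak]:
    """Isolated background peaks: separated from planted footprints and from
    each other by more than the stitch distance, so no background cluster can
    masquerade as a super-enhancer."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    n_peaks = cfg.n_background_peaks if n_peaks is None else n_peaks
    min_gap = cfg.stitch_distance + 1
    shape = 1.0 / cfg.background_signal_cv**2
    peaks: list[SignalPeak] = []
    placed: list[GenomicInterval] = list(avoid)
    attempts = 0
    while len(peaks) < n_peaks:
        attempts += 1
        if attempts > 100 * n_peaks:
            raise ValueError("cannot place background peaks: region too crowded")
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        start = int(rng.integers(0, cfg.chrom_length - cfg.peak_width))
        iv = GenomicInterval(chrom, start, start + cfg.peak_width)
        if any(iv.chrom == a.chrom and iv.start < a.end + min_gap
               and a.start - min_gap < iv.end for a in placed):
            continue
        signal = float(rng.gamma(shape, cfg.background_signal_mean / shape))
        peaks.append(SignalPeak(iv, signal))
        placed.append(iv)
    return peaks


def gen_epigenome(cfg: EpigenomeConfig = EpigenomeConfig(), seed: int = 0) -> EpigenomeData:
    """Per-cell-line H3K27ac / H3K4me3 / KAS-seq peaks plus planted truth."""
    se_len = (cfg.se_n_constituents * cfg.se_constituent_width
              + (cfg.se_n_constituents - 1) * cfg.se_constituent_gap)
    if se_len >= cfg.chrom_length:
        raise ValueError("chromosome too small for an SE footprint")
    place_rng = _rng(seed, "placement")
    signal_rng = _rng(seed, "signals")
    gene_rng = _rng(seed, "genes")

    planted = _place_se_regions(cfg, place_rng)
    n_ss = int(round(cfg.frac_single_stranded * cfg.n_se_per_lineage))
    ss_subset = {
        lin: sorted(place_rng.choice(cfg.n_se_per_lineage, size=n_ss,
                                     replace=False).tolist())
        for lin in (MES, ADRN)
    }
    all_footprints = [iv for lst in planted.values() for iv in lst]

    lineage_of = {cl: MES for cl in cfg.mes_cell_lines}
    lineage_of.update({cl: ADRN for cl in cfg.adrn_cell_lines})

    cell_lines: dict[str, dict] = {}
    for cl, lineage in lineage_of.items():
        h3k27ac: list[SignalPeak] = []
        for region in planted[lineage]:
            h3k27ac.extend(_se_constituents(region, cfg, signal_rng))
        background = _background_peaks(cfg, signal_rng, all_footprints)
        h3k27ac.extend(background)
        # decoy promoters: very high K27ac peaks that a correct pipeline must
        # drop because they carry high H3K4me3 signal
        h3k4me3: list[SignalPeak] = []
        decoys = _background_peaks(cfg, signal_rng,
                                   all_footprints + [p.interval for p in background],
                                   n_peaks=cfg.n_decoy_tss)
        for d in decoys:
            peak = SignalPeak(d.interval, cfg.decoy_tss_signal)
            h3k27ac.append(peak)
            h3k4me3.append(SignalPeak(d.interval, cfg.decoy_k4_signal))
        # diffuse low H3K4me3 elsewhere
        for p in signal_rng.choice(len(background), size=min(20, len(background)),
                                   replace=False):
            h3k4me3.append(SignalPeak(background[int(p)].interval,
                                      float(signal_rng.uniform(10, 200))))
        # KAS peaks over the single-stranded subset of this line's lineage
        kas = [GenomicInterval(r.chrom,
                               max(0, r.start + se_len // 4),
                               r.start + se_len // 4 + se_len // 2)
               for i, r in enumerate(planted[lineage]) if i in set(ss_subset[lineage])]
        # plus unrelated KAS noise peaks
        for _ in range(10):
            chrom = f"chr{int(signal_rng.integers(cfg.n_chroms)) + 1}"
            start = int(signal_rng.integers(0, cfg.chrom_length - 5_000))
            kas.append(GenomicInterval(chrom, start, start + 5_000))
        cell_lines[cl] = {"lineage": lineage, "h3k27ac": h3k27ac,
                          "h3k4me3": h3k4me3, "kas": kas}

    annotation, sig_genes, decoy_genes = _plant_genes(cfg, planted, ss_subset, gene_rng)
    truth = SyntheticTruth(
        seed=seed,
        planted_se={lin: [_region_str(iv) for iv in planted[lin]]
                    for lin in (MES, ADRN)},
        ss_subset=ss_subset,
        signature_genes=sig_genes,
        decoy_de_genes=decoy_genes,
    )
    return EpigenomeData(cfg, annotation, cell_lines, truth)


def _plant_genes(cfg, planted, ss_subset, rng):
    """Annotation with signature genes near single-stranded SEs, decoy
    differential genes near double-stranded SEs only, and background genes
    kept out of every lineage's ssSE windows."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    annotation: list[GeneAnnotation] = []
    sig_genes: dict[str, dict[str, float]] = {MES: {}, ADRN: {}}
    decoy_genes: dict[str, dict[str, float]] = {MES: {}, ADRN: {}}
    ss_regions = {lin: [planted[lin][i] for i in ss_subset[lin]]
                  for lin in (MES, ADRN)}
    ds_regions = {lin: [r for i, r in enumerate(planted[lin])
                        if i not in set(ss_subset[lin])]
                  for lin in (MES, ADRN)}
    all_ss = [r for lst in ss_regions.values() for r in lst]
    counter = 0

    def near(region: GenomicInterval) -> tuple[str, int]:
        offset = int(rng.integers(-(cfg.gene_window - 100_000),
                                  cfg.gene_window - 100_000))
        anchor = region.start if offset < 0 else region.end
        return region.chrom, int(np.clip(anchor + offset, 0, cfg.chrom_length - 1))

    def clear_of_ss(chrom: str, tss: int) -> bool:
        return all(c.chrom != chrom
                   or GenomicInterval(c.chrom, c.start, c.end).distance_to_point(tss)
                   > cfg.gene_window
                   for c in all_ss)

    sign = {MES: 1.0, ADRN: -1.0}
    for lineage in (MES, ADRN):
        n_sig = cfg.n_signature_genes if ss_regions[lineage] else 0
        for _ in range(n_sig):
            region = ss_regions[lineage][int(rng.integers(len(ss_regions[lineage])))]
            chrom, tss = near(region)
            gid = f"G{counter:04d}"
            counter += 1
            annotation.append(GeneAnnotation(gid, gid, chrom, tss))
            sig_genes[lineage][gid] = sign[lineage] * cfg.true_log2fc
        for _ in range(cfg.n_decoy_de_genes):
            if not ds_regions[lineage]:
                break
            for _attempt in range(1000):
                region = ds_regions[lineage][int(rng.integers(len(ds_regions[lineage])))]
                chrom, tss = near(region)
                if clear_of_ss(chrom, tss):
                    break
            else:
                raise ValueError("cannot place decoy gene away from ssSEs")
            gid = f"G{counter:04d}"
            counter += 1
            annotation.append(GeneAnnotation(gid, gid, chrom, tss))
            decoy_genes[lineage][gid] = sign[lineage] * cfg.true_log2fc
    while counter < cfg.n_genes:
        for _attempt in range(1000):
            chrom = chroms[int(rng.integers(cfg.n_chroms))]
            tss = int(rng.integers(0, cfg.chrom_length))
            if clear_of_ss(chrom, tss):
                break
        else:
            raise ValueError("cannot place background gene away from ssSEs")
        gid = f"G{counter:04d}"
        counter += 1
        annotation.append(GeneAnnotation(gid, gid, chrom, tss))
    return annotation, sig_genes, decoy_genes


# ---------------------------------------------------------------------------
# Cell-line counts
# ---------------------------------------------------------------------------

def gen_cellline_counts(
    epi: EpigenomeData,
    n_mes: int = 3,
    n_adrn: int = 5,
    mean: float = 100.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial count matrix over the planted annotation.

    Planted signature and decoy genes get their true log2 fold change as a
    group-mean shift (higher in their lineage); all other genes are
    exchangeable between groups. Returns (counts, groups).
    """
    rng = _rng(seed, "counts")
    genes = [g.gene_id for g in epi.annotation]
    samples = ([f"MESCL{i + 1}" for i in range(n_mes)]
               + [f"ADRNCL{i + 1}" for i in range(n_adrn)])
    groups = pd.Series([MES] * n_mes + [ADRN] * n_adrn, index=samples, name="group")
    lfc = np.zeros(len(genes))
    truth = epi.truth
    gene_pos = {g: i for i, g in enumerate(genes)}
    for lineage in (MES, ADRN):
        for src in (truth.signature_genes, truth.decoy_de_genes):
            for gid, value in src[lineage].items():
                lfc[gene_pos[gid]] = value
    mu = np.empty((len(genes), len(samples)))
    is_mes = (groups == MES).to_numpy()
    mu[:, is_mes] = mean * np.power(2.0, np.maximum(lfc, 0.0))[:, None]
    mu[:, ~is_mes] = mean * np.power(2.0, np.maximum(-lfc, 0.0))[:, None]
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts, index=genes, columns=samples), groups


# ---------------------------------------------------------------------------
# Tumor cohort
# ---------------------------------------------------------------------------

def gen_tumor_cohort(
    epi: EpigenomeData,
    cfg: CohortConfig = CohortConfig(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Tumor TPM matrix, clinical table, and the extended truth.

    Expression mixes the two lineage programs by the tumor's mesenchymal
    fraction f_mes, adds an inflammation-scaled T-cell program on separate
    genes and lognormal noise, and rescales columns to TPM (sum 1e6).
    Survival is exponential with the extra log-hazard ``beta_ni`` for
    non-inflamed tumors in the planted-adrenergic class.
    """
    if cfg.n_tumors < 30:
        raise ValueError("need >= 30 tumors")
    rng = _rng(seed, "cohort")
    surv_rng = _rng(seed, "survival")
    truth = epi.truth
    genes = [g.gene_id for g in epi.annotation]
    samples = [f"T{i + 1:04d}" for i in range(cfg.n_tumors)]

    mes_set = set(truth.signature_genes[MES])
    adrn_set = set(truth.signature_genes[ADRN])
    free = [g for g in genes if g not in mes_set | adrn_set]
    tci_genes = list(rng.choice(free, size=cfg.n_tci_genes, replace=False))
    truth.tci_genes = tci_genes

    # correlated latent uniforms for mixing fraction and inflammation
    cov = np.array([[1.0, cfg.rho], [cfg.rho, 1.0]])
    latent = rng.multivariate_normal(np.zeros(2), cov, size=cfg.n_tumors)
    from scipy.special import ndtr
    f_mes = ndtr(latent[:, 0])
    infl = ndtr(latent[:, 1])

    base = np.exp(rng.normal(np.log(20.0), 0.5, size=len(genes)))
    amp = cfg.program_amplitude
    mes_prog = base * np.where([g in mes_set for g in genes], amp, 1.0)
    adrn_prog = base * np.where([g in adrn_set for g in genes], amp, 1.0)
    tci_idx = np.isin(genes, tci_genes)
    tci_prog = np.where(tci_idx, cfg.tci_amplitude * base, 0.0)

    expr = (np.outer(mes_prog, f_mes) + np.outer(adrn_prog, 1.0 - f_mes)
            + np.outer(tci_prog, infl))
    expr *= np.exp(rng.normal(0.0, cfg.noise_sigma, size=expr.shape))
    expr *= 1e6 / expr.sum(axis=0, keepdims=True)
    tpm = pd.DataFrame(expr, index=genes, columns=samples)

    # classes on planted truth: extreme tertiles of the latent quantities
    k = math.ceil(cfg.n_tumors / 3)
    adrn_true = np.zeros(cfg.n_tumors, dtype=bool)
    adrn_true[np.argsort(f_mes, kind="stable")[:k]] = True
    mes_true = np.zeros(cfg.n_tumors, dtype=bool)
    mes_true[np.argsort(-f_mes, kind="stable")[:k]] = True
    ni_true = np.zeros(cfg.n_tumors, dtype=bool)
    ni_true[np.argsort(infl, kind="stable")[:k]] = True

    p_amp = np.clip(0.7 - 0.6 * infl, 0.05, 0.95)
    mycn_amp = rng.random(cfg.n_tumors) < p_amp
    stage = np.where(rng.random(cfg.n_tumors) < cfg.frac_stage4, "4", "3")
    age = np.exp(surv_rng.normal(np.log(36.0), 0.5, size=cfg.n_tumors))

    log_hazard = np.log(cfg.baseline_hazard) + cfg.beta_ni * (ni_true & adrn_true)
    event_time = surv_rng.exponential(1.0 / np.exp(log_hazard))
    censor_time = surv_rng.uniform(cfg.censor_min_months, cfg.censor_max_months,
                                   size=cfg.n_tumors)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    clinical = pd.DataFrame(
        {
            "time_months": np.round(np.maximum(time, 1e-3), 4),
            "event": event,
            "mycn": np.where(mycn_amp, "amplified", "non-amplified"),
            "stage": stage,
            "age_months": np.round(age, 1),
            "risk_group": "high",
        },
        index=pd.Index(samples, name="sample"),
    )

    truth.f_mes = dict(zip(samples, np.round(f_mes, 10).tolist()))
    truth.inflammation = dict(zip(samples, np.round(infl, 10).tolist()))
    truth.lineage_truth = dict(zip(
        samples, np.where(adrn_true, ADRN, np.where(mes_true, MES, "INTERMEDIATE"))))
    truth.ni_truth = dict(zip(samples, np.where(ni_true, "NI", "TCI")))
    truth.beta_ni = cfg.beta_ni
    return tpm, clinical, truth
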