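"""Two-group negative-binomial differential expression (MES vs ADRN cell lines).

A deliberately simple NB Wald test: median-of-ratios size factors, per-gene
method-of-moments dispersion (no shrinkage, no independent filtering), a
delta-method standard error for the log2 fold change, a normal reference for
the Wald statistic and Benjamini-Hochberg adjustment. The per-gene dispersion
is floored at the across-gene median dispersion: with only a few replicates
per group the raw method-of-moments estimate is noisy enough downward to make
the Wald test anti-conservative, and the data-wide floor restores calibration
without per-gene shrinkage. Gene lists therefore
approximate, rather than replicate, what a shrinkage-based NB-GLM package
would return; the downstream signature intersection only needs a calibrated
two-group test.

Fold changes are oriented MES minus ADRN: log2fc > 0 means higher in MES.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "DEResult",
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "select_lineage_genes",
]

MES, ADRN = "MES", "ADRN"

#: dispersion floor and pseudocount on normalized means (numerical stability
#: at zero counts)
ALPHA_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Integer count matrix (genes x samples) with a MES/ADRN group label."""

    counts: pd.DataFrame  # index = gene_id, columns = sample_id
    groups: pd.Series     # index = sample_id, values in {MES, ADRN}

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - {MES, ADRN}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @classmethod
    def from_tsv(cls, counts_path: str | Path, groups_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        groups_df = pd.read_csv(groups_path, sep="\t", index_col=0)
        return cls(counts, groups_df.iloc[:, 0])


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    base_mean: float
    log2fc: float   # MES minus ADRN
    se: float
    wald_z: float
    p: float        # NaN for untestable (all-zero) genes
    padj: float


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors with a geometric-mean reference.

    Only genes with all-positive counts enter the median unless
    ``pseudo_reference`` is set, in which case zeros are excluded per sample
    from its ratio median (fallback for sparse matrices).
    """
    mat = counts.to_numpy(dtype=float)
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one nonzero count")
    positive = (mat > 0).all(axis=1)
    if not positive.any() and not pseudo_reference:
        raise ValueError(
            "no gene expressed in all samples; re-run with pseudo_reference=True"
        )
    use = positive if positive.any() else (mat > 0).any(axis=1)
    with np.errstate(invalid="ignore"):
        log_ref = np.nanmean(np.log(np.where(mat[use] > 0, mat[use], np.nan)),
                             axis=1)
    with np.errstate(divide="ignore"):
        log_ratios = np.log(mat[use]) - log_ref[:, None]
    factors = np.exp(np.nanmedian(np.where(np.isfinite(log_ratios), log_ratios, np.nan),
                                  axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotone enforcement; NaN passthrough."""
    p = np.asarray(pvalues, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = stats.false_discovery_control(p[finite], method="bh")
    return out


def nb_wald_test(cm: CountMatrix) -> list[DEResult]:
    """Per-gene NB Wald test of MES vs ADRN.

    Counts are normalized by size factors; the dispersion is the pooled
    method-of-moments estimate ``alpha = max((var - mean)/mean^2, floor)``
    from within-group variances, floored at the across-gene median MoM
    dispersion; the Wald z is log2fc over its delta-method standard error,
    with a two-sided normal p-value and BH adjustment over the tested genes. Genes with all-zero counts are reported with p = NaN.
    """
    mes_samples = cm.samples_in(MES)
    adrn_samples = cm.samples_in(ADRN)
    if len(mes_samples) < 2 or len(adrn_samples) < 2:
        raise ValueError("need >= 2 samples per group")

    sf = size_factors(cm.counts)
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    mes_idx = [cm.counts.columns.get_loc(s) for s in mes_samples]
    adrn_idx = [cm.counts.columns.get_loc(s) for s in adrn_samples]
    xm, xa = norm[:, mes_idx], norm[:, adrn_idx]
    nm, na = xm.shape[1], xa.shape[1]

    mean_m, mean_a = xm.mean(axis=1), xa.mean(axis=1)
    base_mean = norm.mean(axis=1)
    var_m = xm.var(axis=1, ddof=1)
    var_a = xa.var(axis=1, ddof=1)
    # pooled within-group moments
    pooled_var = ((nm - 1) * var_m + (na - 1) * var_a) / (nm + na - 2)
    pooled_mean = (nm * mean_m + na * mean_a) / (nm + na)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(np.isfinite(alpha), alpha, ALPHA_FLOOR)
    alpha = np.maximum(alpha, ALPHA_FLOOR)
    # adaptive floor: the across-gene median dispersion
    expressed = norm.sum(axis=1) > 0
    if expressed.any():
        alpha = np.maximum(alpha, max(np.median(alpha[expressed]), ALPHA_FLOOR))

    mm = mean_m + PSEUDOCOUNT
    ma = mean_a + PSEUDOCOUNT
    log2fc = np.log2(mm / ma)
    # Var(log mean) ~ (1/mean + alpha)/n for an NB group mean (delta method)
    var_log = (1.0 / mm + alpha) / nm + (1.0 / ma + alpha) / na
    se = np.sqrt(var_log) / np.log(2)
    with np.errstate(invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    testable = norm.sum(axis=1) > 0
    p = np.where(testable, p, np.nan)
    padj = bh_adjust(p)

    return [
        DEResult(g, float(base_mean[i]), float(log2fc[i]), float(se[i]),
                 float(z[i]), float(p[i]), float(padj[i]))
        for i, g in enumerate(cm.counts.index)
    ]


def select_lineage_genes(
    results: Sequence[DEResult],
    lineage: str,
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
) -> set[str]:
    """Genes significantly higher in one lineage (strict inequalities).

    MES: padj < padj_max and log2fc > lfc_min; ADRN: padj < padj_max and
    log2fc < -lfc_min.
    """
    if lineage not in (MES, ADRN):
        raise ValueError(f"lineage must be {MES} or {ADRN}, got {lineage!r}")
    sign = 1.0 if lineage == MES else -1.0
    return {
        r.gene_id for r in results
        if not np.isnan(r.padj) and r.padj < padj_max and sign * r.log2fc > lfc_min
    }


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "base_mean": [r.base_mean for r in results],
            "log2fc": [r.log2fc for r in results],
            "se": [r.se for r in results],
            "wald_z": [r.wald_z for r in results],
            "p": [r.p for r in results],
            "padj": [r.padj for r in results],
        }
    ).set_index("gene_id")
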