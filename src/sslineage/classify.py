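"""Tertile-based tumor classification and cohort association statistics.

Lineage classes follow the extreme-tertile rule: with k = ceil(n/3), the k
tumors with the highest MES_adj are mesenchymal (MES), the k lowest are
adrenergic (ADRN), the remainder intermediate. At n = 176 this yields the
59/59/58 split. Inflammation labels support the two published variants:
``top_third_tci`` (TCI = top third by TCI score) and ``bottom_third_ni``
(NI = bottom third, TCI = the remaining two thirds; the rule used for the
high-risk survival analyses, giving 117/59 at n = 176). Ties are broken by
stable input order, so classifications are invariant to any strictly
increasing transform of the scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult",
    "tertile_classify",
    "inflammation_classify",
    "classify_cohort",
    "correlate",
    "oneway_anova",
    "ranksum_test",
]

LINEAGE_MES, LINEAGE_INT, LINEAGE_ADRN = "MES", "INTERMEDIATE", "ADRN"
TCI, NI = "TCI", "NI"
INFLAMMATION_RULES = ("top_third_tci", "bottom_third_ni")


@dataclass(frozen=True)
class StatResult:
    method: str
    estimate: float
    p: float
    n: int


def _extreme_tertile_indices(scores: Sequence[float]) -> tuple[list[int], list[int]]:
    n = len(scores)
    if n < 3:
        raise ValueError("need >= 3 samples to form tertiles")
    k = math.ceil(n / 3)
    order_desc = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    top = list(order_desc[:k])
    # bottom k by ascending score, stable in input order
    order_asc = np.argsort(np.asarray(scores, dtype=float), kind="stable")
    bottom = [i for i in order_asc[:k] if i not in set(top)]
    return top, bottom


def tertile_classify(mes_adj: pd.Series) -> pd.Series:
    """Lineage class per sample from MES_adj: top ceil(n/3) MES, bottom
    ceil(n/3) ADRN, remainder INTERMEDIATE."""
    top, bottom = _extreme_tertile_indices(mes_adj.to_numpy())
    labels = np.full(len(mes_adj), LINEAGE_INT, dtype=object)
    labels[top] = LINEAGE_MES
    labels[bottom] = LINEAGE_ADRN
    return pd.Series(labels, index=mes_adj.index, name="lineage_class")


def inflammation_classify(tci_scores: pd.Series, rule: str) -> pd.Series:
    """Inflammation label per sample.

    ``top_third_tci``: TCI = top ceil(n/3) by TCI score, NI = rest.
    ``bottom_third_ni``: NI = bottom ceil(n/3), TCI = rest.
    """
    if rule not in INFLAMMATION_RULES:
        raise ValueError(f"unknown inflammation rule {rule!r}; "
                         f"expected one of {INFLAMMATION_RULES}")
    n = len(tci_scores)
    if n < 3:
        raise ValueError("need >= 3 samples to form tertiles")
    k = math.ceil(n / 3)
    labels = np.empty(n, dtype=object)
    if rule == "top_third_tci":
        order = np.argsort(-tci_scores.to_numpy(dtype=float), kind="stable")
        labels[:] = NI
        labels[order[:k]] = TCI
    else:
        order = np.argsort(tci_scores.to_numpy(dtype=float), kind="stable")
        labels[:] = TCI
        labels[order[:k]] = NI
    return pd.Series(labels, index=tci_scores.index, name="inflammation")


def classify_cohort(scores: pd.DataFrame, tci_rule: str) -> pd.DataFrame:
    """Combine lineage and inflammation classification of a score table."""
    return pd.DataFrame(
        {
            "lineage_class": tertile_classify(scores["mes_adj"]),
            "inflammation": inflammation_classify(scores["tci_score"], tci_rule),
        }
    )


# ---------------------------------------------------------------------------
# Association statistics
# ---------------------------------------------------------------------------

def correlate(x: Sequence[float], y: Sequence[float], method: str) -> StatResult:
    """Pearson, Spearman, or point-biserial correlation with a two-sided p.

    ``point_biserial`` expects binary y (both levels present). The biserial
    association of the inflammation score with MYCN amplification is computed
    as a point-biserial correlation since amplification is observed binary.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r = stats.pearsonr(x, y)
        return StatResult("pearson", float(r.statistic), float(r.pvalue), x.size)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        return StatResult("spearman", float(rho), float(p), x.size)
    if method == "point_biserial":
        levels = np.unique(y)
        if levels.size != 2:
            raise ValueError("point_biserial needs binary y with both levels")
        r, p = stats.pointbiserialr(np.where(y == levels[1], 1, 0), x)
        return StatResult("point_biserial", float(r), float(p), x.size)
    raise ValueError(f"unknown correlation method {method!r}")


def oneway_anova(*groups: Sequence[float]) -> StatResult:
    """Classic one-way ANOVA F with (k-1, n-k) degrees of freedom."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 values")
    n = sum(a.size for a in arrays)
    if n <= len(arrays):
        raise ValueError("degenerate degrees of freedom")
    f, p = stats.f_oneway(*arrays)
    return StatResult("oneway_anova", float(f), float(p), n)


def ranksum_test(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact enumeration for small untied samples; normal approximation with tie
    correction otherwise (scipy's auto rule). The estimate is the U statistic
    of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return StatResult("ranksum", float(res.statistic), float(res.pvalue),
                      a.size + b.size)
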