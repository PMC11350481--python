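"""Stage orchestration: derive signatures, score/classify a cohort, survival.

These functions are the library form of the three CLI commands. Each returns
JSON-serializable report structures echoing the configuration, so a run is
reproducible from its report alone.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import NI, TCI, classify_cohort
from .config import PipelineConfig
from .diffexpr import ADRN, MES, CountMatrix, nb_wald_test, results_to_frame, select_lineage_genes
from .intervals import GeneAnnotation
from .rose import call_superenhancers
from .scoring import ExpressionMatrix, GeneSet, score_cohort
from .signatures import LineageSignature, build_signature, intersect_with_kas, merge_lineage_ssse
from .surv import cox_fit, km_fit, km_point_estimate, logrank_test

log = logging.getLogger(__name__)

__all__ = ["derive_signatures", "score_and_classify", "survival_report"]


def derive_signatures(
    config: PipelineConfig,
    cell_lines: Mapping[str, Mapping],
    counts: pd.DataFrame,
    groups: pd.Series,
    annotation: Sequence[GeneAnnotation],
) -> tuple[dict[str, LineageSignature], pd.DataFrame, dict]:
    """SE calling per cell line -> ssSE merge per lineage -> DE intersection.

    ``cell_lines`` maps a cell-line name to a dict with keys ``lineage``
    (MES/ADRN), ``h3k27ac``, ``h3k4me3`` (SignalPeak lists) and ``kas``
    (GenomicInterval list). Returns (signatures per lineage, DE results
    frame, run report).
    """
    report: dict = {"config": config.echo(), "version": __version__,
                    "cell_lines": {}}
    ssse_by_lineage: dict[str, list] = {MES: [], ADRN: []}
    for name, data in cell_lines.items():
        lineage = data["lineage"]
        call = call_superenhancers(
            data["h3k27ac"], data["h3k4me3"],
            stitch_distance=config.stitch_distance,
            tss_signal_threshold=config.tss_signal_threshold,
            amplicon_mask=config.amplicon_mask,
        )
        ses = [e.interval for e in call.superenhancers]
        ssses = intersect_with_kas(ses, data["kas"], lineage, name)
        ssse_by_lineage[lineage].append(ssses)
        report["cell_lines"][name] = {
            "lineage": lineage, **call.provenance, "n_ssse": len(ssses),
        }
        log.info("%s (%s): %d SEs, %d single-stranded", name, lineage,
                 len(ses), len(ssses))

    de_results = nb_wald_test(CountMatrix(counts, groups))
    signatures: dict[str, LineageSignature] = {}
    for lineage in (MES, ADRN):
        merged = merge_lineage_ssse(ssse_by_lineage[lineage], lineage)
        de_genes = select_lineage_genes(de_results, lineage,
                                        config.padj_max, config.lfc_min)
        signatures[lineage] = build_signature(
            merged, annotation, de_genes, window=config.gene_window)
        report[lineage] = {
            "n_ssse_merged": len(merged),
            "n_de_genes": len(de_genes),
            "n_signature_genes": len(signatures[lineage].genes),
        }
        log.info("%s: %d merged ssSEs, %d DE genes, %d signature genes",
                 lineage, len(merged), len(de_genes),
                 len(signatures[lineage].genes))
    return signatures, results_to_frame(de_results), report


def score_and_classify(
    config: PipelineConfig,
    tpm: pd.DataFrame,
    mes_sig: GeneSet,
    adrn_sig: GeneSet,
    tci_sig: GeneSet,
    tci_rule: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """GSVA scores plus tertile classification of a TPM cohort."""
    rule = tci_rule or config.tci_rule
    if rule is None:
        raise ValueError("an inflammation rule must be chosen explicitly "
                         "(top_third_tci or bottom_third_ni)")
    scores = score_cohort(ExpressionMatrix(tpm), mes_sig, adrn_sig, tci_sig,
                          tau=config.gsva_tau)
    classes = classify_cohort(scores, rule)
    counts = {
        "n_samples": len(scores),
        "tci_rule": rule,
        **classes["lineage_class"].value_counts().to_dict(),
        **classes["inflammation"].value_counts().to_dict(),
    }
    log.info("classified %d tumors: %s", len(scores), counts)
    return scores, classes, {"config": config.echo(), "counts": counts}


SUBGROUP_FILTERS = {
    "hr_stage4_gt18m": lambda df: df[(df["stage"].astype(str) == "4")
                                     & (df["age_months"] > 18.0)],
}


def _km_arm(df: pd.DataFrame, t0: float) -> dict:
    fit = km_fit(df)
    est, lo, hi, beyond = km_point_estimate(fit, t0)
    return {"n": int(len(df)), "n_events": int(df["event"].sum()),
            "os_t0": est, "ci_low": lo, "ci_high": hi,
            "beyond_followup": bool(beyond)}


def _cox_block(fit) -> dict:
    return {
        term: {"coef": float(fit.coef[term]), "hr": float(fit.hr[term]),
               "ci_low": float(fit.ci_low[term]),
               "ci_high": float(fit.ci_high[term]), "p": float(fit.p[term])}
        for term in fit.coef.index
    }


def survival_report(
    config: PipelineConfig,
    classes: pd.DataFrame,
    clinical: pd.DataFrame,
    subgroup: str | None = None,
) -> dict:
    """Survival comparisons of the classified cohort.

    Per lineage class (ADRN, MES): TCI vs NI log-rank and 3-year OS with CI
    per arm. Cohort-wide: univariate Cox for inflammation (NI = 1) and MYCN
    (amplified = 1), and the multivariate model with the NI x MYCN
    interaction. ``subgroup`` optionally restricts to a named filter
    (``hr_stage4_gt18m``: stage 4, age > 18 months).
    """
    df = classes.join(clinical, how="inner")
    df = df.rename(columns={"time_months": "time"})
    if subgroup:
        df = SUBGROUP_FILTERS[subgroup](df)
    df = df[df["mycn"].isin(["amplified", "non-amplified"])].copy()
    df["ni"] = (df["inflammation"] == NI).astype(int)
    df["mycn_amp"] = (df["mycn"] == "amplified").astype(int)
    report: dict = {"config": config.echo(), "subgroup": subgroup,
                    "n": int(len(df)), "comparisons": {}}

    t0 = config.t0_months
    for lineage in (ADRN, MES):
        sub = df[df["lineage_class"] == lineage]
        entry: dict = {}
        arms = {arm: sub[sub["inflammation"] == arm] for arm in (TCI, NI)}
        empty = [arm for arm, d in arms.items() if d.empty]
        if empty:
            entry["warning"] = f"empty arm(s): {empty}; comparison skipped"
            log.warning("%s: %s", lineage, entry["warning"])
        else:
            for arm, d in arms.items():
                entry[arm] = _km_arm(d, t0)
            chi2, p = logrank_test(sub, "inflammation")
            entry["logrank_chi2"] = chi2
            entry["logrank_p"] = p
        report["comparisons"][f"{lineage}_TCI_vs_NI"] = entry

    try:
        report["cox_univariate_tci"] = _cox_block(cox_fit(df, ["ni"]))
        report["cox_univariate_mycn"] = _cox_block(cox_fit(df, ["mycn_amp"]))
        report["cox_multivariate"] = _cox_block(
            cox_fit(df, ["ni", "mycn_amp"], include_interaction=True))
    except ValueError as exc:
        report["cox_warning"] = str(exc)
        log.warning("Cox models skipped: %s", exc)
    return report
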