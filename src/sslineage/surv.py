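"""Survival analysis: Kaplan-Meier, log-rank, Cox proportional hazards.

Estimation is delegated to lifelines (the standard survival stack); this
module adds the cohort-specific surfaces: 3-year (36-month) overall-survival
point estimates with complementary-log-log Greenwood confidence intervals,
log-rank tests between inflammation classes, and univariate/multivariate Cox
fits including the TCI x MYCN interaction. Times are in months throughout.
Cox ties follow lifelines' Efron approximation; simulated and clinical times
here are effectively continuous, so the choice of tie rule is immaterial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMFit",
    "CoxFit",
    "records_to_frame",
    "km_fit",
    "km_point_estimate",
    "logrank_test",
    "cox_fit",
]

THREE_YEARS_MONTHS = 36.0


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float            # months
    event: int             # 1 = death
    inflammation: str = ""  # TCI / NI
    mycn: str = ""          # amplified / non-amplified
    lineage_class: str = ""
    stage: str = ""
    age_months: float = float("nan")

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event}")


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "inflammation": [r.inflammation for r in records],
            "mycn": [r.mycn for r in records],
            "lineage_class": [r.lineage_class for r in records],
            "stage": [r.stage for r in records],
            "age_months": [r.age_months for r in records],
        }
    ).set_index("sample_id")


@dataclass
class KMFit:
    """Product-limit estimate with its Greenwood variance pieces."""

    event_times: np.ndarray          # distinct times with >= 1 death
    survival: np.ndarray             # S(t) at those times
    greenwood_terms: np.ndarray      # cumulative sum of d / (n (n - d))
    at_risk: np.ndarray              # n at risk at each event time
    n_deaths: np.ndarray
    max_followup: float

    def predict(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def greenwood_variance(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 0.0
        s = self.survival[idx]
        return float(s * s * self.greenwood_terms[idx])


def km_fit(df: pd.DataFrame) -> KMFit:
    """Kaplan-Meier fit of a frame with ``time`` and ``event`` columns."""
    if df.empty:
        raise ValueError("no records")
    if not (df["time"] > 0).all():
        raise ValueError("all times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    table = kmf.event_table
    deaths = table["observed"].to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    times = table.index.to_numpy(dtype=float)
    has_death = deaths > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > deaths,
                         deaths / (at_risk * (at_risk - deaths)), np.inf)
    cum_terms = np.cumsum(np.where(has_death, terms, 0.0))
    surv_all = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    return KMFit(
        event_times=times[has_death],
        survival=surv_all[has_death],
        greenwood_terms=cum_terms[has_death],
        at_risk=at_risk[has_death],
        n_deaths=deaths[has_death],
        max_followup=float(df["time"].max()),
    )


def km_point_estimate(
    fit: KMFit, t0: float = THREE_YEARS_MONTHS, alpha: float = 0.05
) -> tuple[float, float, float, bool]:
    """S(t0) with a complementary-log-log Greenwood CI, clipped to [0, 1].

    Returns ``(estimate, ci_low, ci_high, beyond_followup)``; the flag warns
    that t0 exceeds the last follow-up time, where the CI is extrapolated.
    """
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    beyond = t0 > fit.max_followup
    if beyond:
        warnings.warn("t0 beyond last follow-up; estimate carried forward",
                      stacklevel=2)
    s = fit.predict(t0)
    if s >= 1.0:
        return 1.0, 1.0, 1.0, beyond
    if s <= 0.0 or not np.isfinite(fit.greenwood_variance(t0)):
        return max(s, 0.0), 0.0, 0.0, beyond
    z = stats.norm.ppf(1 - alpha / 2)
    idx = np.searchsorted(fit.event_times, t0, side="right") - 1
    cum = fit.greenwood_terms[idx]
    se_cloglog = math.sqrt(cum) / abs(math.log(s))
    lo = s ** math.exp(z * se_cloglog)
    hi = s ** math.exp(-z * se_cloglog)
    return s, float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)), beyond


def logrank_test(df: pd.DataFrame, group_col: str = "inflammation") -> tuple[float, float]:
    """k-sample log-rank test; returns (chi2, p) with k-1 df."""
    groups = df[group_col]
    counts = groups.value_counts()
    if len(counts) < 2 or (counts == 0).any():
        raise ValueError("need >= 2 nonempty groups")
    res = multivariate_logrank_test(df["time"], groups, df["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    coef: pd.Series
    hr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    converged: bool
    n: int
    n_events: int


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    include_interaction: bool = False,
    interaction: tuple[str, str] | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit over 0/1-coded covariate columns.

    ``include_interaction`` adds the product of the two columns named in
    ``interaction`` (default: the first two covariates), coded as the product
    of the 0/1 indicators. Wald CIs are exp(beta +/- 1.96 se). Complete
    separation or rank deficiency raises with a diagnostic.
    """
    if df["event"].sum() < 1:
        raise ValueError("need >= 1 event")
    data = df[["time", "event", *covariates]].copy().astype(float)
    if include_interaction:
        a, b = interaction if interaction else tuple(covariates[:2])
        data[f"{a}*{b}"] = data[a] * data[b]
    design = data.drop(columns=["time", "event"])
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ValueError(
            f"Cox fit did not converge (possible complete separation): {exc}"
        ) from exc
    summary = cph.summary
    return CoxFit(
        coef=summary["coef"],
        hr=summary["exp(coef)"],
        ci_low=summary["exp(coef) lower 95%"],
        ci_high=summary["exp(coef) upper 95%"],
        p=summary["p"],
        converged=True,
        n=len(data),
        n_events=int(data["event"].sum()),
    )
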