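"""ROSE-style super-enhancer calling.

Stitched H3K27ac peaks are ranked by total signal ("ROSE units") and the
hockey-stick elbow of the ranked curve — the point where the unit-scaled
curve is tangent to a slope-1 diagonal — separates super-enhancers (SEs)
from typical enhancers. Peaks that carry high H3K4me3 signal are discarded
first as transcription start sites, as is a configurable amplicon mask
(by default the MYCN locus), and the ranking is re-run on the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import (
    GenomicInterval,
    SignalPeak,
    exclude_mask,
    overlaps,
    stitch_intervals,
)

__all__ = [
    "StitchedEnhancer",
    "SECallResult",
    "stitch",
    "score_enhancers",
    "hockey_stick_cutoff",
    "filter_tss_like",
    "call_superenhancers",
]

# Default MYCN amplicon mask (hg38); overridable in config.
DEFAULT_AMPLICON_MASK = (GenomicInterval("chr2", 15_000_000, 17_000_000),)


@dataclass(frozen=True)
class StitchedEnhancer:
    interval: GenomicInterval
    constituents: tuple[SignalPeak, ...]
    signal_total: float = 0.0
    rank: int = 0  # 1 = lowest signal; 0 = not yet ranked

    def __post_init__(self) -> None:
        if self.signal_total < 0:
            raise ValueError("signal_total must be >= 0")


@dataclass(frozen=True)
class SECallResult:
    """Final SE call: ranked enhancers, the hockey-stick cutoff, SE flags."""

    enhancers: tuple[StitchedEnhancer, ...]
    cutoff_signal: float
    cutoff_rank: int
    se_flags: tuple[bool, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def superenhancers(self) -> tuple[StitchedEnhancer, ...]:
        return tuple(e for e, f in zip(self.enhancers, self.se_flags) if f)


def stitch(peaks: Sequence[SignalPeak], distance: int) -> list[StitchedEnhancer]:
    """Stitch peaks (gap <= distance) into unranked enhancer regions."""
    return [
        StitchedEnhancer(s.interval, s.constituents,
                         signal_total=sum(p.signal for p in s.constituents))
        for s in stitch_intervals(peaks, distance)
    ]


def score_enhancers(
    stitched: Sequence[StitchedEnhancer],
    input_control: Sequence[SignalPeak] | None = None,
) -> list[StitchedEnhancer]:
    """Assign signal totals and ascending ranks.

    signal_total is the sum of constituent signals minus, when an input
    control track is given, the summed signal of control peaks overlapping
    the region, floored at 0. Ranks are ascending by signal_total (rank 1 =
    lowest), ties broken by input order.
    """
    totals = []
    for e in stitched:
        total = sum(p.signal for p in e.constituents)
        if input_control:
            total -= sum(c.signal for c in input_control
                         if overlaps(e.interval, c.interval))
        totals.append(max(total, 0.0))
    order = np.argsort(np.asarray(totals), kind="stable")
    ranks = np.empty(len(stitched), dtype=int)
    ranks[order] = np.arange(1, len(stitched) + 1)
    return [
        StitchedEnhancer(e.interval, e.constituents, totals[i], int(ranks[i]))
        for i, e in enumerate(stitched)
    ]


def hockey_stick_cutoff(signals: Sequence[float]) -> tuple[float, int]:
    """Elbow of the ranked-signal ("hockey stick") curve.

    Signals are sorted ascending; rank is scaled to x = (i-1)/(N-1) and
    signal to y = y_i / max(y). The cutoff point minimizes y - x — the
    tangency point of the slope-1 diagonal approached from below; ties take
    the lowest rank. Returns ``(cutoff_signal, cutoff_rank)`` on the original
    signal scale; super-enhancers are the entries strictly above
    ``cutoff_signal``.
    """
    y = np.sort(np.asarray(signals, dtype=float))
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 signals for a cutoff")
    if y[0] == y[-1]:
        raise ValueError("constant signals: hockey-stick curve is degenerate")
    x_scaled = np.arange(n) / (n - 1)
    y_scaled = y / y[-1]
    idx = int(np.argmin(y_scaled - x_scaled))  # argmin takes the first (lowest rank)
    return float(y[idx]), idx + 1


def filter_tss_like(
    h3k27ac: Sequence[SignalPeak],
    h3k4me3: Sequence[SignalPeak],
    threshold: float = 1000.0,
) -> list[SignalPeak]:
    """Drop H3K27ac peaks that look like transcription start sites.

    A peak is discarded iff the summed signal of overlapping H3K4me3 peaks is
    strictly greater than ``threshold`` (ROSE units). Survivors are unchanged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = []
    for p in h3k27ac:
        k4 = sum(q.signal for q in h3k4me3 if overlaps(p.interval, q.interval))
        if not k4 > threshold:
            kept.append(p)
    return kept


def call_superenhancers(
    h3k27ac: Sequence[SignalPeak],
    h3k4me3: Sequence[SignalPeak],
    stitch_distance: int = 12_500,
    tss_signal_threshold: float = 1000.0,
    amplicon_mask: Sequence[GenomicInterval] = DEFAULT_AMPLICON_MASK,
    input_control: Sequence[SignalPeak] | None = None,
) -> SECallResult:
    """Full SE call for one cell line.

    Stage order: stitch -> score/rank (first pass) -> drop TSS-like peaks by
    H3K4me3 signal -> drop peaks in the amplicon mask -> re-stitch/re-score ->
    hockey-stick cutoff -> SE flags. Both passes' sizes are recorded in
    ``provenance``.
    """
    pass1 = score_enhancers(stitch(h3k27ac, stitch_distance), input_control)
    no_tss = filter_tss_like(h3k27ac, h3k4me3, tss_signal_threshold)
    masked = exclude_mask(no_tss, list(amplicon_mask))
    pass2 = score_enhancers(stitch(masked, stitch_distance), input_control)
    provenance = {
        "n_input_peaks": len(h3k27ac),
        "n_pass1_regions": len(pass1),
        "n_peaks_after_tss_filter": len(no_tss),
        "n_peaks_after_mask": len(masked),
        "n_pass2_regions": len(pass2),
    }
    if not pass2:
        return SECallResult((), float("nan"), 0, (), provenance)
    totals = [e.signal_total for e in pass2]
    try:
        cutoff_signal, cutoff_rank = hockey_stick_cutoff(totals)
    except ValueError:
        # degenerate curve (too few regions or constant signal): no SEs called
        provenance["degenerate_cutoff"] = True
        return SECallResult(tuple(pass2), float("nan"), 0,
                            tuple(False for _ in pass2), provenance)
    flags = tuple(e.signal_total > cutoff_signal for e in pass2)
    provenance["n_superenhancers"] = sum(flags)
    return SECallResult(tuple(pass2), cutoff_signal, cutoff_rank, flags, provenance)
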