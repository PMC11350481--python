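"""Genomic interval data model and the interval algebra used across the pipeline.

All coordinates are 0-based half-open (BED convention). GTF-style 1-based
inputs are converted at the reader boundary. Strand is carried but ignored by
every interval operation: enhancers are strandless regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

__all__ = [
    "GenomicInterval",
    "SignalPeak",
    "GeneAnnotation",
    "read_bed",
    "write_bed",
    "read_gene_annotation",
    "read_gtf_annotation",
    "merge_overlapping",
    "stitch_intervals",
    "window_query",
    "exclude_mask",
    "overlaps",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def distance_to_point(self, pos: int) -> int:
        """Distance from ``pos`` to the interval, 0 if inside.

        Points at the half-open ``end`` boundary are at distance 0 by
        convention (distance is measured to the closed hull ``[start, end]``).
        """
        return max(self.start - pos, pos - self.end, 0)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two regions share >= 1 base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class SignalPeak:
    """A region with a nonnegative signal (MACS2 score or ROSE units)."""

    interval: GenomicInterval
    signal: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not math.isfinite(self.signal) or self.signal < 0:
            raise ValueError(f"signal must be finite and >= 0, got {self.signal}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its transcription start site."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}: {self.tss}")
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, has_signal: bool = True) -> list[SignalPeak]:
    """Read a BED3/BED5 file into :class:`SignalPeak` records.

    Column 5 (``score``) is parsed as the signal when ``has_signal`` is true;
    otherwise the signal is 0. Comment (``#``), ``track`` and ``browser``
    lines are skipped. File order is preserved.
    """
    peaks: list[SignalPeak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            signal = 0.0
            if has_signal:
                if len(fields) < 5:
                    raise ValueError(
                        f"{path}:{lineno}: signal requested but no column 5"
                    )
                try:
                    signal = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed signal") from exc
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(SignalPeak(interval, signal, name))
    return peaks


def write_bed(peaks: Iterable[SignalPeak], path: str | Path) -> None:
    """Write peaks as BED5 (chrom, start, end, name, signal)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.signal:.10g}\n")


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a 5-column TSV annotation: gene_id, symbol, chrom, tss, strand.

    A header line starting with ``gene_id`` is tolerated. TSS is 0-based.
    Duplicate gene ids are rejected.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            gene_id, symbol, chrom, tss_s, strand = fields[:5]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            genes.append(GeneAnnotation(gene_id, symbol, chrom, int(tss_s), strand))
    return genes


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsymbol\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def read_gtf_annotation(path: str | Path, feature: str = "gene") -> list[GeneAnnotation]:
    """Import shim for GTF: extract one TSS per gene from ``feature`` lines.

    GTF is 1-based inclusive; the TSS is converted to 0-based. The TSS is the
    feature start on '+' and the feature end on '-'.
    """
    genes: dict[str, GeneAnnotation] = {}
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature:
                continue
            chrom, start1, end1, strand, attrs = (
                fields[0], int(fields[3]), int(fields[4]), fields[6], fields[8],
            )
            attr_map: dict[str, str] = {}
            for item in attrs.strip().strip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attr_map[key] = val.strip().strip('"')
            gene_id = attr_map.get("gene_id", "")
            if not gene_id:
                continue
            symbol = attr_map.get("gene_name", gene_id)
            tss = start1 - 1 if strand != "-" else end1 - 1
            genes[gene_id] = GeneAnnotation(gene_id, symbol, chrom, tss, strand if strand in _STRANDS else ".")
    return list(genes.values())


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_overlapping(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge overlapping (or touching) intervals.

    Output is sorted by (chrom, start); no two outputs overlap; the base set
    is preserved. Strand collapses to '.'.
    """
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


@dataclass(frozen=True)
class _Stitched:
    interval: GenomicInterval
    constituents: tuple[SignalPeak, ...]


def stitch_intervals(peaks: Sequence[SignalPeak], distance: int) -> list[_Stitched]:
    """ROSE-style stitching: transitively join same-chromosome peaks whose gap
    is <= ``distance`` bp. ``distance == 0`` joins only touching/overlapping
    peaks. Each output records its constituent peaks.
    """
    if distance < 0:
        raise ValueError("stitch distance must be >= 0")
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].interval.chrom,
                                                     peaks[i].interval.start,
                                                     peaks[i].interval.end))
    out: list[_Stitched] = []
    cur: list[SignalPeak] = []
    cur_chrom, cur_start, cur_end = "", 0, 0
    for i in order:
        p = peaks[i]
        iv = p.interval
        if cur and iv.chrom == cur_chrom and iv.start - cur_end <= distance:
            cur.append(p)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                out.append(_Stitched(GenomicInterval(cur_chrom, cur_start, cur_end),
                                     tuple(cur)))
            cur = [p]
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur:
        out.append(_Stitched(GenomicInterval(cur_chrom, cur_start, cur_end), tuple(cur)))
    return out


def window_query(
    annotation: Sequence[GeneAnnotation],
    regions: Sequence[GenomicInterval],
    window: int,
) -> dict[GenomicInterval, list[GeneAnnotation]]:
    """Genes whose TSS lies within ``window`` bp of each region.

    Distance is TSS to the nearest base of the region (0 if the TSS falls
    inside). Returns a mapping region -> genes in annotation order.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    result: dict[GenomicInterval, list[GeneAnnotation]] = {}
    for r in regions:
        hits = [g for g in by_chrom.get(r.chrom, ())
                if r.distance_to_point(g.tss) <= window]
        result[r] = hits
    return result


def exclude_mask(
    peaks: Sequence[SignalPeak], mask: Sequence[GenomicInterval]
) -> list[SignalPeak]:
    """Drop every peak overlapping any mask interval by >= 1 bp.

    Survivors are unchanged and keep their order.
    """
    if not mask:
        return list(peaks)
    return [p for p in peaks
            if not any(overlaps(p.interval, m) for m in mask)]
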