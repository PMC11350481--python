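"""Build lineage gene signatures from single-stranded super-enhancers.

Super-enhancers that overlap a KAS-seq peak carry single-stranded DNA and are
hence transcriptionally engaged ("ssSEs"). ssSEs from all cell lines of a
lineage are union-merged (one supporting cell line suffices), genes with a
TSS within a window (default 500 kb) of a lineage ssSE are collected, and the
signature is the intersection with the genes the differential-expression
filter declared higher in that lineage. A hypergeometric upper-tail test
compares signatures against published gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .intervals import GeneAnnotation, GenomicInterval, overlaps, merge_overlapping, window_query

__all__ = [
    "SsSE",
    "LineageSignature",
    "OverlapTestResult",
    "intersect_with_kas",
    "merge_lineage_ssse",
    "build_signature",
    "hypergeometric_overlap_test",
]


@dataclass(frozen=True)
class SsSE:
    """A single-stranded super-enhancer with its lineage and supporting lines."""

    interval: GenomicInterval
    lineage: str
    source_cell_lines: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.source_cell_lines:
            raise ValueError("ssSE needs at least one source cell line")


@dataclass(frozen=True)
class LineageSignature:
    lineage: str
    genes: tuple[str, ...]  # unique, lexicographic
    provenance: Mapping[str, dict] = field(default_factory=dict)


@dataclass(frozen=True)
class OverlapTestResult:
    overlap_count: int
    universe_size: int
    set_a_size: int
    set_b_size: int
    p: float


def intersect_with_kas(
    superenhancers: Sequence[GenomicInterval],
    kas_peaks: Sequence[GenomicInterval],
    lineage: str,
    cell_line: str,
) -> list[SsSE]:
    """Retain SEs overlapping >= 1 KAS-seq peak by >= 1 bp."""
    return [
        SsSE(se, lineage, (cell_line,))
        for se in superenhancers
        if any(overlaps(se, k) for k in kas_peaks)
    ]


def merge_lineage_ssse(
    per_cell_line: Sequence[Sequence[SsSE]], lineage: str
) -> list[SsSE]:
    """Union-merge ssSEs across cell lines of one lineage.

    No minimum recurrence: a region seen in a single cell line is retained.
    Each merged ssSE accumulates the cell lines whose intervals contributed.
    """
    pooled: list[SsSE] = []
    for lst in per_cell_line:
        for s in lst:
            if s.lineage != lineage:
                raise ValueError(
                    f"mixed lineage input: expected {lineage}, got {s.lineage}"
                )
            pooled.append(s)
    merged = merge_overlapping([s.interval for s in pooled])
    out = []
    for region in merged:
        sources = sorted({cl for s in pooled if overlaps(s.interval, region)
                          for cl in s.source_cell_lines})
        out.append(SsSE(region, lineage, tuple(sources)))
    return out


def build_signature(
    ssses: Sequence[SsSE],
    annotation: Sequence[GeneAnnotation],
    de_genes: set[str],
    window: int = 500_000,
) -> LineageSignature:
    """Signature = (genes with TSS within ``window`` of a lineage ssSE) ∩ DE genes.

    Provenance records, per signature gene, the ssSE regions that placed it
    in range. Gene order is lexicographic for determinism.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if not annotation:
        raise ValueError("empty gene annotation")
    lineages = {s.lineage for s in ssses}
    if len(lineages) > 1:
        raise ValueError(f"mixed lineages in ssSE input: {sorted(lineages)}")
    lineage = lineages.pop() if lineages else "?"
    hits = window_query(annotation, [s.interval for s in ssses], window)
    near: dict[str, list[str]] = {}
    for s in ssses:
        region = s.interval
        label = f"{region.chrom}:{region.start}-{region.end}"
        for g in hits[region]:
            near.setdefault(g.gene_id, []).append(label)
    genes = sorted(set(near) & de_genes)
    provenance = {g: {"ssse": sorted(set(near[g])), "de": True} for g in genes}
    return LineageSignature(lineage, tuple(genes), provenance)


def hypergeometric_overlap_test(
    sig_a: set[str], sig_b: set[str], universe: set[str]
) -> OverlapTestResult:
    """Upper-tail hypergeometric test of gene-set overlap.

    p = P[X >= observed overlap] for X ~ Hypergeometric(universe, |A|, |B|),
    including the observed value.
    """
    if not sig_a <= universe or not sig_b <= universe:
        raise ValueError("signatures must be subsets of the universe")
    n_u, n_a, n_b = len(universe), len(sig_a), len(sig_b)
    k = len(sig_a & sig_b)
    p = float(stats.hypergeom.sf(k - 1, n_u, n_a, n_b))
    return OverlapTestResult(k, n_u, n_a, n_b, min(p, 1.0))
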