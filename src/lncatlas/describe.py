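"""Descriptive atlas statistics: genomic context, strand split, lengths.

A lncRNA's genomic context is classified relative to protein-coding
transcripts with the precedence exonic > intronic > upstream >
downstream > intergenic; sense/antisense orientation is defined
relative to the partner coding transcript, not the absolute genome
strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import AnnotationSet, GenomicInterval, TranscriptModel

CONTEXT_CATEGORIES = ("exonic", "intronic", "upstream", "downstream", "intergenic")

__all__ = [
    "ContextLabel",
    "ContextProportions",
    "CONTEXT_CATEGORIES",
    "classify_context",
    "strand_split",
    "length_histogram",
    "chromosome_stats",
    "compare_proportions",
]


@dataclass(frozen=True)
class ContextLabel:
    category: str  # exonic | intronic | upstream | downstream | intergenic
    orientation: str  # sense | antisense | unassigned
    partner_gene: str | None

    def __post_init__(self) -> None:
        if (self.partner_gene is None) != (self.category == "intergenic"):
            raise ValueError("partner_gene is None iff category is intergenic")
        if self.partner_gene is None and self.orientation != "unassigned":
            raise ValueError("intergenic labels have unassigned orientation")


@dataclass(frozen=True)
class ContextProportions:
    group: str
    proportions: Mapping[str, float]
    n_features: int

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if self.n_features and abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")


def _upstream_region(t: TranscriptModel, window_bp: int) -> GenomicInterval | None:
    """The window 5' of the TSS, strand-aware; None if it has zero width."""
    span = t.span
    if t.strand == "-":
        return GenomicInterval(t.chrom, span.end, span.end + window_bp)
    start = max(0, span.start - window_bp)
    if start == span.start:
        return None
    return GenomicInterval(t.chrom, start, span.start)


def _downstream_region(t: TranscriptModel, window_bp: int) -> GenomicInterval | None:
    span = t.span
    if t.strand == "-":
        start = max(0, span.start - window_bp)
        if start == span.start:
            return None
        return GenomicInterval(t.chrom, start, span.start)
    return GenomicInterval(t.chrom, span.end, span.end + window_bp)


def _pick_partner(
    lnc: TranscriptModel, candidates: list[TranscriptModel]
) -> TranscriptModel:
    """Nearest by span distance, then lexicographic gene then transcript id."""
    span = lnc.span
    return min(
        candidates,
        key=lambda t: (span.distance_to(t.span), t.gene_id, t.transcript_id),
    )


def classify_context(
    lnc: TranscriptModel, ann: AnnotationSet, window_bp: int = 10000
) -> ContextLabel:
    """Classify a lncRNA's position relative to coding transcripts.

    Precedence: exonic (any exon/exon overlap) > intronic (span inside a
    coding span, introns only) > upstream (span overlaps the window 5' of
    a coding TSS) > downstream (3' analogue) > intergenic.
    """
    span = lnc.span
    probe = GenomicInterval(
        span.chrom, max(0, span.start - window_bp), span.end + window_bp
    )
    coding = [
        ann[tid]
        for tid in ann.query(probe)
        if ann[tid].biotype == "protein_coding"
    ]

    exonic = [
        t
        for t in coding
        if any(le.overlaps(ce) for le in lnc.exons for ce in t.exons)
    ]
    if exonic:
        return _label("exonic", lnc, _pick_partner(lnc, exonic))

    intronic = [
        t
        for t in coding
        if t.span.start <= span.start and span.end <= t.span.end
    ]
    if intronic:
        return _label("intronic", lnc, _pick_partner(lnc, intronic))

    upstream = [
        t
        for t in coding
        if (r := _upstream_region(t, window_bp)) is not None and span.overlaps(r)
    ]
    if upstream:
        return _label("upstream", lnc, _pick_partner(lnc, upstream))

    downstream = [
        t
        for t in coding
        if (r := _downstream_region(t, window_bp)) is not None and span.overlaps(r)
    ]
    if downstream:
        return _label("downstream", lnc, _pick_partner(lnc, downstream))

    return ContextLabel("intergenic", "unassigned", None)


def _label(category: str, lnc: TranscriptModel, partner: TranscriptModel) -> ContextLabel:
    if lnc.strand == "." or partner.strand == ".":
        orientation = "unassigned"
    elif lnc.strand == partner.strand:
        orientation = "sense"
    else:
        orientation = "antisense"
    return ContextLabel(category, orientation, partner.gene_id)


def strand_split(labels: Sequence[ContextLabel]) -> tuple[float, float]:
    """(sense, antisense) fractions over labels with assigned orientation."""
    assigned = [l for l in labels if l.orientation in ("sense", "antisense")]
    if not assigned:
        raise ValueError("no labels with assigned orientation")
    n_sense = sum(l.orientation == "sense" for l in assigned)
    return n_sense / len(assigned), 1 - n_sense / len(assigned)


def length_histogram(
    lncs: Sequence[TranscriptModel],
    bin_width: int = 100,
    min_length: int = 200,
    strict: bool = False,
) -> list[tuple[str, int]]:
    """Spliced-length histogram in [k*w, (k+1)*w) bins, sparse and ordered.

    lncRNAs are by definition longer than ``min_length`` nt; shorter
    entries trigger a warning (or an error when ``strict``).
    """
    lengths = [t.spliced_length for t in lncs]
    short = [t.transcript_id for t in lncs if t.spliced_length <= min_length]
    if short:
        msg = f"{len(short)} transcripts with spliced length <= {min_length}: {short[:5]}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    counts: dict[int, int] = {}
    for L in lengths:
        counts[L // bin_width] = counts.get(L // bin_width, 0) + 1
    return [
        (f"{k * bin_width}-{(k + 1) * bin_width}", counts[k])
        for k in sorted(counts)
    ]


def modal_length_bin(
    lncs: Sequence[TranscriptModel], bin_width: int = 100
) -> str:
    """Label of the most populated spliced-length bin (smallest on ties)."""
    hist = length_histogram(lncs, bin_width=bin_width)
    if not hist:
        raise ValueError("empty input")
    return max(hist, key=lambda kv: (kv[1], kv[0]))[0]


def chromosome_stats(
    lncs: Sequence[TranscriptModel], chrom_sizes: Mapping[str, int]
) -> dict[str, tuple[int, float]]:
    """Per-chromosome (lncRNA count, density per Mb); zero for empty chroms."""
    missing = {t.chrom for t in lncs} - set(chrom_sizes)
    if missing:
        raise ValueError(f"chromosomes without a size: {sorted(missing)}")
    counts = {c: 0 for c in chrom_sizes}
    for t in lncs:
        counts[t.chrom] += 1
    return {
        c: (counts[c], counts[c] / (chrom_sizes[c] / 1e6) if chrom_sizes[c] else 0.0)
        for c in chrom_sizes
    }


def compare_proportions(a: Sequence[float], b: Sequence[float]) -> float:
    """Welch two-sample t-test p-value between two sets of proportions.

    With zero variance on both sides and equal means the test is
    degenerate and p = 1 is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per side")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
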