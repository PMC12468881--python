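"""Positional conservation of lifted foreign lncRNAs against the pig atlas.

A foreign (human/mouse) lncRNA whose genome-lifted coordinates overlap
any pig lncRNA span by at least ``min_overlap_bp`` is called
positionally conserved. Overlap is strand-agnostic by default; when a
source id maps to several lifted fragments, any overlapping fragment
makes the source conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .annotation import AnnotationSet, GenomicInterval

__all__ = ["ConservationRecord", "ConservationReport", "call_conserved", "conservation_report"]


@dataclass(frozen=True)
class ConservationRecord:
    source_id: str
    lifted: GenomicInterval | None  # None when LiftOver failed upstream
    overlaps: tuple[str, ...]  # pig lncRNA transcript ids
    conserved: bool

    def __post_init__(self) -> None:
        if self.conserved != (self.lifted is not None and len(self.overlaps) > 0):
            raise ValueError("conserved iff lifted present and overlaps non-empty")


@dataclass(frozen=True)
class ConservationReport:
    n_source: int
    n_mapped: int
    n_conserved: int
    rate_pct: float  # 100 * n_conserved / n_source, one decimal, half-up

    def __post_init__(self) -> None:
        if not (0 <= self.n_conserved <= self.n_mapped <= self.n_source):
            raise ValueError("require n_conserved <= n_mapped <= n_source")


def call_conserved(
    lifted: list[tuple[GenomicInterval, str]],
    pig_lncs: AnnotationSet,
    min_overlap_bp: int = 1,
    match_strand: bool = False,
    unmapped_ids: list[str] = (),
) -> list[ConservationRecord]:
    """Call conservation for lifted (interval, source id) pairs.

    Multiple fragments per source id are merged into one record; ids in
    ``unmapped_ids`` produce unmapped, non-conserved records.
    """
    per_source: dict[str, tuple[GenomicInterval, set[str]]] = {}
    order: list[str] = []
    for iv, sid in lifted:
        hits = set()
        for tid in pig_lncs.query(iv):
            t = pig_lncs[tid]
            if t.biotype != "lncRNA":
                continue
            if match_strand and iv.strand != "." and t.strand != iv.strand:
                continue
            if iv.overlap_bp(t.span) >= min_overlap_bp:
                hits.add(tid)
        if sid not in per_source:
            per_source[sid] = (iv, hits)
            order.append(sid)
        else:
            prev_iv, prev_hits = per_source[sid]
            # keep the first fragment as the representative interval
            per_source[sid] = (prev_iv, prev_hits | hits)
    records = [
        ConservationRecord(sid, per_source[sid][0],
                           tuple(sorted(per_source[sid][1])),
                           bool(per_source[sid][1]))
        for sid in order
    ]
    for sid in unmapped_ids:
        records.append(ConservationRecord(sid, None, (), False))
    return records


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def conservation_report(
    records: list[ConservationRecord] | None,
    n_source: int,
    n_conserved: int | None = None,
    n_mapped: int | None = None,
) -> ConservationReport:
    """Summarise conservation calls as counts and a percentage of n_source.

    Counts can be passed directly (records=None) to reproduce published
    arithmetic; the rate is rounded half-up to one decimal.
    """
    if n_source <= 0:
        raise ValueError("n_source must be positive")
    if records is not None:
        if n_source < len(records):
            raise ValueError("n_source smaller than the number of records")
        n_mapped = sum(r.lifted is not None for r in records)
        n_conserved = sum(r.conserved for r in records)
    else:
        if n_conserved is None:
            raise ValueError("need records or explicit counts")
        n_mapped = n_conserved if n_mapped is None else n_mapped
    return ConservationReport(
        n_source=n_source,
        n_mapped=n_mapped,
        n_conserved=n_conserved,
        rate_pct=_round_half_up_1dp(100.0 * n_conserved / n_source),
    )
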