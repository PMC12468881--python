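"""Genomic annotation containers and GTF/BED input/output.

All coordinates are held internally as 0-based half-open intervals.
GTF input/output converts at the boundary (GTF is 1-based inclusive);
BED shares the internal convention. Chromosome names are compared as
exact strings — no "chr"-prefix normalisation is applied unless the
caller opts in via :func:`parse_gtf`'s ``normalize_chrom``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "AnnotationSet",
    "GtfParseError",
    "parse_gtf",
    "write_gtf",
    "parse_bed",
    "write_bed",
    "query_overlaps",
]


class GtfParseError(ValueError):
    """Raised when a GTF/BED record cannot be interpreted."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Edge-to-edge distance in bp; 0 when overlapping; None across chroms."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered exon chain on one chromosome and strand."""

    transcript_id: str
    gene_id: str
    biotype: str  # lncRNA | protein_coding | circRNA
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons must share one chrom and strand"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        """[min exon start, max exon end) — the genomic footprint."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (0-based position of the first transcribed base)."""
        if self.strand == "-":
            return self.exons[-1].end - 1
        return self.exons[0].start

    def introns(self) -> tuple[GenomicInterval, ...]:
        gaps = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                gaps.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(gaps)


class AnnotationSet:
    """Indexed collection of transcript models with per-chromosome lookup.

    The interval index stores transcript spans; :meth:`query` returns
    exactly the transcripts whose span overlaps the query by >= 1 bp
    (strand ignored), matching a linear scan.
    """

    def __init__(
        self,
        transcripts: Iterable[TranscriptModel] = (),
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes or {})
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript id {t.transcript_id!r}")
        self.transcripts[t.transcript_id] = t
        span = t.span
        self._trees.setdefault(span.chrom, IntervalTree()).addi(
            span.start, span.end, t.transcript_id
        )
        if span.chrom not in self.chrom_sizes:
            self.chrom_sizes[span.chrom] = span.end
        else:
            self.chrom_sizes[span.chrom] = max(self.chrom_sizes[span.chrom], span.end)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def by_biotype(self, biotype: str) -> list[TranscriptModel]:
        return [t for t in self if t.biotype == biotype]

    def query(self, q: GenomicInterval) -> list[str]:
        """Transcript ids whose span overlaps ``q`` (sorted for determinism)."""
        tree = self._trees.get(q.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(q.start, q.end))


def query_overlaps(ann: AnnotationSet, q: GenomicInterval) -> list[str]:
    """Functional alias for :meth:`AnnotationSet.query`."""
    return ann.query(q)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_BIOTYPE_KEYS = ("transcript_biotype", "gene_biotype", "biotype")


def parse_gtf(
    text: str,
    default_biotype: str = "lncRNA",
    normalize_chrom: bool = False,
) -> AnnotationSet:
    """Parse GTF content (Ensembl-dialect attributes) into an AnnotationSet.

    Only ``exon`` features are consumed; every other feature line is
    ignored. GTF's 1-based inclusive coordinates become 0-based
    half-open. ``normalize_chrom`` strips a leading ``chr`` prefix.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line, dialect=None)
        except Exception as exc:  # gffutils raises assorted types
            raise GtfParseError(f"line {lineno}: cannot parse GTF record: {exc}")
        if feat.featuretype != "exon":
            continue
        if feat.end < feat.start:
            raise GtfParseError(f"line {lineno}: end < start")
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except (KeyError, IndexError):
            raise GtfParseError(
                f"line {lineno}: missing transcript_id/gene_id attribute"
            )
        chrom = feat.seqid
        if normalize_chrom and chrom.startswith("chr"):
            chrom = chrom[3:]
        strand = feat.strand if feat.strand in STRANDS else "."
        iv = GenomicInterval(chrom, feat.start - 1, feat.end, strand)
        if tid not in meta:
            biotype = default_biotype
            for key in _BIOTYPE_KEYS:
                if key in feat.attributes:
                    biotype = feat.attributes[key][0]
                    break
            meta[tid] = (gid, biotype)
            order.append(tid)
        exons_by_tx.setdefault(tid, []).append(iv)

    ann = AnnotationSet()
    for tid in order:
        gid, biotype = meta[tid]
        ann.add(TranscriptModel(tid, gid, biotype, tuple(exons_by_tx[tid])))
    return ann


def write_gtf(ann: AnnotationSet, source: str = "lncatlas") -> str:
    """Serialise an AnnotationSet as exon-level GTF (1-based inclusive)."""
    lines = []
    for tid in sorted(ann.transcripts):
        t = ann[tid]
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'transcript_biotype "{t.biotype}";'
        )
        for e in t.exons:
            lines.append(
                "\t".join(
                    (
                        e.chrom,
                        source,
                        "exon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        e.strand,
                        ".",
                        attrs,
                    )
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def write_bed(intervals: Sequence[GenomicInterval], names: Sequence[str]) -> str:
    """Serialise named intervals as BED6 (0-based half-open, strand col 6)."""
    if len(intervals) != len(names):
        raise ValueError("intervals and names must have equal length")
    lines = [
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}"
        for iv, name in zip(intervals, names)
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def parse_bed(text: str) -> list[tuple[GenomicInterval, str]]:
    """Parse BED6 text into (interval, name) pairs, preserving order."""
    records = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GtfParseError(f"line {lineno}: BED needs >= 3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
        strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
        try:
            iv = GenomicInterval(chrom, start, end, strand)
        except ValueError as exc:
            raise GtfParseError(f"line {lineno}: {exc}")
        records.append((iv, name))
    return records
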