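"""Cis-target assignment, co-expression hub selection, DE thresholding,
and ceRNA network assembly.

Cis targets are coding genes within +/-100 kb of a lncRNA locus whose
expression correlates with the lncRNA at Pearson r > 0.6 (strict). Hub
features satisfy |module membership| > 0.8 and |gene significance| >
0.2 (strict), where MM is the Pearson correlation with the module
eigengene (first principal component of the standardised module) and
GS the correlation with a binary one-vs-rest tissue indicator.
Differential expression requires Benjamini-Hochberg adjusted p < 0.05
(strict) and |log2FC| >= 1 (inclusive). ceRNA triples join retained
sponge-miRNA and miRNA-mRNA edges (miRanda-style score > 140 and
energy < -20 kcal/mol, both strict) on the shared miRNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationSet, GenomicInterval, TranscriptModel
from .quantify import ExpressionMatrix

__all__ = [
    "CisTarget",
    "ModuleStats",
    "DERecord",
    "InteractionEdge",
    "CeRNATriple",
    "find_cis_candidates",
    "correlate_and_select",
    "nearest_coding_gene",
    "module_eigengene",
    "module_membership_gs",
    "select_hubs",
    "benjamini_hochberg",
    "select_de",
    "filter_interactions",
    "assemble_cerna",
]


@dataclass(frozen=True)
class CisTarget:
    lnc_id: str
    gene_id: str
    distance: int  # bp between closest span edges, 0 if overlapping
    r: float  # Pearson correlation across samples


@dataclass(frozen=True)
class ModuleStats:
    feature: str
    module: str
    mm: float | None  # correlation with the module eigengene
    gs: float | None  # correlation with the trait indicator
    is_hub: bool


@dataclass(frozen=True)
class DERecord:
    feature: str
    contrast: str
    log2fc: float
    p_raw: float
    p_adj: float
    is_de: bool


@dataclass(frozen=True)
class InteractionEdge:
    source: str
    target: str
    score: float
    energy: float  # kcal/mol


@dataclass(frozen=True, order=True)
class CeRNATriple:
    sponge: str  # lncRNA or circRNA
    mirna: str
    mrna: str


def gene_spans(ann: AnnotationSet, biotype: str = "protein_coding") -> dict[str, GenomicInterval]:
    """Per-gene genomic footprint: union span over the gene's transcripts."""
    spans: dict[str, GenomicInterval] = {}
    for t in ann.by_biotype(biotype):
        s = t.span
        prev = spans.get(t.gene_id)
        if prev is None:
            spans[t.gene_id] = s
        elif prev.chrom == s.chrom:
            spans[t.gene_id] = GenomicInterval(
                s.chrom, min(prev.start, s.start), max(prev.end, s.end), prev.strand
            )
    return spans


def find_cis_candidates(
    lnc: TranscriptModel, ann: AnnotationSet, window_bp: int = 100_000
) -> list[tuple[str, int]]:
    """Coding genes within ``window_bp`` of the lncRNA span (edge-to-edge).

    Overlap counts as distance 0; strand is ignored; both directions are
    searched. Sorted by (distance, gene id).
    """
    span = lnc.span
    out = []
    for gid, gspan in gene_spans(ann).items():
        d = span.distance_to(gspan)
        if d is not None and d <= window_bp:
            out.append((gid, d))
    return sorted(out, key=lambda x: (x[1], x[0]))


def nearest_coding_gene(lnc: TranscriptModel, ann: AnnotationSet) -> str | None:
    """Closest coding gene on the lncRNA's chromosome; ties break on id."""
    span = lnc.span
    best: tuple[int, str] | None = None
    for gid, gspan in gene_spans(ann).items():
        d = span.distance_to(gspan)
        if d is None:
            continue
        if best is None or (d, gid) < best:
            best = (d, gid)
    return best[1] if best else None


def correlate_and_select(
    pairs: list[tuple[str, str, int]],
    em: ExpressionMatrix,
    r_min: float = 0.6,
) -> list[CisTarget]:
    """Keep (lnc, gene, distance) pairs with Pearson r strictly above r_min.

    Zero-variance profiles make r undefined; such pairs are dropped with
    a warning.
    """
    if len(em.samples) < 3:
        raise ValueError("correlation needs >= 3 samples")
    out = []
    for lnc_id, gene_id, distance in pairs:
        x = em.values.loc[lnc_id].to_numpy(dtype=float)
        y = em.values.loc[gene_id].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"zero-variance profile in pair ({lnc_id}, {gene_id}); dropped")
            continue
        r = float(stats.pearsonr(x, y).statistic)
        if r > r_min:
            out.append(CisTarget(lnc_id, gene_id, distance, r))
    return out


def module_eigengene(module_values: pd.DataFrame) -> pd.Series:
    """Module eigengene: first right-singular vector of the feature-standardised
    module matrix (features as rows), sign-fixed so the mean per-feature
    correlation with it is >= 0.

    Zero-variance features are excluded with a warning.
    """
    X = module_values.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 3:
        raise ValueError("module eigengene needs >= 2 features and >= 3 samples")
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance features from eigengene"
        )
    X = X[keep]
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 non-constant features in module")
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    corrs = [np.corrcoef(row, eig)[0, 1] for row in Z]
    if np.mean(corrs) < 0:
        eig = -eig
    return pd.Series(eig, index=module_values.columns, name="eigengene")


def _pearson_or_none(x: np.ndarray, y: np.ndarray) -> float | None:
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def module_membership_gs(
    profile, eigengene, trait
) -> tuple[float | None, float | None]:
    """(MM, GS) = Pearson correlations of a feature profile with the module
    eigengene and with a binary trait indicator; None where undefined."""
    x = np.asarray(profile, dtype=float)
    e = np.asarray(eigengene, dtype=float)
    t = np.asarray(trait, dtype=float)
    if not (len(x) == len(e) == len(t)) or len(x) < 3:
        raise ValueError("profile, eigengene and trait need equal length >= 3")
    return _pearson_or_none(x, e), _pearson_or_none(x, t)


def select_hubs(
    stats_list: list[ModuleStats] | list[tuple],
    mm_min: float = 0.8,
    gs_min: float = 0.2,
) -> set[str]:
    """Features with |MM| > mm_min and |GS| > gs_min (both strict).

    Missing MM or GS disqualifies a feature.
    """
    hubs = set()
    for s in stats_list:
        feature, mm, gs = (
            (s.feature, s.mm, s.gs) if isinstance(s, ModuleStats) else (s[0], s[1], s[2])
        )
        if mm is None or gs is None:
            continue
        if abs(mm) > mm_min and abs(gs) > gs_min:
            hubs.add(feature)
    return hubs


def benjamini_hochberg(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de(
    table: pd.DataFrame,
    fdr: float = 0.05,
    lfc: float = 1.0,
    adjust: bool = True,
) -> list[DERecord]:
    """Call differential expression: p_adj < fdr (strict) and |log2fc| >= lfc.

    ``table`` needs columns feature, contrast, log2fc and either p (raw,
    adjusted per contrast when ``adjust``) or p_adj.
    """
    df = table.copy()
    if "p_adj" not in df.columns:
        if not adjust:
            raise ValueError("table has no p_adj column and adjust=False")
        df["p_adj"] = np.nan
        for _, idx in df.groupby("contrast").groups.items():
            df.loc[idx, "p_adj"] = benjamini_hochberg(df.loc[idx, "p"].to_numpy())
    records = []
    for row in df.itertuples(index=False):
        is_de = (row.p_adj < fdr) and (abs(row.log2fc) >= lfc)
        records.append(
            DERecord(
                feature=row.feature,
                contrast=row.contrast,
                log2fc=float(row.log2fc),
                p_raw=float(getattr(row, "p", row.p_adj)),
                p_adj=float(row.p_adj),
                is_de=bool(is_de),
            )
        )
    return records


def filter_interactions(edges: pd.DataFrame | list[InteractionEdge],
                        score_min: float = 140.0,
                        energy_max: float = -20.0) -> list[InteractionEdge]:
    """Retain miRanda-style edges with score > score_min and energy < energy_max
    (both strict); edges with missing fields are dropped with a warning."""
    if isinstance(edges, pd.DataFrame):
        rows = [
            InteractionEdge(str(r.source), str(r.target), r.score, r.energy)
            if pd.notna(r.score) and pd.notna(r.energy)
            else None
            for r in edges.itertuples(index=False)
        ]
        n_bad = sum(r is None for r in rows)
        if n_bad:
            warnings.warn(f"dropping {n_bad} edges with missing score/energy")
        edges = [r for r in rows if r is not None]
    return [e for e in edges if e.score > score_min and e.energy < energy_max]


def assemble_cerna(
    sponge_mirna: list[InteractionEdge], mirna_mrna: list[InteractionEdge]
) -> list[CeRNATriple]:
    """Join already-filtered edge sets on the shared miRNA.

    A triple (sponge, miRNA, mRNA) exists iff both constituent edges do;
    output is deduplicated and sorted for determinism.
    """
    by_mirna: dict[str, set[str]] = {}
    for e in mirna_mrna:
        by_mirna.setdefault(e.source, set()).add(e.target)
    triples = {
        CeRNATriple(e.source, e.target, g)
        for e in sponge_mirna
        for g in by_mirna.get(e.target, ())
    }
    return sorted(triples)


def top_sponges(
    edges: list[InteractionEdge], n: int = 5, agg: str = "max"
) -> list[str]:
    """Top-n sponges by aggregated interaction score (max by default, or sum)."""
    if agg not in ("max", "sum"):
        raise ValueError("agg must be 'max' or 'sum'")
    scores: dict[str, float] = {}
    for e in edges:
        if agg == "max":
            scores[e.source] = max(scores.get(e.source, -np.inf), e.score)
        else:
            scores[e.source] = scores.get(e.source, 0.0) + e.score
    return [s for s, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:n]]
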