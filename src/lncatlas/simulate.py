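"""Synthetic multi-tissue atlas data with planted ground truth.

Every input the analysis pipeline consumes can be generated here:
an annotation with known genomic contexts, negative-binomial count
matrices with planted housekeeping and tissue-specific features, lifted
cross-species intervals with a known conserved subset, DE tables with
planted effects, and miRanda-style interaction edges. All generators
are deterministic given their seed; one global seed fans out to
per-generator child seeds by fixed offsets (annotation +1000, counts
+2000, lifted +3000, DE +4000, edges +5000) so each stage is
reproducible in isolation.

Layout model: each protein-coding gene occupies a fixed-pitch slot
(gene body 20 kb: two 2 kb exons flanking a 16 kb intron), leaving
ample margins so upstream/downstream windows of neighbouring genes
never collide and planted context labels are exactly recoverable by
the context classifier. lncRNAs are single-exon; spliced lengths are
drawn from a log-normal whose mode sits at 850 nt (truncated to the
>200 nt lncRNA definition).

Planted expression classes: housekeeping features share one high mean
across tissues (cross-tissue CV well below 1); tissue-specific features
are 10x higher in their home tissue than anywhere else; background
features are expressed in exactly two tissues at comparable levels,
which keeps their cross-tissue CV above 1 (never housekeeping) while
their top/second tissue ratio stays below 3 (never tissue-specific).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GenomicInterval, TranscriptModel
from .describe import ContextLabel
from .quantify import CountMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "sample_spliced_lengths",
    "generate_annotation",
    "generate_counts",
    "generate_lifted_bed",
    "generate_de_tables",
    "generate_interactions",
    "stage_templates",
]

DEFAULT_TISSUES = ("heart", "ileum", "liver", "lung", "pituitary")
DEFAULT_CONTEXT_MIX = {
    "exonic": 0.5,
    "intronic": 0.3,
    "upstream": 0.1,
    "downstream": 0.1,
    "intergenic": 0.0,
}

# slot geometry (bp)
_PITCH = 300_000
_GENE_OFF = 60_000
_EXON = 2_000
_INTRON = 16_000
_GENE_LEN = 2 * _EXON + _INTRON  # 20 kb
_MAX_LNC_LEN = 14_000  # fits the intron and the exonic placement margins


@dataclass
class SimConfig:
    """Default study conditions for the synthetic atlas."""

    n_genes: int = 400
    n_lncs: int = 2000
    n_chroms: int = 5
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_samples_per_tissue: int = 4
    n_hk: int = 200
    n_ts: int = 300
    seed: int = 42
    context_mix: dict = field(default_factory=lambda: dict(DEFAULT_CONTEXT_MIX))
    sense_frac: float = 0.25
    length_mode: float = 850.0
    length_sigma: float = 0.4
    window_bp: int = 10_000
    dispersion: float = 0.05
    hk_mean: float = 500.0
    ts_home_mean: float = 1500.0
    ts_fold: float = 10.0
    bg_mean: float = 50.0
    bg_sigma: float = 1.0
    frac_conserved: float = 0.1
    n_foreign: int = 500
    jitter_bp: int = 50
    contrasts: tuple[str, ...] = ("AF1_vs_AF2", "AF2_vs_AF3", "AF3_vs_AF4", "AF4_vs_AF5")
    n_de: int = 50
    effect_lfc: float = 2.0


@dataclass
class SyntheticTruth:
    planted_housekeeping: set
    planted_tissue_specific: dict
    planted_context: dict
    planted_conserved: set
    planted_de: dict
    generator_config: dict


def sample_spliced_lengths(
    n: int, rng: np.random.Generator, mode: float = 850.0, sigma: float = 0.4,
    min_length: int = 200, max_length: int = _MAX_LNC_LEN,
) -> np.ndarray:
    """Log-normal spliced lengths with density mode at ``mode`` nt.

    For a log-normal, mode = exp(mu - sigma^2); lengths are truncated by
    resampling to (min_length, max_length] — both tails carry negligible
    mass at the defaults.
    """
    mu = np.log(mode) + sigma**2
    out = np.empty(n, dtype=int)
    todo = np.arange(n)
    while todo.size:
        draw = rng.lognormal(mu, sigma, todo.size).astype(int)
        ok = (draw > min_length) & (draw <= max_length)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def generate_annotation(
    n_genes: int = 400,
    n_lncs: int = 2000,
    n_chroms: int = 5,
    seed: int = 42,
    context_mix: dict | None = None,
    sense_frac: float = 0.25,
    length_mode: float = 850.0,
    length_sigma: float = 0.4,
) -> tuple[AnnotationSet, dict[str, ContextLabel]]:
    """Place coding genes on a fixed-pitch grid and lncRNAs at positions
    realising the configured context/orientation mix; return the
    annotation plus the planted context truth."""
    if n_genes < 1 or n_lncs < 0 or n_chroms < 1:
        raise ValueError("sizes must be positive")
    mix = dict(DEFAULT_CONTEXT_MIX if context_mix is None else context_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("context mix must sum to 1")
    rng = np.random.default_rng(seed)

    ann = AnnotationSet()
    gene_strands = rng.choice(["+", "-"], size=n_genes)
    genes: list[tuple[str, int, str]] = []  # (gene_id, slot base, strand) per gene
    slots_per_chrom = -(-n_genes // n_chroms)
    for c in range(n_chroms):
        ann.chrom_sizes[f"chr{c + 1}"] = (slots_per_chrom + 1) * _PITCH
    for g in range(n_genes):
        chrom = f"chr{g % n_chroms + 1}"
        base = (g // n_chroms) * _PITCH
        strand = str(gene_strands[g])
        gid = f"G{g:05d}"
        e1 = GenomicInterval(chrom, base + _GENE_OFF, base + _GENE_OFF + _EXON, strand)
        e2 = GenomicInterval(
            chrom, base + _GENE_OFF + _EXON + _INTRON,
            base + _GENE_OFF + _GENE_LEN, strand,
        )
        ann.add(TranscriptModel(f"{gid}.t1", gid, "protein_coding", (e1, e2)))
        genes.append((gid, base, strand))

    cats = list(mix)
    lnc_cats = rng.choice(cats, size=n_lncs, p=[mix[c] for c in cats])
    lengths = sample_spliced_lengths(n_lncs, rng, length_mode, length_sigma)
    sense = rng.random(n_lncs) < sense_frac
    host = rng.integers(0, n_genes, size=n_lncs)
    truth: dict[str, ContextLabel] = {}
    for i in range(n_lncs):
        lid = f"LNC{i:05d}"
        cat = str(lnc_cats[i])
        L = int(lengths[i])
        gid, base, gstrand = genes[host[i]]
        chrom = f"chr{host[i] % n_chroms + 1}"
        gene_start = base + _GENE_OFF
        gene_end = base + _GENE_OFF + _GENE_LEN
        if cat == "exonic":
            start = gene_start + 500  # inside exon 1 -> guaranteed exon overlap
        elif cat == "intronic":
            start = gene_start + _EXON + 1000  # 1 kb inside the intron
        elif cat == "upstream":
            if gstrand == "+":
                start = gene_start - 100 - L
            else:
                start = gene_end + 100
        elif cat == "downstream":
            if gstrand == "+":
                start = gene_end + 100
            else:
                start = gene_start - 100 - L
        elif cat == "intergenic":
            start = base + 2 * _GENE_OFF  # > window from every gene span
        else:
            raise ValueError(f"unknown context category {cat!r}")
        if cat == "intergenic":
            strand = str(rng.choice(["+", "-"]))
            orientation = "unassigned"
            partner = None
        else:
            strand = gstrand if sense[i] else ("-" if gstrand == "+" else "+")
            orientation = "sense" if sense[i] else "antisense"
            partner = gid
        ann.add(
            TranscriptModel(
                lid, lid, "lncRNA",
                (GenomicInterval(chrom, start, start + L, strand),),
            )
        )
        truth[lid] = ContextLabel(cat, orientation, partner)
    return ann, truth


def generate_counts(
    feature_ids: list[str],
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    n_samples_per_tissue: int = 4,
    n_hk: int = 200,
    n_ts: int = 300,
    seed: int = 42,
    dispersion: float = 0.05,
    hk_mean: float = 500.0,
    ts_home_mean: float = 1500.0,
    ts_fold: float = 10.0,
    bg_mean: float = 50.0,
    bg_sigma: float = 1.0,
) -> tuple[CountMatrix, set[str], dict[str, str]]:
    """Negative-binomial counts with planted housekeeping and tissue-specific
    features; returns (counts, housekeeping ids, tissue-specific id->tissue).

    Per-feature dispersions are Gamma-distributed around ``dispersion``;
    per-sample library-size factors vary uniformly within +/-30%.
    """
    n_feat = len(feature_ids)
    if n_hk + n_ts > n_feat:
        raise ValueError("n_hk + n_ts exceeds the number of features")
    if ts_fold < 3:
        raise ValueError("ts_fold below the specificity ratio threshold is infeasible")
    n_t = len(tissues)
    if n_t < 2:
        raise ValueError("need >= 2 tissues")
    rng = np.random.default_rng(seed)

    perm = rng.permutation(n_feat)
    hk_idx = perm[:n_hk]
    ts_idx = perm[n_hk:n_hk + n_ts]
    bg_idx = perm[n_hk + n_ts:]
    home = rng.integers(0, n_t, size=n_ts)

    mu = np.empty((n_feat, n_t))
    mu[hk_idx] = rng.lognormal(np.log(hk_mean), 0.3, size=n_hk)[:, None]
    ts_home_mu = rng.lognormal(np.log(ts_home_mean), 0.4, size=n_ts)
    mu[ts_idx] = (ts_home_mu / ts_fold)[:, None]
    mu[ts_idx, home] = ts_home_mu
    bg_mu = rng.lognormal(np.log(bg_mean), bg_sigma, size=len(bg_idx))
    bg_rows = np.full((len(bg_idx), n_t), 0.02) * bg_mu[:, None]
    for k in range(len(bg_idx)):
        active = rng.choice(n_t, size=2, replace=False)
        bg_rows[k, active] = bg_mu[k] * rng.uniform(0.8, 1.25, size=2)
    mu[bg_idx] = bg_rows

    disp = rng.gamma(shape=4.0, scale=dispersion / 4.0, size=n_feat)
    disp = np.maximum(disp, 1e-4)
    size = 1.0 / disp  # NB "number of failures" parameter

    samples, groups = [], {}
    cols = []
    for t_i, t in enumerate(tissues):
        for s_i in range(n_samples_per_tissue):
            name = f"{t}_s{s_i + 1}"
            samples.append(name)
            groups[name] = t
            depth = rng.uniform(0.7, 1.3)
            m = np.maximum(mu[:, t_i] * depth, 1e-8)
            p = size / (size + m)
            cols.append(rng.negative_binomial(size, p))
    counts = pd.DataFrame(
        np.column_stack(cols), index=feature_ids, columns=samples
    )
    cm = CountMatrix(counts, pd.Series(groups))
    hk_ids = {feature_ids[i] for i in hk_idx}
    ts_ids = {feature_ids[i]: tissues[home[k]] for k, i in enumerate(ts_idx)}
    return cm, hk_ids, ts_ids


def _lnc_free_gaps(ann: AnnotationSet, min_width: int) -> list[GenomicInterval]:
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in ann.chrom_sizes}
    for t in ann.by_biotype("lncRNA"):
        s = t.span
        spans[s.chrom].append((s.start, s.end))
    gaps = []
    for chrom, size in sorted(ann.chrom_sizes.items()):
        merged: list[list[int]] = []
        for a, b in sorted(spans[chrom]):
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        pos = 0
        for a, b in merged + [[size, size]]:
            if a - pos >= min_width:
                gaps.append(GenomicInterval(chrom, pos, a))
            pos = max(pos, b)
    return gaps


def generate_lifted_bed(
    pig_lncs: AnnotationSet,
    frac_conserved: float = 0.1,
    jitter_bp: int = 50,
    seed: int = 42,
    n_foreign: int = 500,
    species: str = "HSA",
) -> tuple[list[tuple[GenomicInterval, str]], set[str]]:
    """Fabricate LiftOver-style lifted intervals for ``n_foreign`` foreign
    lncRNAs: a ``frac_conserved`` subset is guaranteed to overlap a pig
    lncRNA span (start jittered by <= jitter_bp); the rest land in
    lncRNA-free gaps with a >= 1 kb buffer. Returns the (interval, name)
    records and the conserved truth set."""
    if not 0 <= frac_conserved <= 1:
        raise ValueError("frac_conserved must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lncs = sorted(pig_lncs.by_biotype("lncRNA"), key=lambda t: t.transcript_id)
    n_cons = int(round(frac_conserved * n_foreign))
    if n_cons > 0 and not lncs:
        raise ValueError("no pig lncRNAs to overlap")
    buffer = 1000
    gaps = [
        g for g in _lnc_free_gaps(pig_lncs, 2 * buffer + 3000)
    ]
    if n_cons < n_foreign and not gaps:
        raise ValueError("no lncRNA-free gap available for non-conserved intervals")

    records: list[tuple[GenomicInterval, str]] = []
    conserved: set[str] = set()
    for k in range(n_foreign):
        name = f"{species}_LNC{k:05d}"
        if k < n_cons:
            t = lncs[int(rng.integers(0, len(lncs)))]
            span = t.span
            # shift by less than the span length -> overlap >= 1 bp guaranteed
            jitter = int(rng.integers(-jitter_bp, jitter_bp + 1))
            jitter = max(jitter, 1 - len(span))
            start = max(0, span.start + jitter)
            end = span.end + jitter
            records.append((GenomicInterval(span.chrom, start, end, span.strand), name))
            conserved.add(name)
        else:
            g = gaps[int(rng.integers(0, len(gaps)))]
            width = int(rng.integers(500, 3000))
            lo = g.start + buffer
            hi = g.end - buffer - width
            start = int(rng.integers(lo, max(lo + 1, hi)))
            records.append(
                (GenomicInterval(g.chrom, start, start + width,
                                 str(rng.choice(["+", "-"]))), name)
            )
    return records, conserved


def generate_de_tables(
    features: list[str],
    contrasts: tuple[str, ...] = ("AF1_vs_AF2",),
    n_de: int = 50,
    effect_lfc: float = 2.0,
    p_de: float = 1e-6,
    seed: int = 42,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Per-contrast DE tables with ``n_de`` planted effects per contrast.

    Planted rows carry |log2FC| >= effect_lfc and p <= p_de; null rows
    get uniform p and |log2FC| < 1 (truncated normal around 0), so the
    FDR/fold-change thresholds separate the classes by construction.
    """
    if n_de > len(features):
        raise ValueError("n_de exceeds the number of features")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[tuple[str, str], float] = {}
    for contrast in contrasts:
        de_feats = rng.choice(features, size=n_de, replace=False)
        de_set = set(de_feats)
        for f in features:
            if f in de_set:
                lfc = float(
                    (effect_lfc + rng.exponential(0.5)) * rng.choice([-1.0, 1.0])
                )
                p = float(rng.uniform(0, p_de))
                truth[(f, contrast)] = lfc
            else:
                lfc = float(np.clip(rng.normal(0, 0.3), -0.95, 0.95))
                p = float(rng.uniform())
            rows.append((f, contrast, lfc, p))
    return (
        pd.DataFrame(rows, columns=["feature", "contrast", "log2fc", "p"]),
        truth,
    )


def generate_interactions(
    sponges: list[str],
    mirnas: list[str],
    mrnas: list[str],
    edge_prob: float = 0.3,
    pass_prob: float = 0.5,
    seed: int = 42,
) -> tuple[pd.DataFrame, pd.DataFrame, set[tuple[str, str, str]]]:
    """miRanda-style sponge-miRNA and miRNA-mRNA edge tables.

    Each emitted edge passes the retention thresholds (score > 140,
    energy < -20) with probability ``pass_prob``; the truth triples are
    the nested-loop join of the passing edges.
    """
    rng = np.random.default_rng(seed)

    def _edges(sources, targets):
        rows, passing = [], set()
        for s in sources:
            for t in targets:
                if rng.random() >= edge_prob:
                    continue
                if rng.random() < pass_prob:
                    score = float(rng.uniform(141, 200))
                    energy = float(rng.uniform(-40, -20.01))
                    passing.add((s, t))
                else:  # fail score, energy, or both
                    mode = rng.integers(0, 3)
                    score = float(rng.uniform(100, 140)) if mode != 1 else float(rng.uniform(141, 200))
                    energy = float(rng.uniform(-19.99, -5)) if mode != 0 else float(rng.uniform(-40, -20.01))
                rows.append((s, t, score, energy))
        return pd.DataFrame(rows, columns=["source", "target", "score", "energy"]), passing

    sp_df, sp_pass = _edges(sponges, mirnas)
    mm_df, mm_pass = _edges(mirnas, mrnas)
    truth = {
        (s, m, g)
        for (s, m) in sp_pass
        for (m2, g) in mm_pass
        if m2 == m
    }
    return sp_df, mm_df, truth


def stage_templates(stages: tuple[str, ...]) -> pd.DataFrame:
    """Five canonical temporal templates over the given stages:
    rising, falling, mid-peak, mid-dip, late spike."""
    n = len(stages)
    x = np.linspace(0, 1, n)
    shapes = {
        1: x,
        2: 1 - x,
        3: -((x - 0.5) ** 2),
        4: (x - 0.5) ** 2,
        5: np.where(x >= x[-2], 1.0, 0.0) if n >= 2 else x,
    }
    return pd.DataFrame(shapes, index=stages).T.rename_axis("profile_id")


def child_seed(seed: int, offset: int) -> int:
    """Deterministic per-generator child seed, kept below 2**31."""
    return (int(seed) + offset) % (2**31 - 1)


def simulate_truth(config: SimConfig) -> tuple[AnnotationSet, CountMatrix, SyntheticTruth, dict]:
    """Run all generators under one config; returns the annotation, the lnc
    count matrix, the combined truth, and the auxiliary tables."""
    c = config
    ann, ctx_truth = generate_annotation(
        c.n_genes, c.n_lncs, c.n_chroms, child_seed(c.seed, 1000),
        c.context_mix, c.sense_frac, c.length_mode, c.length_sigma,
    )
    lnc_ids = sorted(t.transcript_id for t in ann.by_biotype("lncRNA"))
    cm, hk, ts = generate_counts(
        lnc_ids, c.tissues, c.n_samples_per_tissue, c.n_hk, c.n_ts,
        child_seed(c.seed, 2000), c.dispersion, c.hk_mean, c.ts_home_mean,
        c.ts_fold, c.bg_mean, c.bg_sigma,
    )
    lifted, conserved = generate_lifted_bed(
        ann, c.frac_conserved, c.jitter_bp, child_seed(c.seed, 3000), c.n_foreign
    )
    de_table, de_truth = generate_de_tables(
        lnc_ids, c.contrasts, c.n_de, c.effect_lfc, seed=child_seed(c.seed, 4000)
    )
    mirnas = [f"miR-{k}" for k in range(1, 21)]
    mrnas = [f"G{g:05d}" for g in range(40)]
    sponges = lnc_ids[:30]
    sp_df, mm_df, cerna_truth = generate_interactions(
        sponges, mirnas, mrnas, seed=child_seed(c.seed, 5000)
    )
    truth = SyntheticTruth(
        planted_housekeeping=hk,
        planted_tissue_specific=ts,
        planted_context=ctx_truth,
        planted_conserved=conserved,
        planted_de=de_truth,
        generator_config={**asdict(c)},
    )
    aux = {
        "lifted": lifted,
        "de_table": de_table,
        "sponge_mirna": sp_df,
        "mirna_mrna": mm_df,
        "cerna_truth": cerna_truth,
    }
    return ann, cm, truth, aux


def truth_to_json(truth: SyntheticTruth) -> str:
    """Serialise the planted truth (sets/tuples become sorted lists)."""
    payload = {
        "planted_housekeeping": sorted(truth.planted_housekeeping),
        "planted_tissue_specific": dict(sorted(truth.planted_tissue_specific.items())),
        "planted_context": {
            k: {"category": v.category, "orientation": v.orientation,
                "partner_gene": v.partner_gene}
            for k, v in sorted(truth.planted_context.items())
        },
        "planted_conserved": sorted(truth.planted_conserved),
        "planted_de": [
            {"feature": f, "contrast": c, "log2fc": lfc}
            for (f, c), lfc in sorted(truth.planted_de.items())
        ],
        "generator_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in truth.generator_config.items()
        },
    }
    return json.dumps(payload, indent=2)
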