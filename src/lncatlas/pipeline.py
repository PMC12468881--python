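"""End-to-end atlas run: simulate -> filter -> describe -> classify ->
cis -> conserve -> hubs -> de-filter -> cerna -> stages.

The pipeline writes every intermediate in its public text format
(GTF, TSV, BED, JSON) and reads it back through the package's own
parsers, so a run also exercises the I/O layer. The JSON report records
per-stage input/output counts, the thresholds used, and — because the
inputs are synthetic — planted-truth recovery metrics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as anno
from . import conservation as cons
from . import describe, networks, quantify, simulate, stages as stage_mod
from .classify import Thresholds, classify_all

__all__ = ["RunConfig", "run_pipeline", "precision_recall"]


@dataclass
class RunConfig:
    """Everything a full run needs: generator conditions, thresholds, unit."""

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    unit: str = "CPM"  # CPM or MoR
    min_reads: int = 10
    min_samples: int = 3
    context_window_bp: int = 10_000
    enriched_profiles: tuple[int, ...] = (1, 3)
    stage_labels: tuple[str, ...] = ("AF1", "AF2", "AF3", "AF4", "AF5")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "sim":
                sim_known = {sf.name for sf in dataclasses.fields(simulate.SimConfig)}
                bad = set(v) - sim_known
                if bad:
                    raise ValueError(f"unknown sim keys: {sorted(bad)}")
                v = simulate.SimConfig(**{
                    k: tuple(x) if isinstance(x, list) else x for k, x in v.items()
                })
            elif f.name == "thresholds":
                v = Thresholds(**v)
            elif isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        d["sim"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d["sim"].items()}
        return d


def precision_recall(predicted: set, truth: set) -> tuple[float, float]:
    """(precision, recall); conventions: empty prediction -> precision 1,
    empty truth -> recall 1."""
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def _normalize(cm, unit: str):
    if unit.upper() == "CPM":
        return quantify.cpm_normalize(cm)
    if unit.upper() == "MOR":
        return quantify.median_of_ratios_normalize(cm)
    raise ValueError(f"unknown unit {unit!r}")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages in dependency order; returns the run report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    report: dict = {
        "schema_version": 1,
        "config": config.to_dict(),
        "stages": {},
    }

    # -- simulate ------------------------------------------------------
    ann, cm, truth, aux = simulate.simulate_truth(config.sim)
    (out / "annotation.gtf").write_text(anno.write_gtf(ann))
    cm.counts.to_csv(out / "counts.tsv", sep="\t")
    cm.sample_group.to_csv(out / "groups.tsv", sep="\t", header=False)
    (out / "lifted.bed").write_text(
        anno.write_bed([iv for iv, _ in aux["lifted"]], [n for _, n in aux["lifted"]])
    )
    aux["de_table"].to_csv(out / "de.tsv", sep="\t", index=False)
    aux["sponge_mirna"].to_csv(out / "sponge_mirna.tsv", sep="\t", index=False)
    aux["mirna_mrna"].to_csv(out / "mirna_mrna.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(simulate.truth_to_json(truth))
    report["stages"]["simulate"] = {
        "n_transcripts": len(ann),
        "n_lncRNAs": len(ann.by_biotype("lncRNA")),
        "n_coding": len(ann.by_biotype("protein_coding")),
        "n_samples": len(cm.samples),
        "seed": config.sim.seed,
    }

    # -- read back through the public formats --------------------------
    ann = anno.parse_gtf((out / "annotation.gtf").read_text())
    cm = quantify.CountMatrix.from_tsv(str(out / "counts.tsv"), str(out / "groups.tsv"))
    lifted = anno.parse_bed((out / "lifted.bed").read_text())

    # -- filter + normalize --------------------------------------------
    kept = sorted(quantify.expression_filter(cm, config.min_reads, config.min_samples))
    cm_kept = cm.subset(kept)
    em = _normalize(cm_kept, config.unit)
    report["stages"]["filter"] = {
        "min_reads": config.min_reads,
        "min_samples": config.min_samples,
        "n_in": len(cm.features),
        "n_kept": len(kept),
        "unit": em.unit,
    }

    # -- describe -------------------------------------------------------
    lncs = ann.by_biotype("lncRNA")
    labels = {
        t.transcript_id: describe.classify_context(t, ann, config.context_window_bp)
        for t in lncs
    }
    sense, antisense = describe.strand_split(list(labels.values()))
    hist = describe.length_histogram(lncs)
    modal = describe.modal_length_bin(lncs)
    chrom = describe.chromosome_stats(lncs, ann.chrom_sizes)
    cat_counts = {c: 0 for c in describe.CONTEXT_CATEGORIES}
    for lab in labels.values():
        cat_counts[lab.category] += 1
    ctx_truth = truth.planted_context
    ctx_correct = sum(
        labels[i].category == ctx_truth[i].category for i in labels if i in ctx_truth
    )
    report["stages"]["describe"] = {
        "sense_fraction": sense,
        "antisense_fraction": antisense,
        "modal_length_bin": modal,
        "n_length_bins": len(hist),
        "context_counts": cat_counts,
        "context_truth_agreement": ctx_correct / len(labels) if labels else 1.0,
        "densest_chrom": max(chrom, key=lambda c: chrom[c][1]),
    }

    # -- classify -------------------------------------------------------
    results = classify_all(em, thr)
    hk_pred = {r.feature for r in results if r.label == "housekeeping"}
    ts_pred = {r.feature for r in results if r.label == "tissue_specific"}
    hk_p, hk_r = precision_recall(hk_pred, truth.planted_housekeeping)
    ts_p, ts_r = precision_recall(ts_pred, set(truth.planted_tissue_specific))
    pd.DataFrame(
        [
            {
                "feature": r.feature,
                "label": r.label,
                "tissue": r.specific_tissue or "",
                **r.evidence,
            }
            for r in results
        ]
    ).to_csv(out / "classes.tsv", sep="\t", index=False)
    report["stages"]["classify"] = {
        "n_housekeeping": len(hk_pred),
        "n_tissue_specific": len(ts_pred),
        "housekeeping_precision": hk_p,
        "housekeeping_recall": hk_r,
        "tissue_specific_precision": ts_p,
        "tissue_specific_recall": ts_r,
    }

    # -- cis ------------------------------------------------------------
    gene_ids = sorted({t.gene_id for t in ann.by_biotype("protein_coding")})
    gene_cm, _, _ = simulate.generate_counts(
        gene_ids, config.sim.tissues, config.sim.n_samples_per_tissue,
        n_hk=0, n_ts=0, seed=simulate.child_seed(config.sim.seed, 6000),
    )
    combined = quantify.CountMatrix(
        pd.concat([cm_kept.counts, gene_cm.counts[cm_kept.counts.columns]]),
        cm.sample_group,
    )
    em_all = _normalize(combined, config.unit)
    n_candidates = 0
    cis_targets = []
    kept_lncs = [ann[i] for i in kept if i in ann]
    for lnc in kept_lncs[:200]:  # representative subset keeps the run quick
        cands = networks.find_cis_candidates(lnc, ann, thr.cis_window)
        n_candidates += len(cands)
        pairs = [(lnc.transcript_id, gid, d) for gid, d in cands]
        cis_targets.extend(networks.correlate_and_select(pairs, em_all, thr.cis_r))
    report["stages"]["cis"] = {
        "window_bp": thr.cis_window,
        "r_min": thr.cis_r,
        "n_lncs_scanned": len(kept_lncs[:200]),
        "n_candidates": n_candidates,
        "n_cis_targets": len(cis_targets),
    }

    # -- conserve ---------------------------------------------------------
    records = cons.call_conserved(lifted, ann)
    calls = {r.source_id for r in records if r.conserved}
    c_p, c_r = precision_recall(calls, truth.planted_conserved)
    rep = cons.conservation_report(records, n_source=config.sim.n_foreign)
    report["stages"]["conserve"] = {
        "n_source": rep.n_source,
        "n_conserved": rep.n_conserved,
        "rate_pct": rep.rate_pct,
        "precision": c_p,
        "recall": c_r,
    }

    # -- hubs (per-tissue modules from the classified TS sets) -----------
    hub_sets = {}
    for tissue in config.sim.tissues:
        members = sorted(
            r.feature for r in results
            if r.label == "tissue_specific" and r.specific_tissue == tissue
        )
        if len(members) < 2:
            continue
        sub = em.values.loc[members]
        eig = networks.module_eigengene(sub)
        trait = (em.sample_group == tissue).astype(float).to_numpy()
        stats_list = []
        for f in members:
            mm, gs = networks.module_membership_gs(
                sub.loc[f].to_numpy(), eig.to_numpy(), trait
            )
            stats_list.append(networks.ModuleStats(
                f, tissue, mm, gs,
                mm is not None and gs is not None
                and abs(mm) > thr.mm_min and abs(gs) > thr.gs_min,
            ))
        hub_sets[tissue] = networks.select_hubs(stats_list, thr.mm_min, thr.gs_min)
    report["stages"]["hubs"] = {
        "mm_min": thr.mm_min,
        "gs_min": thr.gs_min,
        "n_hubs_per_module": {t: len(h) for t, h in sorted(hub_sets.items())},
    }

    # -- de-filter --------------------------------------------------------
    de_records = networks.select_de(aux["de_table"], thr.de_fdr, thr.de_lfc)
    de_pred = {(r.feature, r.contrast) for r in de_records if r.is_de}
    de_p, de_r = precision_recall(de_pred, set(truth.planted_de))
    report["stages"]["de_filter"] = {
        "fdr": thr.de_fdr,
        "lfc": thr.de_lfc,
        "n_tests": len(de_records),
        "n_de": len(de_pred),
        "precision": de_p,
        "recall": de_r,
    }

    # -- cerna ------------------------------------------------------------
    sp_edges = networks.filter_interactions(
        aux["sponge_mirna"], thr.mirna_score, thr.mirna_energy
    )
    mm_edges = networks.filter_interactions(
        aux["mirna_mrna"], thr.mirna_score, thr.mirna_energy
    )
    triples = networks.assemble_cerna(sp_edges, mm_edges)
    trip_set = {(t.sponge, t.mirna, t.mrna) for t in triples}
    ce_p, ce_r = precision_recall(trip_set, aux["cerna_truth"])
    pd.DataFrame(
        [(t.sponge, t.mirna, t.mrna) for t in triples],
        columns=["sponge", "mirna", "mrna"],
    ).to_csv(out / "cerna.tsv", sep="\t", index=False)
    report["stages"]["cerna"] = {
        "n_sponge_mirna_edges": len(sp_edges),
        "n_mirna_mrna_edges": len(mm_edges),
        "n_triples": len(triples),
        "precision": ce_p,
        "recall": ce_r,
        "top_sponges": networks.top_sponges(sp_edges),
    }

    # -- stages -----------------------------------------------------------
    stage_feats = sorted(kept)[:300]
    stage_cm, _, _ = simulate.generate_counts(
        stage_feats, config.stage_labels, 3, n_hk=30, n_ts=60,
        seed=simulate.child_seed(config.sim.seed, 7000),
    )
    stage_em = _normalize(stage_cm, config.unit)
    corr = stage_mod.stage_correlation_matrix(stage_em)
    templates = simulate.stage_templates(config.stage_labels)
    assignments = stage_mod.assign_profiles(
        quantify.tissue_means(stage_em), templates
    )
    de_features = {f for (f, _) in de_pred}
    key = stage_mod.select_key_lncs(
        assignments, de_features, set(config.enriched_profiles)
    )
    report["stages"]["stages"] = {
        "n_stages": len(config.stage_labels),
        "min_stage_correlation": float(corr.min().min()),
        "n_assigned": sum(a.profile_id is not None for a in assignments),
        "n_key_lncs": len(key),
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
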