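"""Housekeeping and tissue-specific expression classifiers.

A feature is *housekeeping* when its cross-tissue mean exceeds the
median of all features' means (strict) and its cross-tissue coefficient
of variation is below 1 (strict). It is *tissue-specific* for tissue T
when (i) its mean in T ranks in the top 25% of all features in T,
(ii) T accounts for more than half of its summed means (strict), and
(iii) its mean in T is at least three times the mean in any other
tissue (inclusive). Clause (ii) can hold for at most one tissue, so
the assignment is unique. All criteria are scale-free, so the labels
are invariant under global positive rescaling of the expression matrix.

The same rules apply to lncRNAs and mRNAs; which feature set is passed
in (and hence what "the median of all genes" ranges over) is the
caller's data-selection choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quantify import ExpressionMatrix, TissueSummary, summarize_tissues

__all__ = [
    "Thresholds",
    "ClassificationResult",
    "coefficient_of_variation",
    "classify_housekeeping",
    "classify_tissue_specific",
    "classify_all",
]


@dataclass(frozen=True)
class Thresholds:
    """Literature-default decision thresholds for the whole pipeline."""

    cv_max: float = 1.0  # housekeeping: CV strictly below
    rank_top: float = 0.25  # tissue-specific: top fraction by within-tissue rank
    share_min: float = 0.5  # tissue-specific: strict share of total expression
    ratio_min: float = 3.0  # tissue-specific: inclusive fold over any other tissue
    de_fdr: float = 0.05  # DE: adjusted p strictly below
    de_lfc: float = 1.0  # DE: |log2 fold change| inclusive
    cis_window: int = 100_000  # cis: +/- bp around the lncRNA locus
    cis_r: float = 0.6  # cis: Pearson r strictly above
    mm_min: float = 0.8  # hubs: |module membership| strictly above
    gs_min: float = 0.2  # hubs: |gene significance| strictly above
    mirna_score: float = 140.0  # ceRNA edges: score strictly above
    mirna_energy: float = -20.0  # ceRNA edges: energy strictly below (kcal/mol)


@dataclass(frozen=True)
class ClassificationResult:
    feature: str
    label: str  # housekeeping | tissue_specific | neither
    specific_tissue: str | None
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.specific_tissue is not None) != (self.label == "tissue_specific"):
            raise ValueError("specific_tissue set iff label is tissue_specific")


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) over the mean.

    Defined as +inf when the mean is 0, so such a feature can never be
    called housekeeping.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs >= 2 values")
    m = v.mean()
    if m == 0:
        return float("inf")
    return float(v.std(ddof=1) / m)


def classify_housekeeping(ts: TissueSummary, thr: Thresholds = Thresholds()) -> set[str]:
    """Features with overall mean above the all-feature median and CV < cv_max."""
    if len(ts.groups) < 2:
        raise ValueError("housekeeping classification needs >= 2 tissues")
    med = float(ts.overall_mean.median())
    keep = (ts.overall_mean > med) & (ts.cv < thr.cv_max)
    return set(ts.overall_mean.index[keep])


def classify_tissue_specific(
    ts: TissueSummary, thr: Thresholds = Thresholds()
) -> dict[str, str]:
    """Map feature -> home tissue under the three-clause specificity rule."""
    if len(ts.groups) < 2:
        raise ValueError("tissue-specific classification needs >= 2 tissues")
    out: dict[str, str] = {}
    m = ts.mean_expr
    rank_min = 1.0 - thr.rank_top
    for f in ts.features:
        row = m.loc[f]
        shares = ts.share.loc[f]
        # share > 0.5 holds for at most one tissue
        dominant = shares.index[shares > thr.share_min]
        if len(dominant) != 1:
            continue
        t = dominant[0]
        if ts.rank_q.at[f, t] < rank_min:
            continue
        home = row[t]
        other_max = row.drop(t).max()
        if other_max == 0:
            if home > 0:
                out[f] = t
        elif home >= thr.ratio_min * other_max:
            out[f] = t
    return out


def classify_all(
    em: ExpressionMatrix, thr: Thresholds = Thresholds()
) -> list[ClassificationResult]:
    """Run both classifiers and emit one labelled record per feature.

    A feature meeting both rule sets is labelled tissue_specific: a
    single tissue holding >50% of the expression contradicts the
    housekeeping concept. Features with zero overall mean are "neither"
    without evaluation. Output follows the input feature order.
    """
    if not em.features:
        return []
    ts = summarize_tissues(em)
    hk = classify_housekeeping(ts, thr)
    spec = classify_tissue_specific(ts, thr)
    results = []
    for f in em.features:
        best_t = ts.mean_expr.loc[f].idxmax()
        others = ts.mean_expr.loc[f].drop(best_t)
        other_max = float(others.max())
        best = float(ts.mean_expr.at[f, best_t])
        evidence = {
            "overall_mean": float(ts.overall_mean[f]),
            "cv": float(ts.cv[f]),
            "best_share": float(ts.share.loc[f].max()),
            "best_ratio": best / other_max if other_max > 0 else float("inf"),
            "rank_q": float(ts.rank_q.at[f, best_t]),
        }
        if ts.overall_mean[f] == 0:
            results.append(ClassificationResult(f, "neither", None, evidence))
        elif f in spec:
            results.append(
                ClassificationResult(f, "tissue_specific", spec[f], evidence)
            )
        elif f in hk:
            results.append(ClassificationResult(f, "housekeeping", None, evidence))
        else:
            results.append(ClassificationResult(f, "neither", None, evidence))
    return results
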