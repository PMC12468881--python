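"""Count matrices, the expression filter, and normalisation.

The expression filter keeps a feature when at least one tissue has
strictly more than ``min_reads`` counts in at least ``min_samples`` of
its samples. Two normalisations are provided: counts per million (CPM)
and DESeq-style median-of-ratios size factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "TissueSummary",
    "expression_filter",
    "cpm_normalize",
    "median_of_ratios_factors",
    "median_of_ratios_normalize",
    "tissue_means",
    "summarize_tissues",
]


@dataclass
class CountMatrix:
    """Feature x sample integer counts plus a sample -> group mapping."""

    counts: pd.DataFrame  # features as rows, samples as columns
    sample_group: pd.Series  # index = sample id, value = tissue/stage label

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.sample_group = pd.Series(self.sample_group)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = self.counts.columns.difference(self.sample_group.index)
        if len(missing):
            raise ValueError(f"samples without a group label: {list(missing)}")
        self.sample_group = self.sample_group.loc[self.counts.columns]

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> list[str]:
        return sorted(self.sample_group.unique())

    def subset(self, features) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(features)], self.sample_group)

    @classmethod
    def from_tsv(cls, counts_tsv: str, groups_tsv: str) -> "CountMatrix":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        groups = pd.read_csv(
            groups_tsv, sep="\t", index_col=0, header=None, names=["sample", "group"]
        )["group"]
        return cls(counts, groups)


@dataclass
class ExpressionMatrix:
    """Normalised expression on the same axes as the source CountMatrix."""

    values: pd.DataFrame
    sample_group: pd.Series
    unit: str  # "CPM" or "MoR"

    def __post_init__(self) -> None:
        self.sample_group = pd.Series(self.sample_group).loc[self.values.columns]
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def scaled(self, k: float) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values * k, self.sample_group, self.unit)


def expression_filter(
    cm: CountMatrix, min_reads: int = 10, min_samples: int = 3
) -> set[str]:
    """Features with > ``min_reads`` counts in >= ``min_samples`` samples of one group.

    "More than" is strict: a count of exactly ``min_reads`` does not
    qualify. A group with fewer than ``min_samples`` samples can never
    qualify a feature on its own.
    """
    if min_reads < 1 or min_samples < 1:
        raise ValueError("thresholds must be >= 1")
    kept: set[str] = set()
    for group in cm.groups:
        cols = cm.sample_group.index[cm.sample_group == group]
        n_qual = (cm.counts[cols] > min_reads).sum(axis=1)
        kept.update(cm.counts.index[n_qual >= min_samples])
    return kept


def cpm_normalize(cm: CountMatrix) -> ExpressionMatrix:
    """Counts per million: count / library size x 1e6, per sample."""
    libsize = cm.counts.sum(axis=0)
    zero = libsize.index[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero)}")
    return ExpressionMatrix(cm.counts / libsize * 1e6, cm.sample_group, "CPM")


def median_of_ratios_factors(cm: CountMatrix) -> pd.Series:
    """DESeq median-of-ratios size factors, rescaled to geometric mean 1.

    Only features with strictly positive counts in every sample enter the
    per-feature geometric means; the factor for a sample is the median of
    its count/geomean ratios over those features.
    """
    counts = cm.counts.to_numpy(dtype=float)
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no feature with positive counts in all samples; "
            "add a pseudocount or use CPM normalisation"
        )
    sub = counts[usable]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def median_of_ratios_normalize(cm: CountMatrix) -> ExpressionMatrix:
    factors = median_of_ratios_factors(cm)
    return ExpressionMatrix(cm.counts / factors, cm.sample_group, "MoR")


@dataclass
class TissueSummary:
    """Per-feature per-tissue means and the derived classification statistics.

    ``mean_expr``: feature x tissue means of normalised expression.
    ``overall_mean``: row means of ``mean_expr``.
    ``cv``: cross-tissue coefficient of variation, sample sd (n-1) / mean;
    +inf where the mean is 0 (such a feature can never be housekeeping).
    ``share``: each tissue's fraction of the feature's summed means.
    ``rank_q``: within-tissue quantile rank of the mean,
    (# features with strictly smaller mean) / (n - 1); ties share the
    lower rank.
    """

    mean_expr: pd.DataFrame
    overall_mean: pd.Series = field(init=False)
    cv: pd.Series = field(init=False)
    share: pd.DataFrame = field(init=False)
    rank_q: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        m = self.mean_expr
        self.overall_mean = m.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sd = m.std(axis=1, ddof=1)
            cv = sd / self.overall_mean
        cv[self.overall_mean == 0] = np.inf
        self.cv = cv
        totals = m.sum(axis=1)
        share = m.div(totals.where(totals > 0), axis=0).fillna(0.0)
        self.share = share
        n = len(m)
        if n > 1:
            rq = pd.DataFrame(
                {
                    t: (rankdata(m[t], method="min") - 1) / (n - 1)
                    for t in m.columns
                },
                index=m.index,
            )
        else:
            rq = pd.DataFrame(1.0, index=m.index, columns=m.columns)
        self.rank_q = rq

    @property
    def features(self) -> list[str]:
        return list(self.mean_expr.index)

    @property
    def groups(self) -> list[str]:
        return list(self.mean_expr.columns)


def tissue_means(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature arithmetic mean of normalised values within each group.

    Columns are ordered lexicographically for determinism.
    """
    groups = sorted(em.sample_group.unique())
    out = {}
    for g in groups:
        cols = em.sample_group.index[em.sample_group == g]
        out[g] = em.values[cols].mean(axis=1)
    return pd.DataFrame(out, index=em.values.index)


def summarize_tissues(em: ExpressionMatrix) -> TissueSummary:
    """Compose :func:`tissue_means` with the derived per-feature statistics."""
    return TissueSummary(tissue_means(em))
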