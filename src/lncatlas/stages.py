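"""Stage-wise expression dynamics across antral follicle stages (AF1-AF5).

Provides pairwise Spearman correlation between stage mean profiles,
assignment of features to caller-supplied temporal template profiles
(best Pearson match of standardised stage means, minimum r = 0.7), and
the key-lncRNA selection that intersects profile membership with
differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix, tissue_means

__all__ = [
    "StageProfile",
    "stage_correlation_matrix",
    "assign_profiles",
    "select_key_lncs",
]


@dataclass(frozen=True)
class StageProfile:
    feature: str
    stage_means: tuple[float, ...]
    profile_id: int | None  # best-matching template, None if below r_min
    match_r: float | None


def stage_correlation_matrix(
    em: ExpressionMatrix, method: str = "spearman"
) -> pd.DataFrame:
    """Stage x stage correlation of per-stage mean profiles.

    Symmetric with unit diagonal; a pair involving a constant profile is
    reported as NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    means = tissue_means(em)
    if means.shape[1] < 2 or means.shape[0] < 3:
        raise ValueError("need >= 2 stages and >= 3 features")
    stages = list(means.columns)
    out = pd.DataFrame(np.eye(len(stages)), index=stages, columns=stages)
    for i, a in enumerate(stages):
        for b in stages[i + 1:]:
            x, y = means[a].to_numpy(), means[b].to_numpy()
            if x.std() == 0 or y.std() == 0:
                r = np.nan
            elif method == "spearman":
                r = stats.spearmanr(x, y).statistic
            else:
                r = stats.pearsonr(x, y).statistic
            out.at[a, b] = out.at[b, a] = r
    return out


def _standardize(v: np.ndarray) -> np.ndarray | None:
    sd = v.std(ddof=1)
    if sd == 0:
        return None
    return (v - v.mean()) / sd


def assign_profiles(
    stage_means: pd.DataFrame,
    templates: pd.DataFrame,
    r_min: float = 0.7,
) -> list[StageProfile]:
    """Assign each feature to the best-correlated template profile.

    ``stage_means``: feature x stage matrix; ``templates``: profile_id x
    stage matrix (at most 50 rows). Stage means are standardised before
    Pearson matching, so the assignment is invariant to affine
    transformations of a feature's profile. Assignment requires the best
    r >= r_min; ties go to the lowest template index; zero-variance
    features stay unassigned.
    """
    if len(templates) > 50:
        raise ValueError("at most 50 template profiles")
    if list(templates.columns) != list(stage_means.columns):
        raise ValueError("templates and stage means must share stage columns")
    t_std = {}
    for pid in templates.index:
        z = _standardize(templates.loc[pid].to_numpy(dtype=float))
        if z is None:
            raise ValueError(f"template {pid} is constant")
        t_std[pid] = z
    out = []
    for f in stage_means.index:
        v = stage_means.loc[f].to_numpy(dtype=float)
        z = _standardize(v)
        if z is None:
            out.append(StageProfile(f, tuple(v), None, None))
            continue
        best_pid, best_r = None, -np.inf
        for pid in templates.index:  # index order; lowest wins ties
            r = float(np.corrcoef(z, t_std[pid])[0, 1])
            if r > best_r:
                best_pid, best_r = pid, r
        if best_r >= r_min:
            out.append(StageProfile(f, tuple(v), int(best_pid), best_r))
        else:
            out.append(StageProfile(f, tuple(v), None, float(best_r)))
    return out


def select_key_lncs(
    assignments: list[StageProfile],
    de_features: set[str],
    enriched_profiles: set[int],
) -> list[str]:
    """Key lncRNAs: differentially expressed in >= 1 stage contrast AND
    assigned to an enriched temporal profile. Sorted for determinism."""
    return sorted(
        p.feature
        for p in assignments
        if p.profile_id is not None
        and p.profile_id in enriched_profiles
        and p.feature in de_features
    )
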