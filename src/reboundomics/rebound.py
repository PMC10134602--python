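"""Calling differential features and classifying post-partum rebound.

A feature "rebounds" when it is significant in both the 3rd-vs-1st
trimester window and the post-partum-vs-3rd window with opposite
directions (e.g. hypomethylated during pregnancy, hypermethylated after).
Features rebounding with the identical direction pattern in both the
disease and control groups form the *shared rebound* set that seeds the
network-module stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CpGAnnotation, ValidationError
from .differential import DifferentialResult


def call_dmps(
    result: DifferentialResult, p_max: float = 0.05, db_min: float = 0.05
) -> pd.DataFrame:
    """Differentially methylated probes: p <= p_max and |delta beta| > db_min.

    Direction is taken from the sign of the mean beta difference
    (hyper if positive); probes whose delta-beta and M-scale coefficient
    disagree in sign are excluded from the significant set and counted in
    ``df.attrs['n_sign_conflict']``.
    """
    if "delta_beta" not in result.table.columns:
        raise ValidationError("result carries no delta_beta; not a methylation contrast")
    t = result.table
    direction = np.where(t["delta_beta"] > 0, "hyper", "hypo")
    significant = (t["p"] <= p_max) & (t["delta_beta"].abs() > db_min)
    conflict = significant & (np.sign(t["delta_beta"]) * np.sign(t["estimate"]) < 0)
    calls = pd.DataFrame(
        {
            "direction": direction,
            "p": t["p"],
            "delta_beta": t["delta_beta"],
            "significant": significant & ~conflict,
        },
        index=t.index,
    )
    calls.attrs["n_sign_conflict"] = int(conflict.sum())
    calls.attrs["contrast"] = result.contrast_name
    return calls


def call_degs(result: DifferentialResult, p_max: float = 0.05) -> pd.DataFrame:
    """Differentially expressed genes: nominal p <= p_max; direction by sign."""
    t = result.table
    calls = pd.DataFrame(
        {
            "direction": np.where(t["estimate"] > 0, "up", "down"),
            "p": t["p"],
            "estimate": t["estimate"],
            "significant": (t["p"] <= p_max) & (t["estimate"] != 0),
        },
        index=t.index,
    )
    calls.attrs["contrast"] = result.contrast_name
    return calls


@dataclass
class ReboundResult:
    """Rebound classification for one group and omic.

    ``rebound`` lists features significant in both windows with opposite
    directions, with their pattern (e.g. "up-down"); ``same_direction``
    lists features significant in both windows with the same direction.
    """

    rebound: pd.DataFrame
    same_direction: pd.DataFrame

    @property
    def rebound_ids(self) -> set[str]:
        return set(self.rebound.index)


def find_rebound(calls_w1: pd.DataFrame, calls_w2: pd.DataFrame) -> ReboundResult:
    """Split features significant in both windows by direction reversal.

    ``calls_w1`` are the 3rd-vs-1st calls and ``calls_w2`` the
    post-partum-vs-3rd calls for the same group and omic.
    """
    if not calls_w1.index.equals(calls_w2.index):
        raise ValidationError("the two windows cover different feature universes")
    both = calls_w1["significant"] & calls_w2["significant"]
    d1 = calls_w1.loc[both, "direction"]
    d2 = calls_w2.loc[both, "direction"]
    pattern = d1.str.cat(d2, sep="-")
    detail = pd.DataFrame(
        {
            "pattern": pattern,
            "direction_w1": d1,
            "direction_w2": d2,
            "p_w1": calls_w1.loc[both, "p"],
            "p_w2": calls_w2.loc[both, "p"],
        }
    )
    for col in ("delta_beta", "estimate"):
        if col in calls_w1.columns:
            detail[f"{col}_w1"] = calls_w1.loc[both, col]
            detail[f"{col}_w2"] = calls_w2.loc[both, col]
    reversed_dir = d1 != d2
    return ReboundResult(
        rebound=detail.loc[reversed_dir],
        same_direction=detail.loc[~reversed_dir],
    )


@dataclass
class SharedRebound:
    """Rebound features with the same direction pattern in both groups."""

    shared: pd.DataFrame
    quadrant_table: pd.DataFrame

    @property
    def shared_ids(self) -> set[str]:
        return set(self.shared.index)


def shared_rebound(rebound_a: ReboundResult, rebound_b: ReboundResult) -> SharedRebound:
    """Intersect two groups' rebound sets requiring identical patterns.

    Also reports, per window, the percentage of features (rebounding in
    both groups) whose direction agrees between the groups -- the
    quadrant percentages of the direction-agreement scatter.
    """
    common = rebound_a.rebound.index.intersection(rebound_b.rebound.index)
    a = rebound_a.rebound.loc[common]
    b = rebound_b.rebound.loc[common]
    same_pattern = a["pattern"] == b["pattern"]
    shared = a.loc[same_pattern].copy()
    shared["pattern_other_group"] = b.loc[same_pattern, "pattern"]

    rows = []
    for window in ("direction_w1", "direction_w2"):
        if len(common):
            agree = float((a[window] == b[window]).mean() * 100.0)
        else:
            agree = np.nan
        rows.append({"window": window, "pct_same_direction": agree, "n": len(common)})
    return SharedRebound(shared=shared, quadrant_table=pd.DataFrame(rows))


def map_cpgs_to_genes(
    cpgs, annotation: CpGAnnotation
) -> tuple[set[str], int]:
    """Union of annotated genes over the probes (the DMG set).

    Returns the gene set and the number of probes that carried no
    annotation and therefore contributed nothing.
    """
    cpgs = set(cpgs)
    annotated = annotation.annotated_cpgs()
    n_unannotated = len(cpgs - annotated)
    return annotation.genes_for(cpgs), n_unannotated


def contrast_correlation(
    result_a: DifferentialResult, result_b: DifferentialResult
) -> tuple[float, float]:
    """Pearson correlation of two contrasts' effect estimates.

    Computed over the features common to both results; a planted
    reversal (rebound) makes the during- vs after-pregnancy contrast
    correlation negative.
    """
    common = result_a.table.index.intersection(result_b.table.index)
    if len(common) < 3:
        raise ValidationError("need at least 3 shared features for a correlation")
    r, p = stats.pearsonr(
        result_a.table.loc[common, "estimate"], result_b.table.loc[common, "estimate"]
    )
    return float(r), float(p)


def category_counts(rebound: ReboundResult) -> pd.DataFrame:
    """Counts per direction-pattern category (input for alluvial plots)."""
    pooled = pd.concat([rebound.rebound, rebound.same_direction])
    out = pooled["pattern"].value_counts().rename_axis("pattern").reset_index(name="n")
    return out
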