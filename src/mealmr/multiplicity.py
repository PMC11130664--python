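"""Effective number of independent tests via principal-variable clustering.

Traits are clustered on the distance 1 - |correlation| with hierarchical
agglomeration; the tree is cut at a fixed height, each cluster is
summarized by its most central member (the medoid), and the number of
clusters is the effective number of tests used for Bonferroni
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = ["PVClusterResult", "pv_cluster", "bonferroni_threshold"]

log = logging.getLogger(__name__)

_MIN_PAIRWISE = 10


@dataclass
class PVClusterResult:
    assignments: pd.Series  # trait -> cluster id
    representatives: pd.Series  # cluster id -> trait
    n_effective: int
    cut_height: float
    linkage: str
    excluded: list

    def __post_init__(self):
        if not (1 <= self.n_effective <= len(self.assignments)):
            raise ValueError("n_effective outside [1, n_traits]")


def pv_cluster(
    matrix: pd.DataFrame,
    cut_height: float = 0.5,
    linkage: str = "average",
    corr: str = "spearman",
) -> PVClusterResult:
    """Cluster traits and pick a representative per cluster.

    Distances are 1 - |pairwise-complete correlation|; the tree is cut at
    ``cut_height``; within each cluster the representative is the trait
    with minimal summed distance to its co-members (ties broken by trait
    id; singletons represent themselves). Traits with fewer than 10
    pairwise-complete observations against some other trait are excluded
    and logged.
    """
    if not (0.0 < cut_height < 1.0):
        raise ValueError("cut_height must lie in (0, 1)")
    counts = matrix.notna().astype(float)
    pair_n = counts.T @ counts
    np.fill_diagonal(pair_n.values, np.inf)
    excluded = []
    keep = matrix.columns.tolist()
    while True:
        sub = pair_n.loc[keep, keep]
        violations = (sub < _MIN_PAIRWISE).sum(axis=1)
        if (violations == 0).all():
            break
        drop = violations.idxmax()  # the trait causing the most bad pairs
        excluded.append(drop)
        keep.remove(drop)
        if len(keep) < 2:
            raise ValueError("fewer than 2 traits with sufficient pairwise overlap")
    if excluded:
        log.warning("excluded %d trait(s) with <%d pairwise-complete observations", len(excluded), _MIN_PAIRWISE)
    data = matrix[keep]
    # deterministic trait order so results are permutation-invariant
    order = sorted(keep)
    data = data[order]
    cmat = data.corr(method=corr, min_periods=_MIN_PAIRWISE).to_numpy()
    dist = 1.0 - np.abs(cmat)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    assignments = pd.Series(labels, index=order, name="cluster")
    reps = {}
    for cid in np.unique(labels):
        members = [t for t, lab in zip(order, labels) if lab == cid]
        if len(members) == 1:
            reps[cid] = members[0]
            continue
        midx = [order.index(t) for t in members]
        sums = dist[np.ix_(midx, midx)].sum(axis=1)
        best = min(zip(sums, members))  # ties resolved lexicographically
        reps[cid] = best[1]
    representatives = pd.Series(reps, name="representative")
    return PVClusterResult(
        assignments=assignments,
        representatives=representatives,
        n_effective=int(len(representatives)),
        cut_height=float(cut_height),
        linkage=linkage,
        excluded=excluded,
    )


def bonferroni_threshold(alpha: float, n_effective: int) -> float:
    """Multiple-testing threshold alpha / n_effective."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_effective < 1:
        raise ValueError("n_effective must be >= 1")
    return alpha / n_effective
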