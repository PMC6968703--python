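"""Single-linkage clustering of ligands on a Tanimoto-distance matrix.

Ligands are merged agglomeratively with the single-linkage rule (the
distance between clusters is the smallest member-pair Td). Clusters are
then read off the dendrogram with a balanced cut: the threshold is a
fraction of the root merge height (default 30%), and two ligands share
a cluster when they are connected by merges strictly below it. An
absolute-Td threshold mode is also available. Clusters smaller than a
minimum size (default 5) are discarded before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .datamodel import PairwiseMatrix

__all__ = ["Dendrogram", "CutConfig", "single_linkage",
           "cut_at_height_ratio", "filter_clusters"]

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form.

    ``merges`` has one row per merge: (left node, right node, height,
    size); leaves are nodes 0..n-1 and merge i creates node n+i.
    """

    merges: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float).reshape(-1, 4)
        if self.n_leaves >= 2 and len(self.merges) != self.n_leaves - 1:
            raise ValueError("a full tree needs n_leaves - 1 merges")
        heights = self.merges[:, 2]
        if len(heights) and np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def root_height(self) -> float:
        return float(self.heights[-1]) if len(self.merges) else 0.0

    def to_newick(self) -> str:
        """Nested-parenthesis export with branch heights as comments."""
        if self.n_leaves == 1:
            return f"{self.labels[0]};"
        n = self.n_leaves
        reps = {i: self.labels[i] for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.merges):
            reps[n + i] = f"({reps[int(a)]},{reps[int(b)]})[{h:.6g}]"
        return reps[n + len(self.merges) - 1] + ";"


@dataclass(frozen=True)
class CutConfig:
    """Dendrogram cut: relative (default) or absolute threshold, min size."""

    height_ratio: float = 0.30
    min_cluster_size: int = 5
    mode: str = "ratio"  # ratio | absolute
    absolute_td: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.height_ratio <= 1:
            raise ValueError("height_ratio must be in (0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.mode not in ("ratio", "absolute"):
            raise ValueError(f"unknown cut mode {self.mode!r}")
        if self.mode == "absolute" and self.absolute_td is None:
            raise ValueError("absolute mode needs absolute_td")

    def threshold(self, root_height: float) -> float:
        if self.mode == "absolute":
            return float(self.absolute_td)
        return self.height_ratio * root_height


def single_linkage(distance: PairwiseMatrix) -> Dendrogram:
    """Single-linkage merge tree of a Td matrix.

    A single ligand yields a degenerate dendrogram with no merges.
    """
    if distance.kind != "distance":
        raise ValueError("single_linkage expects a distance matrix")
    if distance.n < 2:
        return Dendrogram(merges=np.empty((0, 4)), labels=list(distance.ligand_order))
    merges = linkage(distance.condensed(), method="single")
    return Dendrogram(merges=merges, labels=list(distance.ligand_order))


def cut_at_height_ratio(
    dendrogram: Dendrogram, cut_config: Optional[CutConfig] = None
) -> list[list[str]]:
    """Clusters from a balanced dendrogram cut.

    The threshold is ``height_ratio x root height`` (or the absolute Td
    in absolute mode) and members are joined by merges strictly below
    it, i.e. the clusters are the connected components of the
    merged-below-threshold graph. Returned clusters are ordered by
    descending size, then by lowest member index, and each cluster's
    members keep the original ligand order.
    """
    if cut_config is None:
        cut_config = CutConfig()
    n = dendrogram.n_leaves
    if n == 0:
        return []
    t = cut_config.threshold(dendrogram.root_height)

    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, h, _) in enumerate(dendrogram.merges):
        if h < t:  # strict comparison: equal-height merges stay split
            ra, rb = find(int(a)), find(int(b))
            parent[ra] = parent[rb] = parent[n + i] = min(ra, rb)

    groups: dict[int, list[int]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), g[0]))
    return [[dendrogram.labels[i] for i in g] for g in ordered]


def filter_clusters(
    clusters: Sequence[list[str]], cut_config: Optional[CutConfig] = None
) -> list[list[str]]:
    """Drop clusters below ``min_cluster_size``, preserving order."""
    if cut_config is None:
        cut_config = CutConfig()
    kept = [list(c) for c in clusters if len(c) >= cut_config.min_cluster_size]
    if not kept:
        logger.warning("no cluster reaches the minimum size of %d",
                       cut_config.min_cluster_size)
    return kept


def write_membership(clusters: Sequence[list[str]], path: str | Path) -> None:
    """Cluster membership CSV (cluster_id, cid); ids start at 1."""
    rows = [(i + 1, cid) for i, c in enumerate(clusters) for cid in c]
    pd.DataFrame(rows, columns=["cluster_id", "cid"]).to_csv(path, index=False)
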