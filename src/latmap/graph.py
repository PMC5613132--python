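"""Threshold-free classification of subjects by pattern similarity.

Each subject's unthresholded Z-map, restricted to an ROI mask, is treated as
a vector; pairwise Pearson correlations between subjects form a similarity
matrix, which becomes a weighted undirected graph.  Two-phase greedy
modularity maximization (the Blondel "Louvain" method) then partitions the
subjects into communities of similar activation patterns — no threshold is
ever applied to the maps themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .volumes import GridMismatchError, RoiMask, StatMap

NEGATIVE_EDGE_RULES = ("truncate", "shift")


class SimilarityError(ValueError):
    """Raised when a pattern correlation is undefined."""


@dataclass(frozen=True)
class SimilarityMatrix:
    values: np.ndarray
    subject_ids: list[str]
    mask_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.subject_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} subjects")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")
        if v.min() < -1.0 - 1e-9 or v.max() > 1.0 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.subject_ids,
                     columns=self.subject_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float),
                   subject_ids=[str(c) for c in df.columns])


@dataclass(frozen=True)
class CommunityPartition:
    labels: dict[str, int]
    q: float
    resolution: float
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values())) if self.labels else 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.labels, fh, indent=1, sort_keys=True)


def spatial_correlation(map_a: StatMap, map_b: StatMap, mask: RoiMask) -> float:
    """Pearson correlation of two maps over the masked voxels."""
    if not map_a.same_grid(map_b):
        raise GridMismatchError("maps are on different grids")
    if map_a.shape != mask.data.shape:
        raise GridMismatchError("mask is not on the map grid")
    if mask.n_voxels < 3:
        raise SimilarityError("mask must contain at least 3 voxels")
    va = map_a.data[mask.data]
    vb = map_b.data[mask.data]
    for v, m in ((va, map_a), (vb, map_b)):
        if np.ptp(v) == 0:
            raise SimilarityError(
                f"zero variance in masked map {m.subject_id!r}: correlation undefined"
            )
    r = float(np.corrcoef(va, vb)[0, 1])
    return max(-1.0, min(1.0, r))


def similarity_matrix(maps: list[StatMap], mask: RoiMask) -> SimilarityMatrix:
    """All pairwise masked Pearson correlations between subject maps."""
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    ref = maps[0]
    vectors = []
    for m in maps:
        if not ref.same_grid(m):
            raise GridMismatchError(f"map {m.subject_id!r} is on a different grid")
        v = m.data[mask.data]
        if np.ptp(v) == 0:
            raise SimilarityError(f"zero variance in masked map {m.subject_id!r}")
        vectors.append(v)
    values = np.corrcoef(np.stack(vectors))
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    ids = [m.subject_id or f"sub-{i:03d}" for i, m in enumerate(maps)]
    return SimilarityMatrix(values=values, subject_ids=ids, mask_label=mask.label)


def build_graph(matrix: SimilarityMatrix, negative: str = "truncate") -> nx.Graph:
    """Similarity matrix to weighted undirected graph (no self-loops).

    ``negative="truncate"`` (default) drops edges with r <= 0, since the
    modularity objective is defined for non-negative weights; ``"shift"``
    instead maps every correlation to weight r + 1.
    """
    if negative not in NEGATIVE_EDGE_RULES:
        raise ValueError(f"negative must be one of {NEGATIVE_EDGE_RULES}")
    g = nx.Graph()
    g.add_nodes_from(matrix.subject_ids)
    n = len(matrix.subject_ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = matrix.values[i, j]
            w = r + 1.0 if negative == "shift" else r
            if w > 0:
                g.add_edge(matrix.subject_ids[i], matrix.subject_ids[j], weight=float(w))
    return g


def detect_communities(graph: nx.Graph, resolution: float = 1.0,
                       seed: int = 0) -> CommunityPartition:
    """Two-phase greedy (Louvain) modularity maximization on edge weights.

    Deterministic given ``seed``.  Communities are renumbered 0..K-1 in order
    of their smallest member under sorted node ids, so the labelling itself
    is reproducible.  A graph with no edges puts every node in its own
    community with Q = 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    if graph.number_of_edges() == 0:
        communities = [{n} for n in graph.nodes]
        q = 0.0
    else:
        communities = nx.community.louvain_communities(
            graph, weight="weight", resolution=resolution, seed=seed
        )
        q = float(nx.community.modularity(graph, communities, weight="weight",
                                          resolution=resolution))
    order = sorted(range(len(communities)),
                   key=lambda c: min(str(n) for n in communities[c]))
    labels: dict[str, int] = {}
    for new, c in enumerate(order):
        for node in communities[c]:
            labels[node] = new
    return CommunityPartition(labels=labels, q=q, resolution=float(resolution),
                              seed=int(seed))


def partition_agreement(partition: CommunityPartition,
                        reference: dict[str, int]) -> float:
    """Best-matching accuracy between a partition and reference labels.

    Labels are permuted by Hungarian assignment on the confusion matrix, so
    the score is invariant to label renaming; 1.0 means the groupings agree
    exactly on every subject.
    """
    if set(partition.labels) != set(reference):
        raise ValueError("partition and reference cover different subject sets")
    subjects = sorted(partition.labels)
    a = np.array([partition.labels[s] for s in subjects])
    b = np.array([reference[s] for s in subjects])
    ua, ub = np.unique(a), np.unique(b)
    confusion = np.zeros((len(ua), len(ub)), dtype=int)
    for i, la in enumerate(ua):
        for j, lb in enumerate(ub):
            confusion[i, j] = int(np.sum((a == la) & (b == lb)))
    rows, cols = linear_sum_assignment(-confusion)
    return float(confusion[rows, cols].sum()) / len(subjects)
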