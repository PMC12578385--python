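"""Transcriptional distance among (cell type, group) populations.

Populations are summarized by their centroids in PC space; pairwise Euclidean
distances between centroids are clustered agglomeratively. The merge tree
answers questions of the form "which condition does this population resemble
most" — e.g. whether a treated late-stage population sits nearer the early
disease stage than the untreated late stage.

The agglomeration is implemented directly (Lance-Williams updates) so that the
tie rule — merge the smallest (node_a, node_b) pair among equal-height
candidates — is explicit and deterministic; the handful of populations involved
makes the naive O(n^3) loop irrelevant to performance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import Embedding

LINKAGES = ("single", "complete", "average", "ward")


def population_centroids(emb, metadata: pd.DataFrame,
                         by=("cell_type", "group")):
    """Coordinate-wise mean per population; returns (labels, centroid matrix).

    ``by`` names the metadata columns whose combination defines a population;
    labels are "val1|val2" strings in sorted order.
    """
    coords = np.asarray(getattr(emb, "coords", emb), dtype=float)
    if len(metadata) != coords.shape[0]:
        raise ValueError("metadata does not cover all embedded cells")
    keys = metadata[list(by)].astype(str).agg("|".join, axis=1).to_numpy()
    labels = sorted(set(keys))
    cents = np.empty((len(labels), coords.shape[1]))
    for i, lab in enumerate(labels):
        mask = keys == lab
        if not mask.any():
            raise ValueError(f"empty population {lab!r}")
        cents[i] = coords[mask].mean(axis=0)
    return labels, cents


def pairwise_euclidean(centroids) -> np.ndarray:
    """Symmetric zero-diagonal Euclidean distance matrix between centroids."""
    c = np.asarray(centroids, dtype=float)
    if c.shape[0] < 2:
        raise ValueError("need at least 2 populations")
    d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
    d = np.sqrt(np.maximum(d2, 0.0))
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_cluster(distance, linkage: str = "average"):
    """Agglomerative clustering of a distance matrix.

    Returns a merge list of (node_a, node_b, height, size) rows in scipy
    numbering: leaves are 0..n-1, the i-th merge creates node n+i. Among pairs
    of minimal distance, the smallest (node_a, node_b) pair merges first.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance must be a symmetric square matrix")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    n = d.shape[0]
    # active clusters: node id -> (row index in working matrix, size)
    work = d.copy().astype(float)
    np.fill_diagonal(work, np.inf)
    node_of = list(range(n))  # working-row index -> node id
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))  # working-row indices still live
    merges = []
    next_node = n
    for step in range(n - 1):
        # find minimal pair; break ties by smallest (node_a, node_b)
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                h = work[i, j]
                na, nb = sorted((node_of[i], node_of[j]))
                key = (h, na, nb)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (h, na, nb), i, j = best
        si, sj = sizes[node_of[i]], sizes[node_of[j]]
        new_size = si + sj
        merges.append((na, nb, float(h), new_size))
        # Lance-Williams update into row i
        for k in active:
            if k in (i, j):
                continue
            dik, djk = work[i, k], work[j, k]
            if linkage == "single":
                new = min(dik, djk)
            elif linkage == "complete":
                new = max(dik, djk)
            elif linkage == "average":
                new = (si * dik + sj * djk) / new_size
            else:  # ward (Lance-Williams on Euclidean distances)
                sk = sizes[node_of[k]]
                t = new_size + sk
                new = np.sqrt(
                    max(
                        ((si + sk) * dik**2 + (sj + sk) * djk**2
                         - sk * h**2) / t,
                        0.0,
                    )
                )
            work[i, k] = work[k, i] = new
        sizes[next_node] = new_size
        node_of[i] = next_node
        next_node += 1
        active.remove(j)
    return merges


def similarity_rank(distance, labels, query):
    """Populations ordered by ascending distance from ``query`` (query excluded).

    Exact distance ties break by ascending label order (stable sort on a
    label-sorted candidate list).
    """
    labels = list(labels)
    if query not in labels:
        raise ValueError(f"unknown population {query!r}")
    d = np.asarray(distance, dtype=float)
    qi = labels.index(query)
    others = sorted(lab for lab in labels if lab != query)
    dq = np.array([d[qi, labels.index(lab)] for lab in others])
    order = np.argsort(dq, kind="stable")
    return [others[i] for i in order]


def merges_to_newick(merges, labels) -> str:
    """Newick string (branch lengths from merge heights) for a merge list."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    text = {i: str(labels[i]) for i in range(n)}
    node = n
    for a, b, h, _size in merges:
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        text[node] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
        height[node] = h
        node += 1
    return text[node - 1] + ";"


class PopulationDistance:
    """Fitted population-distance analysis.

    Built by :meth:`from_embedding`; carries the population labels, centroid
    matrix, pairwise distance matrix and the agglomerative merge tree, and
    exposes ranking, Newick export and a text summary.
    """

    def __init__(self, labels, centroids, distance, merges, linkage):
        self.labels = list(labels)
        self.centroids = np.asarray(centroids, float)
        self.distance = np.asarray(distance, float)
        self.merges = merges
        self.linkage = linkage

    @classmethod
    def from_embedding(cls, emb, metadata, by=("cell_type", "group"),
                       linkage: str = "average"):
        labels, cents = population_centroids(emb, metadata, by=by)
        dist = pairwise_euclidean(cents)
        merges = hierarchical_cluster(dist, linkage=linkage)
        return cls(labels, cents, dist, merges, linkage)

    def rank(self, query):
        return similarity_rank(self.distance, self.labels, query)

    def to_newick(self) -> str:
        return merges_to_newick(self.merges, self.labels)

    def distance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distance, index=self.labels,
                            columns=self.labels)

    def merge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges,
                            columns=["node_a", "node_b", "height", "size"])

    def summary(self) -> str:
        lines = [
            "Population distance (PC-space centroids)",
            "=" * 60,
            f"populations: {len(self.labels)}   linkage: {self.linkage}",
            "merge tree (node_a, node_b, height, size):",
        ]
        for a, b, h, s in self.merges:
            lines.append(f"  {a:>3} + {b:>3}  @ {h:10.4f}  (size {s})")
        lines.append("newick: " + self.to_newick())
        return "\n".join(lines)
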