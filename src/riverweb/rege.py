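"""Regular-equivalence (REGE) similarity and trophic-guild clustering.

Two nodes are *regularly equivalent* when they are connected to
equivalent — not necessarily identical — partners: a perch and a pike
can be equivalent because both eat some (possibly different) forage
fish and are eaten by some (possibly different) top predator.  REGE
approximates the maximal regular equivalence by iterating a similarity
matrix: starting from all-alike, each pass rescores a pair (i, j) by
how well every trophic partner of i can be matched with a partner of j
that plays the same role (prey matched with prey, consumer with
consumer), weighted by the current similarity of the matched partners.

The recurrence on a binary adjacency matrix x (x_ij = 1 when i eats j)
is, with k running over i's in/out neighbors and m over j's:

    num_ij = sum_k max_m  R_km * (min(x_ik, x_jm) + min(x_ki, x_mj))
    den_ij = sum_k max_m  (max(x_ik, x_jm) + max(x_ki, x_mj))

and the updated similarity is the two-sided ratio
(num_ij + num_ji) / (den_ij + den_ji), which keeps the matrix exactly
symmetric.  A pair whose denominator is zero (two fully isolated
nodes) is given similarity 100 by convention.  Similarities live on a
0-100 scale; 100 means strict regular equivalence.

Clustering by regular equivalence runs on the *directed* web: the
grouping of basal resources (detritus, producers, water mites) rests
on all three having only consumers eating them, which direction alone
encodes.  A symmetrized mode is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .core import FoodWeb, ValidationError

__all__ = [
    "SimilarityMatrix",
    "Dendrogram",
    "rege_similarity",
    "cluster_similarity",
    "cut_dendrogram",
]

DEFAULT_ITERATIONS = 3


@dataclass
class SimilarityMatrix:
    labels: list[str]
    S: np.ndarray  # square, symmetric, values in [0, 100], diagonal 100
    iterations: int

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.labels)
        if self.S.shape != (n, n):
            raise ValidationError("similarity matrix shape does not match labels")
        if not np.allclose(self.S, self.S.T, atol=1e-9):
            raise ValidationError("similarity matrix must be symmetric")
        if self.S.min() < -1e-9 or self.S.max() > 100 + 1e-9:
            raise ValidationError("similarities must lie in [0, 100]")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.S[i, j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.S, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """Agglomerative merge tree with heights on the similarity scale.

    ``linkage_matrix`` is a scipy linkage array over dissimilarities
    100 - S; ``merge_similarities`` are the corresponding heights
    mapped back to similarity (monotone non-increasing).
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    method: str

    @property
    def merge_similarities(self) -> np.ndarray:
        return 100.0 - self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_dist: float) -> str:
            length = parent_dist - node.dist
            if node.is_leaf():
                name = self.labels[node.id].replace(" ", "_").replace(",", "")
                return f"{name}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def _rege_pass(x: np.ndarray, r: np.ndarray) -> np.ndarray:
    """One REGE iteration; returns the updated similarity in [0, 1]."""
    n = x.shape[0]
    neigh = [np.flatnonzero(x[i] + x[:, i]) for i in range(n)]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for i in range(n):
        ki = neigh[i]
        if ki.size == 0:
            continue
        for j in range(n):
            mj = neigh[j]
            if mj.size == 0:
                # j isolated: no partner of i can be matched, the
                # one-sided denominator still counts i's obligations
                den[i, j] = (np.maximum(x[i, ki], 0) + np.maximum(x[ki, i], 0)).sum()
                continue
            # matches[k_idx, m_idx]: score of matching partner k of i
            # with partner m of j, both trophic directions at once
            out_min = np.minimum.outer(x[i, ki], x[j, mj])
            in_min = np.minimum.outer(x[ki, i], x[mj, j])
            out_max = np.maximum.outer(x[i, ki], x[j, mj])
            in_max = np.maximum.outer(x[ki, i], x[mj, j])
            num[i, j] = (r[np.ix_(ki, mj)] * (out_min + in_min)).max(axis=1).sum()
            den[i, j] = (out_max + in_max).max(axis=1).sum()
    total_num = num + num.T
    total_den = den + den.T
    out = np.ones((n, n))  # zero-denominator pairs stay fully similar
    mask = total_den > 0
    out[mask] = total_num[mask] / total_den[mask]
    np.fill_diagonal(out, 1.0)
    return out


def rege_similarity(
    web: FoodWeb, iterations: int = DEFAULT_ITERATIONS
) -> SimilarityMatrix:
    """Iterated REGE similarity of all node pairs of a directed web.

    ``iterations`` (default 3) bounds how far structural context
    propagates: one pass sees direct partners, two passes partners of
    partners, and so on.  Values are on the 0-100 scale.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    labels = sorted(web.nodes)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    x = np.zeros((n, n))
    for u, v in web.edges:
        x[index[u], index[v]] = 1.0
    r = np.ones((n, n))
    for _ in range(iterations):
        r = _rege_pass(x, r)
    return SimilarityMatrix(labels=labels, S=100.0 * r, iterations=iterations)


def cluster_similarity(sim: SimilarityMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative clustering of the REGE similarities.

    Works on dissimilarity 100 - S with the chosen linkage (average by
    default; single and complete are also meaningful here).
    """
    if method not in ("average", "single", "complete", "ward"):
        raise ValueError(f"unknown linkage method {method!r}")
    n = len(sim.labels)
    if n < 2:
        raise ValidationError("need at least two nodes to cluster")
    dist = 100.0 - sim.S
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(n, k=1)]
    z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(labels=list(sim.labels), linkage_matrix=z, method=method)


def cut_dendrogram(dend: Dendrogram, n_clusters: int) -> list[set[str]]:
    """Flat clusters from the merge tree."""
    assignments = hierarchy.fcluster(
        dend.linkage_matrix, t=n_clusters, criterion="maxclust"
    )
    groups: dict[int, set[str]] = {}
    for label, cid in zip(dend.labels, assignments):
        groups.setdefault(int(cid), set()).add(label)
    return list(groups.values())
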