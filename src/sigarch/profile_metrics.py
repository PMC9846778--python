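"""Similarity, flatness and cluster-map metrics over a signature catalogue.

The two scalar metrics at the heart of this module are

* the **cosine similarity** between two profiles,
  ``cos(a, b) = a.b / (|a| |b|)``, and
* the **flatness** of a profile, defined as its cosine similarity to the
  uniform distribution over the 96 contexts. Flatness ranges from
  ``1/sqrt(96) ~ 0.102`` (a one-hot profile) to 1 (perfectly flat) for
  nonnegative profiles, and is invariant to positive rescaling.

Pairwise similarities feed a hierarchical cluster map (average linkage on
cosine distance ``1 - sim``), the construction used to pick groups of
mutually similar signatures for the extraction scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .catalogue_io import SignatureMatrix
from .contexts import N_CONTEXTS

__all__ = [
    "cosine_similarity",
    "flatness",
    "pairwise_similarity",
    "SimilarityMatrix",
    "ClusterMap",
    "build_cluster_map",
    "similarity_groups",
    "scenario_summary",
]


def cosine_similarity(a, b) -> float:
    """Cosine similarity between two vectors; errors on a zero vector."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def flatness(s) -> float:
    """Cosine similarity between profile *s* and the uniform 96-profile.

    Equals 1 iff *s* is uniform; a one-hot profile scores ``1/sqrt(96)``.
    Scale-invariant: ``flatness(c * s) == flatness(s)`` for any ``c > 0``.
    """
    s = np.asarray(s, dtype=float).ravel()
    if s.size != N_CONTEXTS:
        raise ValueError(f"expected a {N_CONTEXTS}-vector, got length {s.size}")
    uniform = np.full(N_CONTEXTS, 1.0 / N_CONTEXTS)
    return cosine_similarity(s, uniform)


@dataclass
class SimilarityMatrix:
    """Pairwise cosine similarities (and distances ``1 - sim``) of signatures."""

    names: list[str]
    sim: np.ndarray

    def __post_init__(self) -> None:
        self.sim = np.asarray(self.sim, dtype=float)
        d = len(self.names)
        if self.sim.shape != (d, d):
            raise ValueError("similarity matrix shape does not match names")
        if not np.allclose(self.sim, self.sim.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.sim), 1.0, atol=1e-12):
            raise ValueError("similarity diagonal must be 1")

    @property
    def dist(self) -> np.ndarray:
        d = 1.0 - self.sim
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sim, index=self.names, columns=self.names)

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle similarities (each unordered pair once)."""
        iu = np.triu_indices(len(self.names), k=1)
        return self.sim[iu]


def pairwise_similarity(sig: SignatureMatrix) -> SimilarityMatrix:
    """All-pairs cosine similarity between the rows of *sig*."""
    if sig.n_signatures < 2:
        raise ValueError("need at least 2 signatures for pairwise similarity")
    x = sig.values
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError("cosine similarity is undefined for a zero vector")
    sim = (x @ x.T) / np.outer(norms, norms)
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(list(sig.names), sim)


@dataclass
class ClusterMap:
    """Average-linkage merge tree over a similarity matrix."""

    names: list[str]
    linkage: np.ndarray  # scipy linkage matrix on cosine distance

    @property
    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage))

    def groups(self, t: float) -> list[list[str]]:
        """Partition of the signatures obtained by cutting the tree at
        distance threshold *t* (members at cophenetic distance <= t)."""
        labels = hierarchy.fcluster(self.linkage, t=t, criterion="distance")
        out: dict[int, list[str]] = {}
        for name, lab in zip(self.names, labels):
            out.setdefault(int(lab), []).append(name)
        return [out[k] for k in sorted(out)]

    def to_newick(self) -> str:
        """Render the merge tree as a Newick string with merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.names[node.id]
            left = render(node.left)
            right = render(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return render(tree) + ";"


def build_cluster_map(simm: SimilarityMatrix) -> ClusterMap:
    """Agglomerative clustering (average linkage) on the distance matrix."""
    condensed = squareform(simm.dist, checks=False)
    linkage = hierarchy.average(condensed)
    return ClusterMap(list(simm.names), linkage)


def similarity_groups(
    sig: SignatureMatrix, similarity_cut: float = 0.8
) -> list[list[str]]:
    """Cluster-map groups at cosine similarity > *similarity_cut*.

    Cuts the average-linkage tree at distance ``1 - similarity_cut``; the
    grouping criterion used throughout scenario construction.
    """
    return build_cluster_map(pairwise_similarity(sig)).groups(1.0 - similarity_cut)


def scenario_summary(sig: SignatureMatrix) -> dict:
    """Median pairwise similarity, most-similar pair and median flatness.

    The median is over the strict upper triangle (each unordered pair counted
    once); ties in the maximal pair are broken by lexicographic name order.
    """
    simm = pairwise_similarity(sig)
    tri = simm.upper_triangle()
    d = sig.n_signatures
    best = None
    for i in range(d):
        for j in range(i + 1, d):
            key = (-simm.sim[i, j], *sorted((sig.names[i], sig.names[j])))
            if best is None or key < best[0]:
                best = (key, (sig.names[i], sig.names[j]), simm.sim[i, j])
    flats = [flatness(row) for row in sig.values]
    return {
        "n_signatures": d,
        "median_similarity": float(np.median(tri)),
        "max_similarity_pair": best[1],
        "max_similarity": float(best[2]),
        "median_flatness": float(np.median(flats)),
    }
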