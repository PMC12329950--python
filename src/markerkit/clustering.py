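"""Jaccard similarity and UPGMA dendrograms for binary band profiles.

Similarity between two banding profiles is the Jaccard coefficient
``J = a / (a + b + c)`` where ``a`` counts shared band presences and
``b``/``c`` the presences unique to either taxon; co-absences carry no
signal for dominant markers and are ignored.  Dendrograms use UPGMA
(size-weighted arithmetic-mean linkage) on ``d = 1 - J``, yielding rooted
ultrametric trees whose node heights are half the merge distance.  Trees
are scikit-bio ``TreeNode`` objects and serialise to Newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import ValidationError
from .io import BandMatrix

__all__ = [
    "SimilarityMatrix",
    "jaccard_similarity",
    "upgma",
    "cophenetic_matrix",
    "discrimination_report",
    "DiscriminationReport",
]


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity coefficients with unit diagonal."""

    taxa: list[str]
    values: np.ndarray
    coefficient: str = "jaccard"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValidationError("similarity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValidationError("similarity diagonal must be 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValidationError("similarities must lie in [0, 1]")

    def to_distance(self) -> DistanceMatrix:
        """Complement transform d = 1 - J."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(d, ids=self.taxa)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def jaccard_similarity(matrix: BandMatrix, level: str = "replicate") -> SimilarityMatrix:
    """Pairwise Jaccard coefficients between the matrix rows.

    Rows are compared as scored by default; pass ``level="species"`` to
    compare per-species consensus profiles of a replicated matrix.
    """
    m = matrix.collapse() if level == "species" else matrix
    x = m.values.astype(bool)
    n = m.n_taxa
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a = int((x[i] & x[j]).sum())
            union = int((x[i] | x[j]).sum())
            if union == 0:
                warnings.warn(
                    f"taxa {m.taxa[i]!r}/{m.taxa[j]!r} share no scored band; "
                    "Jaccard defined as 0"
                )
                sim[i, j] = sim[j, i] = 0.0
            else:
                sim[i, j] = sim[j, i] = a / union
    return SimilarityMatrix(taxa=list(m.taxa), values=sim)


def _as_distance(matrix: SimilarityMatrix | DistanceMatrix | np.ndarray, ids=None) -> DistanceMatrix:
    if isinstance(matrix, SimilarityMatrix):
        return matrix.to_distance()
    if isinstance(matrix, DistanceMatrix):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValidationError("distance matrix is not symmetric")
    if ids is None:
        ids = [f"t{i}" for i in range(arr.shape[0])]
    return DistanceMatrix(arr, ids=ids)


def upgma(matrix: SimilarityMatrix | DistanceMatrix | np.ndarray) -> TreeNode:
    """UPGMA tree from similarities (via d = 1 - J) or distances.

    Size-weighted arithmetic-mean linkage; node height equals half the
    merge distance so the tree is ultrametric.  Ties in the minimum
    linkage distance break on the lexicographically lowest pair of
    cluster representative labels, making the result deterministic.
    """
    dm = _as_distance(matrix)
    labels = list(dm.ids)
    # cluster id -> (representative label, size, height, node)
    clusters: dict[int, tuple[str, int, float, TreeNode]] = {
        i: (lab, 1, 0.0, TreeNode(name=lab)) for i, lab in enumerate(labels)
    }
    dist: dict[tuple[int, int], float] = {}
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = dm[i, j]
    next_id = n
    while len(clusters) > 1:
        # minimum distance, ties by lexicographic representative pair
        best_key, best_d, best_reps = None, np.inf, None
        for (i, j), d in dist.items():
            reps = tuple(sorted((clusters[i][0], clusters[j][0])))
            if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and reps < best_reps):
                best_key, best_d, best_reps = (i, j), d, reps
        i, j = best_key
        rep_i, size_i, h_i, node_i = clusters[i]
        rep_j, size_j, h_j, node_j = clusters[j]
        height = best_d / 2.0
        node_i.length = max(height - h_i, 0.0)
        node_j.length = max(height - h_j, 0.0)
        parent = TreeNode(children=[node_i, node_j])
        new_rep = min(rep_i, rep_j)
        # weighted average linkage to every remaining cluster
        for k in clusters:
            if k in (i, j):
                continue
            d_ik = dist[tuple(sorted((i, k)))]
            d_jk = dist[tuple(sorted((j, k)))]
            d_new = (size_i * d_ik + size_j * d_jk) / (size_i + size_j)
            dist[tuple(sorted((next_id, k)))] = d_new
        dist = {
            key: d for key, d in dist.items() if i not in key and j not in key
        }
        del clusters[i], clusters[j]
        clusters[next_id] = (new_rep, size_i + size_j, height, parent)
        next_id += 1
    (_, _, _, root) = next(iter(clusters.values()))
    root.length = None
    return root


def cophenetic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between the tree's tips."""
    return tree.tip_tip_distances()


@dataclass(frozen=True)
class DiscriminationReport:
    """Whether a focal taxon forms its own clade directly under the root."""

    focal: str
    sole_clade: bool
    neighbor: str | None
    neighbor_distance: float | None
    neighbor_similarity: float | None


def discrimination_report(tree: TreeNode, focal: str) -> DiscriminationReport:
    """Report whether ``focal`` is the sole member of a child clade of the
    root (complete discrimination) and its cophenetically nearest neighbor.

    ``neighbor_similarity`` is ``1 - distance``, meaningful when the tree
    was built from a similarity-derived distance.
    """
    tips = {t.name for t in tree.tips()}
    if focal not in tips:
        raise ValidationError(f"taxon {focal!r} not in tree (tips: {sorted(tips)})")
    sole = False
    for child in tree.children:
        child_tips = {t.name for t in child.tips()} or {child.name}
        if child_tips == {focal}:
            sole = True
    if len(tips) < 2:
        return DiscriminationReport(focal, sole, None, None, None)
    dm = cophenetic_matrix(tree)
    row = {other: dm[focal, other] for other in tips if other != focal}
    neighbor = min(sorted(row), key=row.get)
    d = float(row[neighbor])
    return DiscriminationReport(focal, sole, neighbor, d, 1.0 - d)
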