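"""Section-based L2 distance between oriented shapes and cluster validity.

Once every contour has been projected onto the same section (same canonical
parameterization, same number of samples N), the discrete L2(S^1) distance

    d(a, b) = sqrt( (1/N) * sum_j ||a_j - b_j||^2 )

is a true metric on canonical representatives: symmetric, non-degenerate and
satisfying the triangle inequality.  The uniform 1/N quadrature weight makes
the distance between two concentric uniformly-sampled circles of radii r1, r2
exactly |r1 - r2|.

Cluster validity follows the centroid-based convention: the inter-class
distance is the distance between class mean shapes (not single linkage), the
intra-class diameter is the maximum pairwise distance within a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contour import Contour
from .errors import ShapesectError, UndefinedIndexError

__all__ = [
    "LabeledShapeSet",
    "ValidityReport",
    "section_distance",
    "distance_matrix",
    "class_centroids",
    "dunn_index",
    "davies_bouldin_index",
    "extreme_pairs",
    "interpolate",
    "validity_report",
]


@dataclass
class LabeledShapeSet:
    """Contours with integer class labels (1..K) and optional class names."""

    contours: list
    labels: np.ndarray
    class_names: dict | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.contours) != self.labels.size:
            raise ShapesectError("labels length must match number of contours")
        if self.labels.size == 0:
            raise ShapesectError("empty shape set")

    def __len__(self) -> int:
        return len(self.contours)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def subset(self, indices) -> "LabeledShapeSet":
        indices = np.asarray(indices, dtype=int)
        return LabeledShapeSet(
            [self.contours[i] for i in indices], self.labels[indices], self.class_names
        )

    def map(self, fn) -> "LabeledShapeSet":
        return LabeledShapeSet([fn(c) for c in self.contours], self.labels, self.class_names)


def section_distance(a: Contour, b: Contour) -> float:
    """Discrete L2(S^1) distance between canonical representatives."""
    if a.n_vertices != b.n_vertices:
        raise ShapesectError(
            f"contours must share the sample count: {a.n_vertices} != {b.n_vertices}"
        )
    d = a.vertices - b.vertices
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def distance_matrix(ds: LabeledShapeSet | list) -> np.ndarray:
    """Symmetric pairwise section-distance matrix with zero diagonal."""
    contours = ds.contours if isinstance(ds, LabeledShapeSet) else list(ds)
    stack = np.stack([c.vertices for c in contours])
    n = stack.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        d = stack[i + 1:] - stack[i]
        if d.size:
            mat[i, i + 1:] = np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))
    mat = mat + mat.T
    return mat


def class_centroids(ds: LabeledShapeSet) -> dict:
    """Vertex-wise mean contour of each class (the average shape)."""
    out = {}
    for k in ds.classes:
        idx = ds.class_indices(k)
        if idx.size == 0:
            raise ShapesectError(f"class {k} is empty")
        out[int(k)] = Contour(
            np.mean([ds.contours[i].vertices for i in idx], axis=0), label=int(k)
        )
    return out


def _inter_intra(ds: LabeledShapeSet, dmat: np.ndarray | None = None):
    classes = [int(k) for k in ds.classes]
    cents = class_centroids(ds)
    kk = len(classes)
    inter = np.zeros((kk, kk))
    for i in range(kk):
        for j in range(i + 1, kk):
            inter[i, j] = inter[j, i] = section_distance(cents[classes[i]], cents[classes[j]])
    if dmat is None:
        dmat = distance_matrix(ds)
    intra = np.zeros(kk)
    for i, k in enumerate(classes):
        idx = ds.class_indices(k)
        intra[i] = dmat[np.ix_(idx, idx)].max() if idx.size > 1 else 0.0
    return classes, cents, inter, intra, dmat


def dunn_index(ds: LabeledShapeSet, dmat: np.ndarray | None = None) -> float:
    """Minimal centroid-to-centroid distance over maximal intraclass diameter.

    Higher is better (dense, well-separated clusters).  Raises if every class
    is a singleton (zero denominator).
    """
    classes, _, inter, intra, _ = _inter_intra(ds, dmat)
    if len(classes) < 2:
        raise UndefinedIndexError("Dunn index needs at least two classes")
    diam = intra.max()
    if diam <= 0.0:
        raise UndefinedIndexError("all classes are singletons; Dunn index undefined")
    iu = np.triu_indices(len(classes), k=1)
    return float(inter[iu].min() / diam)


def davies_bouldin_index(ds: LabeledShapeSet, dmat: np.ndarray | None = None) -> float:
    """Mean over classes of the worst (spread_k + spread_k') / centroid distance.

    The spread of a class is the mean distance of its members to the class
    centroid.  Lower is better.  Raises on coincident class centroids.
    """
    classes = [int(k) for k in ds.classes]
    if len(classes) < 2:
        raise UndefinedIndexError("Davies-Bouldin index needs at least two classes")
    cents = class_centroids(ds)
    kk = len(classes)
    delta = np.zeros(kk)
    for i, k in enumerate(classes):
        idx = ds.class_indices(k)
        delta[i] = np.mean([section_distance(ds.contours[j], cents[k]) for j in idx])
    inter = np.zeros((kk, kk))
    for i in range(kk):
        for j in range(i + 1, kk):
            d = section_distance(cents[classes[i]], cents[classes[j]])
            if d <= 0.0:
                raise UndefinedIndexError("coincident class centroids; index undefined")
            inter[i, j] = inter[j, i] = d
    total = 0.0
    for i in range(kk):
        ratios = [(delta[i] + delta[j]) / inter[i, j] for j in range(kk) if j != i]
        total += max(ratios)
    return float(total / kk)


def extreme_pairs(ds: LabeledShapeSet, dmat: np.ndarray | None = None):
    """(argmax same-class pair, argmin different-class pair), ties lexicographic."""
    if dmat is None:
        dmat = distance_matrix(ds)
    n = len(ds)
    best_intra, best_inter = None, None
    max_d, min_d = -np.inf, np.inf
    for i in range(n):
        for j in range(i + 1, n):
            if ds.labels[i] == ds.labels[j]:
                if dmat[i, j] > max_d:
                    max_d, best_intra = dmat[i, j], (i, j)
            else:
                if dmat[i, j] < min_d:
                    min_d, best_inter = dmat[i, j], (i, j)
    return best_intra, best_inter


def interpolate(a: Contour, b: Contour, steps: int) -> list:
    """Linear interpolation between canonical representatives.

    Returns ``steps`` contours at u = j/(steps-1); the endpoints reproduce the
    inputs bit-exactly.
    """
    if steps < 2:
        raise ShapesectError("need at least 2 interpolation steps")
    if a.n_vertices != b.n_vertices:
        raise ShapesectError("contours must share the sample count")
    out = []
    for j in range(steps):
        if j == 0:
            out.append(a.with_vertices(a.vertices.copy()))
        elif j == steps - 1:
            out.append(b.with_vertices(b.vertices.copy()))
        else:
            u = j / (steps - 1)
            out.append(Contour((1.0 - u) * a.vertices + u * b.vertices))
    return out


@dataclass
class ValidityReport:
    """Per-class centroids, inter/intra distances and both validity indices."""

    classes: list
    centroids: dict
    inter: np.ndarray
    intra: np.ndarray
    delta_bar: np.ndarray
    dunn: float
    davies_bouldin: float
    extreme_intra_pair: tuple
    extreme_inter_pair: tuple

    def to_dict(self) -> dict:
        return {
            "classes": [int(k) for k in self.classes],
            "inter": self.inter.tolist(),
            "intra": self.intra.tolist(),
            "delta_bar": self.delta_bar.tolist(),
            "dunn": self.dunn,
            "davies_bouldin": self.davies_bouldin,
            "extreme_intra_pair": list(self.extreme_intra_pair),
            "extreme_inter_pair": list(self.extreme_inter_pair),
        }


def validity_report(ds: LabeledShapeSet) -> ValidityReport:
    """Compute centroids, distance summaries, Dunn and Davies-Bouldin at once."""
    dmat = distance_matrix(ds)
    classes, cents, inter, intra, _ = _inter_intra(ds, dmat)
    delta = np.zeros(len(classes))
    for i, k in enumerate(classes):
        idx = ds.class_indices(k)
        delta[i] = np.mean([section_distance(ds.contours[j], cents[k]) for j in idx])
    pair_intra, pair_inter = extreme_pairs(ds, dmat)
    return ValidityReport(
        classes=classes,
        centroids=cents,
        inter=inter,
        intra=intra,
        delta_bar=delta,
        dunn=dunn_index(ds, dmat),
        davies_bouldin=davies_bouldin_index(ds, dmat),
        extreme_intra_pair=pair_intra,
        extreme_inter_pair=pair_inter,
    )
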