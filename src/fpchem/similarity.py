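"""Fingerprint similarity, hierarchical clustering and its validation.

Similarity between fingerprints is measured by the Pearson correlation
distance, 1 - r.  An elementwise square-root transform compresses the
distances (a monotone transform, so it never changes which pairs are
closer) before Ward agglomeration.  Two validation statistics accompany the
dendrogram: the cophenetic correlation coefficient (Pearson r between the
original dissimilarities and the dendrogram merge heights) and the Hopkins
clustering-tendency statistic, here in the near-zero-is-clusterable
orientation and computed on low-dimensional PCA scores, since uniform
reference sampling in the raw several-thousand-dimensional bounding box is
meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .chromatogram import FingerprintMatrix


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    ids: list[str]
    D: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape must match ids")
        if np.max(np.abs(self.D - self.D.T)) > 1e-12:
            raise ValueError("distance matrix must be symmetric within 1e-12")
        if np.max(np.abs(np.diag(self.D))) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.D < -1e-12):
            raise ValueError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)


@dataclass
class LinkageTree:
    """Agglomeration result: scipy linkage matrix plus leaf ids."""

    ids: list[str]
    Z: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 merges")
        heights = self.Z[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing (Ward monotonicity)")

    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.Z]


@dataclass
class ClusterValidation:
    ccc: float
    hopkins: float
    wavelength_nm: int


def correlation_distance(F: FingerprintMatrix | np.ndarray, ids=None) -> DistanceMatrix:
    """Pairwise Pearson correlation distance, D[i,j] = 1 - r(row_i, row_j)."""
    if isinstance(F, FingerprintMatrix):
        X, ids = F.X, list(F.sample_ids)
    else:
        X = np.asarray(F, dtype=float)
        ids = list(ids) if ids is not None else [f"s{i}" for i in range(X.shape[0])]
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    sds = X.std(axis=1)
    if np.any(sds == 0):
        bad = [ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant fingerprint row(s): {bad}")
    R = np.corrcoef(X)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)  # symmetrize away rounding
    D[D < 0] = 0.0
    return DistanceMatrix(ids=ids, D=D)


def sqrt_transform(D: DistanceMatrix) -> DistanceMatrix:
    """Elementwise square root; monotone, so distance ordering is kept."""
    if np.any(D.D < 0):
        raise ValueError("negative entries; cannot take square root")
    return DistanceMatrix(ids=list(D.ids), D=np.sqrt(D.D))


def ward_linkage(D: DistanceMatrix) -> LinkageTree:
    """Ward agglomeration on the supplied dissimilarities (ward.D2 dialect).

    The inputs are treated as distances and the Ward objective is applied to
    their squares, matching R's ``hclust(method="ward.D2")`` and scipy.
    """
    if len(D.ids) < 2:
        raise ValueError("need >= 2 leaves")
    Z = hierarchy.linkage(D.condensed(), method="ward")
    return LinkageTree(ids=list(D.ids), Z=Z)


def cophenetic_distances(tree: LinkageTree) -> np.ndarray:
    """Condensed cophenetic distances (lowest-common-merge heights)."""
    return hierarchy.cophenet(tree.Z)


def cophenetic_correlation(tree: LinkageTree, D: DistanceMatrix) -> float:
    """Pearson r between original and cophenetic upper-triangle distances."""
    if tree.ids != D.ids:
        raise ValueError("tree leaves and distance-matrix ids differ")
    orig = D.condensed()
    coph = cophenetic_distances(tree)
    if np.ptp(orig) == 0 or np.ptp(coph) == 0:
        raise ValueError("degenerate input: zero variance in distances")
    return float(pearsonr(orig, coph).statistic)


def pca_scores(X: np.ndarray, n_dims: int) -> np.ndarray:
    """Principal-component scores of mean-centred rows (via SVD)."""
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_dims, s.size)
    return U[:, :k] * s[:k]


def hopkins_statistic(
    F: FingerprintMatrix | np.ndarray,
    m_fraction: float = 0.1,
    pca_dims: int = 2,
    seed: int = 0,
) -> float:
    """Hopkins clustering-tendency statistic, near-zero-is-clusterable.

    Fingerprint rows are first standardized (centred and scaled per row, as
    in the correlation distance, which is likewise insensitive to each
    trace's offset and overall intensity); raw coordinate arrays are used
    as-is.  Rows are then projected to ``pca_dims`` principal-component
    scores; ``m = max(5, floor(m_fraction * n))`` real points are drawn
    without replacement and m uniform points in the scores' bounding box.
    With w the nearest-real-neighbour distances of the sampled real points
    and u those of the uniform points, ``H = sum(w) / (sum(w) + sum(u))``:
    clustered data give H near 0, uniform data near 0.5.
    """
    if isinstance(F, FingerprintMatrix):
        X = F.X
        sds = X.std(axis=1)
        if np.any(sds == 0):
            raise ValueError("constant fingerprint row; cannot standardize")
        X = (X - X.mean(axis=1, keepdims=True)) / sds[:, None]
    else:
        X = np.asarray(F, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("Hopkins statistic needs n >= 10")
    scores = pca_scores(X, pca_dims)
    m = max(5, int(np.floor(m_fraction * n)))
    if m < 2 or m > n:
        raise ValueError("invalid number of probe points")
    rng = np.random.default_rng(seed)
    real_idx = rng.choice(n, size=m, replace=False)
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    uniform = rng.uniform(lo, hi, size=(m, scores.shape[1]))

    def nn(points: np.ndarray, exclude_self: bool) -> np.ndarray:
        d = np.linalg.norm(points[:, None, :] - scores[None, :, :], axis=2)
        if exclude_self:
            for row, j in enumerate(real_idx):
                d[row, j] = np.inf
        return d.min(axis=1)

    w = nn(scores[real_idx], exclude_self=True)
    u = nn(uniform, exclude_self=False)
    total = w.sum() + u.sum()
    if total == 0:
        raise ValueError("degenerate scores: all points identical")
    return float(w.sum() / total)


def cut_clusters(tree: LinkageTree, k: int = 2) -> dict[str, int]:
    """Cut the dendrogram into exactly k groups; returns id -> cluster."""
    n = len(tree.ids)
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of leaves")
    labels = hierarchy.fcluster(tree.Z, t=k, criterion="maxclust")
    return {i: int(lab) for i, lab in zip(tree.ids, labels)}


def validate_clustering(
    F: FingerprintMatrix,
    use_sqrt: bool = True,
    seed: int = 0,
) -> tuple[ClusterValidation, LinkageTree, DistanceMatrix]:
    """Distance -> (sqrt) -> Ward -> CCC + Hopkins, in one call.

    The CCC is computed against the matrix actually clustered (the
    square-root-transformed one when ``use_sqrt``).
    """
    D = correlation_distance(F)
    Dt = sqrt_transform(D) if use_sqrt else D
    tree = ward_linkage(Dt)
    val = ClusterValidation(
        ccc=cophenetic_correlation(tree, Dt),
        hopkins=hopkins_statistic(F, seed=seed),
        wavelength_nm=F.wavelength_nm,
    )
    return val, tree, Dt
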