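"""Point-cloud geometric primitives.

k-nearest-neighbor search with a deterministic tie rule, PCA-based
surface-normal and curvature estimation, and principal axes of point
segments.  All routines operate on plain ``(N, 3)`` float arrays in
meters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "NormalField",
    "knn",
    "estimate_normals_curvature",
    "principal_axes",
]

#: Curvature here is "surface variation": smallest eigenvalue of the local
#: covariance over the eigenvalue sum, bounded above by 1/3.
CURVATURE_MAX = 1.0 / 3.0

DEFAULT_K_FINE = 10
DEFAULT_K_COARSE = 30


@dataclass(frozen=True)
class NormalField:
    """Per-point surface normals and curvatures of a cloud.

    Attributes
    ----------
    normals : (N, 3) float array
        Unit normals, oriented toward the view origin used during
        estimation.  Rows flagged invalid are zero vectors.
    curvatures : (N,) float array
        Surface variation ``lambda_min / (l1 + l2 + l3)`` in
        ``[0, 1/3]``.
    valid : (N,) bool array
        False where the neighborhood was degenerate.
    k : int
        Neighborhood size used for estimation.
    """

    normals: np.ndarray
    curvatures: np.ndarray
    valid: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if len(self.normals) != len(self.curvatures):
            raise ValueError("normals and curvatures length mismatch")

    def __len__(self) -> int:
        return len(self.normals)


def _as_points(cloud) -> np.ndarray:
    pts = np.asarray(getattr(cloud, "points", cloud), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (N, 3) points, got shape {pts.shape}")
    return pts


def knn(cloud, k: int) -> np.ndarray:
    """Indices of the ``k`` nearest neighbors of every point (self included).

    Neighbors are ordered by increasing Euclidean distance; exact distance
    ties are broken by ascending point index.

    Parameters
    ----------
    cloud : (N, 3) array or object with ``.points``
    k : int
        Neighborhood size, ``1 <= k <= N``.

    Returns
    -------
    (N, k) int array
    """
    pts = _as_points(cloud)
    n = len(pts)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds cloud size {n}")
    tree = cKDTree(pts)
    # Query extra neighbors so distance ties at the k-th rank can be
    # re-broken by index before truncation.
    kq = min(n, k + 8)
    dist, idx = tree.query(pts, k=kq)
    if kq == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    order = np.lexsort((idx, dist), axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    return idx[:, :k]


def estimate_normals_curvature(cloud, k: int, view_origin) -> NormalField:
    """PCA normal/curvature estimation over k-neighborhoods.

    The normal of a point is the eigenvector of the smallest eigenvalue of
    its k-neighborhood covariance, sign-flipped so that it points toward
    ``view_origin``.  Curvature is the surface variation
    ``lambda_min / sum(lambda)``.

    Degenerate neighborhoods (zero covariance) yield curvature 0, a zero
    normal, and ``valid=False``.
    """
    pts = _as_points(cloud)
    if k < 3:
        raise ValueError("k must be >= 3 for PCA normal estimation")
    view_origin = np.asarray(view_origin, dtype=float)
    nbrs = knn(pts, k)
    neigh = pts[nbrs]                             # (N, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    evals, evecs = np.linalg.eigh(cov)            # ascending eigenvalues
    evals = np.clip(evals, 0.0, None)
    total = evals.sum(axis=1)
    valid = total > 1e-30
    curv = np.zeros(len(pts))
    np.divide(evals[:, 0], total, out=curv, where=valid)
    curv = np.clip(curv, 0.0, CURVATURE_MAX)

    normals = evecs[:, :, 0].copy()
    # Orient toward the sensor; exact right angles fall back to the
    # first-nonzero-component-positive convention.
    to_view = view_origin[None, :] - pts
    dots = np.einsum("ni,ni->n", normals, to_view)
    flip = dots < 0
    normals[flip] *= -1.0
    ortho = dots == 0
    if np.any(ortho):
        normals[ortho] = _canonical_sign(normals[ortho])
    normals[~valid] = 0.0
    return NormalField(normals=normals, curvatures=curv, valid=valid, k=k)


def _canonical_sign(vecs: np.ndarray) -> np.ndarray:
    """Flip rows so the first nonzero component is positive."""
    vecs = np.atleast_2d(np.array(vecs, dtype=float, copy=True))
    for row in vecs:
        for comp in row:
            if comp != 0:
                if comp < 0:
                    row *= -1.0
                break
    return vecs


@dataclass(frozen=True)
class PrincipalAxes:
    """Covariance eigenframe of a point segment.

    ``axes`` rows are unit vectors ordered by decreasing eigenvalue
    (major, minor, normal); ``extents`` are point-projection ranges along
    each axis.
    """

    centroid: np.ndarray
    axes: np.ndarray          # (3, 3), rows major/minor/normal
    extents: np.ndarray       # (3,)
    eigenvalues: np.ndarray   # (3,), descending


def principal_axes(segment_points) -> PrincipalAxes:
    """Principal axes, centroid and extents of a point segment.

    Axes are the covariance eigenvectors ordered by decreasing eigenvalue,
    each with its first nonzero component positive; eigenvalue ties are
    broken by the original axis-index order returned by the symmetric
    eigensolver.
    """
    pts = _as_points(segment_points)
    if len(pts) < 3:
        raise ValueError("principal_axes needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals, kind="stable")[::-1]
    evals = evals[order]
    axes = evecs[:, order].T
    axes = _canonical_sign(axes)
    proj = centered @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    return PrincipalAxes(
        centroid=centroid,
        axes=axes,
        extents=extents,
        eigenvalues=np.clip(evals, 0.0, None),
    )
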