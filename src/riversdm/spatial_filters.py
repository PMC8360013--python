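"""Spatial eigenvector covariates from doubly centered distance matrices.

Large-scale geographic patterns are summarised by the leading eigenvectors
of the doubly centered matrix of Euclidean distances between reaches; the
first few eigenvectors describe broad gradients (coast-to-coast, corner
contrasts) and are attached to the predictor matrix to absorb spatial
structure.  Two centering conventions are implemented:

* ``kind="distance"`` (default): double-center the raw distance matrix,
  C = -1/2 H D H.  This matrix has a rich positive spectrum even for planar
  coordinates, so any reasonable number of leading eigenvectors exists.
* ``kind="squared"``: classical principal-coordinates centering of squared
  distances, C = -1/2 H D^2 H.  For n x 2 coordinates this has rank 2 and
  is exposed for sensitivity analysis and for its closed-form geometry.

For large n the exact eigendecomposition is replaced by a Nystrom
approximation anchored on k-means cluster centres of the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "EigenvectorSet",
    "exact_spatial_eigenvectors",
    "approx_spatial_eigenvectors",
    "assign_eigenvectors",
]

EV_COLUMNS = [f"ev{i + 1}" for i in range(5)]


@dataclass
class EigenvectorSet:
    """k orthonormal, centered eigenvector columns with their eigenvalues."""

    vectors: pd.DataFrame  # n x k, columns ev1..evk
    eigenvalues: np.ndarray  # descending

    def validate(self) -> None:
        V = self.vectors.to_numpy()
        n = V.shape[0]
        if np.abs(V.sum(axis=0)).max() > 1e-8 * n:
            raise ValueError("eigenvector columns must sum to ~0")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")


def _kernel(a: np.ndarray, b: np.ndarray, kind: str) -> np.ndarray:
    D = cdist(a, b)
    return -0.5 * (D**2 if kind == "squared" else D)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    V = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            V[:, j] = -col
    return V


def _as_set(V: np.ndarray, eigvals: np.ndarray, index) -> EigenvectorSet:
    V = _fix_signs(V)
    cols = [f"ev{i + 1}" for i in range(V.shape[1])]
    return EigenvectorSet(
        vectors=pd.DataFrame(V, columns=cols, index=index), eigenvalues=np.asarray(eigvals)
    )


def exact_spatial_eigenvectors(
    coords: np.ndarray | pd.DataFrame, k: int = 5, kind: str = "distance"
) -> EigenvectorSet:
    """Leading eigenvectors of the doubly centered distance matrix.

    ``coords`` is an n x 2 array (or DataFrame whose index labels the
    units).  Only positive-eigenvalue vectors are returned; if fewer than
    ``k`` exist the call fails.  Sign convention: first non-zero loading of
    each column is positive.
    """
    index = coords.index if isinstance(coords, pd.DataFrame) else None
    pts = np.asarray(coords, dtype=float)
    n = pts.shape[0]
    if n < k + 1:
        raise ValueError("need at least k+1 points")
    if not np.isfinite(pts).all():
        raise ValueError("coordinates must be finite")
    K = _kernel(pts, pts, kind)
    rmean = K.mean(axis=1, keepdims=True)
    cmean = K.mean(axis=0, keepdims=True)
    C = K - rmean - cmean + K.mean()
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1])) * 1e-10
    n_pos = int((eigvals > tol).sum())
    if n_pos == 0:
        raise ValueError("degenerate coordinates: no positive eigenvalue")
    if n_pos < k:
        raise ValueError(
            f"only {n_pos} positive eigenvalues available, {k} requested "
            f"(kind={kind!r})"
        )
    return _as_set(eigvecs[:, :k], eigvals[:k], index)


def approx_spatial_eigenvectors(
    coords: np.ndarray | pd.DataFrame,
    k: int = 5,
    n_anchors: int = 100,
    seed: int = 0,
    kind: str = "distance",
) -> EigenvectorSet:
    """Nystrom approximation of :func:`exact_spatial_eigenvectors`.

    Anchors are k-means cluster centres of the coordinates (the points
    themselves when ``n_anchors == n``, in which case the result equals the
    exact decomposition up to sign).  Columns are re-centered and
    re-orthonormalised after the Nystrom extension; runtime is
    O(n * n_anchors) plus the anchor eigendecomposition, so n in the tens of
    thousands is feasible.
    """
    index = coords.index if isinstance(coords, pd.DataFrame) else None
    pts = np.asarray(coords, dtype=float)
    n = pts.shape[0]
    if n_anchors < k + 1:
        raise ValueError("n_anchors must be at least k+1")
    if n_anchors > n:
        raise ValueError("n_anchors cannot exceed the number of points")

    if n_anchors == n:
        anchors = pts
    else:
        km = KMeans(n_clusters=n_anchors, random_state=seed, n_init=4)
        km.fit(pts)
        anchors = km.cluster_centers_

    K_mm = _kernel(anchors, anchors, kind)
    col_m = K_mm.mean(axis=0, keepdims=True)
    C_mm = K_mm - K_mm.mean(axis=1, keepdims=True) - col_m + K_mm.mean()
    eigvals, eigvecs = np.linalg.eigh(C_mm)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1])) * 1e-10
    if int((eigvals > tol).sum()) < k:
        raise ValueError("anchor decomposition has fewer than k positive eigenvalues")

    K_nm = _kernel(pts, anchors, kind)
    C_nm = K_nm - K_nm.mean(axis=1, keepdims=True) - col_m + K_mm.mean()
    U = C_nm @ eigvecs[:, :k] / eigvals[:k]

    # re-center and re-orthonormalise the extended columns
    U = U - U.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(U)

    # Rayleigh-Ritz refinement: project the full centered kernel onto the
    # approximated subspace and re-diagonalise.  This undoes the rotation
    # the anchor sampling introduces between near-degenerate eigenvectors,
    # at O(n^2 k) time but only O(n k) memory (blockwise kernel rows).
    CQ = np.zeros_like(Q)
    block = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, block):
        K_blk = _kernel(pts[start : start + block], pts, kind)
        CQ[start : start + block] = K_blk @ Q
    CQ -= CQ.mean(axis=0, keepdims=True)  # column centering of C (1'Q = 0)
    B = Q.T @ CQ
    B = (B + B.T) / 2.0
    ritz_vals, ritz_vecs = np.linalg.eigh(B)
    order = np.argsort(ritz_vals)[::-1]
    return _as_set(Q @ ritz_vecs[:, order], ritz_vals[order], index)


def assign_eigenvectors(
    reach_evs: pd.DataFrame, site_to_reach: pd.DataFrame
) -> pd.DataFrame:
    """Copy reach-level eigenvector columns onto sites via their mapping.

    ``reach_evs`` is indexed by reach_id; ``site_to_reach`` has columns
    site_id and reach_id.  Every site must be mapped.
    """
    missing = set(site_to_reach["reach_id"]) - set(reach_evs.index)
    if missing:
        raise KeyError(f"unmapped reach ids: {sorted(missing)[:5]}")
    out = reach_evs.loc[site_to_reach["reach_id"]].reset_index(drop=True)
    out.index = pd.Index(site_to_reach["site_id"], name="site_id")
    return out
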