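"""Convex nonnegative matrix factorization of MRSI spectra.

Rows of the data matrix are voxel spectra. The factorization constrains the
sources to nonnegative combinations of the data rows (``F = Wᵀ X`` with
``W >= 0``) and the per-spectrum mixing weights to ``G >= 0``, while the
spectra themselves may contain (small) negative values. Multiplicative
updates follow the convex-NMF scheme of Ding, Li & Jordan (2010), with a
seeded k-means initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.cluster import KMeans

from glioresponse.datatypes import SliceRecord

_EPS = 1e-12

DEFAULT_K = 20


@dataclass
class SpectrumMatrix:
    """n x L stack of voxel spectra with per-row provenance."""

    X: np.ndarray
    row_ids: list[tuple[str, int, int, int]]  # (subject, slice, row, col)
    ppm_axis: np.ndarray

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2D")
        if len(self.row_ids) != self.X.shape[0]:
            raise ValueError("row_ids length mismatch")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row_ids must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class SourceSet:
    """Result of a convex-NMF fit: sources + both weight matrices."""

    F: np.ndarray            # (K, L) sources
    W: np.ndarray            # (n_train, K) >= 0, sources = Wᵀ X
    G: np.ndarray            # (n_train, K) >= 0, per-spectrum mixing
    ppm_axis: np.ndarray
    K: int
    seed: int
    n_iter: int
    error_log: list[float] = field(default_factory=list)

    @property
    def final_error(self) -> float:
        return self.error_log[-1] if self.error_log else np.nan


def select_tumor_spectra(record: SliceRecord) -> SpectrumMatrix:
    """Spectra of voxels whose full pixel block lies inside the tumor mask.

    Row order is row-major over the grid. An empty selection returns a
    0-row matrix with a warning; the caller should skip the slice.
    """
    if record.grid is None:
        raise ValueError(f"slice {record.subject_id}/{record.slice_index} has no grid")
    grid = record.grid
    in_t = grid.in_tumor(record.mask)
    rows, ids = [], []
    for r in range(grid.dims[0]):
        for c in range(grid.dims[1]):
            if in_t[r, c]:
                rows.append(grid.spectra[r, c])
                ids.append((record.subject_id, record.slice_index, r, c))
    if not rows:
        warnings.warn(
            f"no tumor-complete voxel in {record.subject_id}/{record.slice_index}",
            stacklevel=2,
        )
        return SpectrumMatrix(
            X=np.zeros((0, grid.spectra.shape[-1])), row_ids=[], ppm_axis=grid.ppm_axis
        )
    return SpectrumMatrix(X=np.asarray(rows), row_ids=ids, ppm_axis=grid.ppm_axis)


def stack_spectra(mats: list[SpectrumMatrix]) -> SpectrumMatrix:
    mats = [m for m in mats if m.n > 0]
    if not mats:
        raise ValueError("no spectra to stack")
    return SpectrumMatrix(
        X=np.vstack([m.X for m in mats]),
        row_ids=[rid for m in mats for rid in m.row_ids],
        ppm_axis=mats[0].ppm_axis,
    )


def _reconstruction_error(X: np.ndarray, G: np.ndarray, W: np.ndarray,
                          norm_X: float) -> float:
    return float(np.linalg.norm(X - G @ (W.T @ X)) / norm_X)


def _init_kmeans(X: np.ndarray, K: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Cluster-indicator initialization (smoothed), per Ding et al."""
    n = X.shape[0]
    try:
        km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(X)
        labels = km.labels_
    except Exception:  # degenerate input: fall back to random assignment
        labels = np.random.default_rng(seed).integers(0, K, size=n)
    H = np.zeros((n, K))
    H[np.arange(n), labels] = 1.0
    counts = H.sum(axis=0)
    counts[counts == 0] = 1.0
    G0 = H + 0.2
    W0 = (H + 0.2) / counts
    return W0, G0


def fit_convex_nmf(
    X_train: SpectrumMatrix | np.ndarray,
    K: int = DEFAULT_K,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    ppm_axis: np.ndarray | None = None,
    polish: bool = True,
    polish_iter: int = 100,
) -> SourceSet:
    """Fit convex-NMF: ``X ≈ G (Wᵀ X)`` with W, G >= 0.

    Iterates the multiplicative updates until the relative change of the
    Frobenius reconstruction error drops below ``tol`` or ``max_iter`` is
    reached. Nonnegativity of W and G is preserved by every update, and the
    logged error is non-increasing.

    The multiplicative updates have a very slow sublinear tail, so by
    default a monotone block-coordinate polish follows: exact NNLS for the
    rows of G alternating with Lipschitz-step projected-gradient descent on
    W. Both phases decrease the same objective, so the full error log stays
    non-increasing.
    """
    if isinstance(X_train, SpectrumMatrix):
        X = np.asarray(X_train.X, dtype=float)
        ppm = X_train.ppm_axis
    else:
        X = np.asarray(X_train, dtype=float)
        ppm = ppm_axis if ppm_axis is not None else np.arange(X.shape[1])[::-1].astype(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in spectra")
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds n_train={n}")

    W, G = _init_kmeans(X, K, seed)
    Y = X @ X.T
    Yp = (np.abs(Y) + Y) / 2.0
    Ym = (np.abs(Y) - Y) / 2.0
    norm_X = float(np.linalg.norm(X))
    if norm_X == 0:
        raise ValueError("zero data matrix")

    errors = [_reconstruction_error(X, G, W, norm_X)]
    it = 0
    for it in range(1, max_iter + 1):
        YpW = Yp @ W
        YmW = Ym @ W
        GWt = G @ W.T
        num = YpW + GWt @ YmW
        den = YmW + GWt @ YpW
        G = G * np.sqrt(num / np.maximum(den, _EPS))

        GtG = G.T @ G
        num = Yp @ G + Ym @ W @ GtG
        den = Ym @ G + Yp @ W @ GtG
        W = W * np.sqrt(num / np.maximum(den, _EPS))

        err = _reconstruction_error(X, G, W, norm_X)
        errors.append(err)
        if abs(errors[-2] - errors[-1]) < tol * max(errors[-2], _EPS):
            break

    if polish:
        lip_scale = 2.0 * np.linalg.norm(Y, 2)
        for pit in range(polish_iter):
            A = (W.T @ X).T  # (L, K) current sources as design matrix
            for i in range(n):
                G[i], _ = nnls(A, X[i])
            GtG = G.T @ G
            lip = lip_scale * max(np.linalg.norm(GtG, 2), _EPS)
            YG = Y @ G
            for _ in range(10):
                grad = 2.0 * (Y @ W @ GtG - YG)
                W = np.maximum(W - grad / lip, 0.0)
            err = _reconstruction_error(X, G, W, norm_X)
            errors.append(err)
            it += 1
            if abs(errors[-2] - errors[-1]) < tol * max(errors[-2], _EPS):
                break

    F = W.T @ X
    return SourceSet(F=F, W=W, G=G, ppm_axis=ppm, K=K, seed=seed,
                     n_iter=it, error_log=errors)


def project(spectra: SpectrumMatrix | np.ndarray, source_set: SourceSet) -> np.ndarray:
    """Nonnegative least-squares weights of each spectrum on the sources."""
    if isinstance(spectra, SpectrumMatrix):
        if spectra.ppm_axis.shape != source_set.ppm_axis.shape or not np.allclose(
            spectra.ppm_axis, source_set.ppm_axis
        ):
            raise ValueError("ppm axis mismatch between spectra and sources")
        X = spectra.X
    else:
        X = np.asarray(spectra, dtype=float)
    A = source_set.F.T  # (L, K)
    out = np.empty((X.shape[0], source_set.K))
    for i, x in enumerate(X):
        out[i], _ = nnls(A, x)
    return out


def match_sources(recovered: np.ndarray, truth: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of recovered to true sources on cosine similarity.

    Returns (assignment into truth rows, per-pair cosine similarities).
    Used by every recovery test to resolve permutation/scale ambiguity.
    """
    def _unit(M):
        nrm = np.linalg.norm(M, axis=1, keepdims=True)
        return M / np.maximum(nrm, _EPS)

    sim = _unit(recovered) @ _unit(truth).T
    rr, cc = linear_sum_assignment(-sim)
    order = np.empty(len(rr), dtype=int)
    order[rr] = cc
    return order, sim[rr, cc]
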