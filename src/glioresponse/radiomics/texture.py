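"""Texture matrices (GLCM, GLRLM, GLSZM, NGTDM) and the 42 texture features.

The feature manifest is 11 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM statistics
(classical Haralick / Galloway-Chu-Dasarathy / Thibault / Amadasun sets).
GLCM and GLRLM features are computed per displacement direction and averaged;
GLSZM and NGTDM are single-matrix. Degenerate (e.g. constant) regions produce
well-defined limits, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

_EPS = np.finfo(float).eps

#: default displacement directions at distance 1 (0, 45, 90, 135 degrees)
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

GLCM_NAMES = [
    "GLCM_Autocorrelation", "GLCM_ClusterProminence", "GLCM_ClusterShade",
    "GLCM_Contrast", "GLCM_Correlation", "GLCM_Dissimilarity", "GLCM_Energy",
    "GLCM_Entropy", "GLCM_Homogeneity", "GLCM_SumAverage", "GLCM_Variance",
]
GLRLM_NAMES = [
    "GLRLM_SRE", "GLRLM_LRE", "GLRLM_GLN", "GLRLM_RLN", "GLRLM_RP",
    "GLRLM_LGRE", "GLRLM_HGRE", "GLRLM_SRLGE", "GLRLM_SRHGE",
    "GLRLM_LRLGE", "GLRLM_LRHGE", "GLRLM_GLV", "GLRLM_RLV",
]
GLSZM_NAMES = [
    "GLSZM_SAE", "GLSZM_LAE", "GLSZM_GLN", "GLSZM_ZSN", "GLSZM_ZP",
    "GLSZM_LGZE", "GLSZM_HGZE", "GLSZM_SALGE", "GLSZM_SAHGE",
    "GLSZM_LALGE", "GLSZM_LAHGE", "GLSZM_GLV", "GLSZM_ZSV",
]
NGTDM_NAMES = [
    "NGTDM_Coarseness", "NGTDM_Contrast", "NGTDM_Busyness",
    "NGTDM_Complexity", "NGTDM_Strength",
]
TEXTURE_NAMES = GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES


@dataclass
class TextureConfig:
    n_gray_levels: int = 32
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    run_directions: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        if not self.offsets:
            raise ValueError("offsets must be nonempty")


def quantize(roi: np.ndarray, n_gray_levels: int) -> np.ndarray:
    """Equal-width binning over the ROI range into integer levels 1..n.

    A constant image maps entirely to level 1.
    """
    roi = np.asarray(roi, dtype=float)
    if not np.all(np.isfinite(roi)):
        raise ValueError("non-finite intensities in ROI")
    lo, hi = roi.min(), roi.max()
    if hi == lo:
        return np.ones(roi.shape, dtype=np.int64)
    q = np.floor((roi - lo) / (hi - lo) * n_gray_levels).astype(np.int64) + 1
    return np.clip(q, 1, n_gray_levels)


# ---------------------------------------------------------------- matrices


def glcm_matrix(q: np.ndarray, offset: tuple[int, int], n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence matrix at one offset, normalized to sum 1."""
    dy, dx = offset
    h, w = q.shape
    mat = np.zeros((n_levels, n_levels))
    r0, r1 = max(0, -dy), min(h, h - dy)
    c0, c1 = max(0, -dx), min(w, w - dx)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
    np.add.at(mat, (a.ravel() - 1, b.ravel() - 1), 1.0)
    mat = mat + mat.T
    s = mat.sum()
    return mat / s if s > 0 else mat


def glrlm_matrix(q: np.ndarray, direction: tuple[int, int], n_levels: int) -> np.ndarray:
    """Run-length counts: rows = gray level, cols = run length."""
    h, w = q.shape
    max_run = max(h, w)
    mat = np.zeros((n_levels, max_run))
    dy, dx = direction
    # starting points: cells with no predecessor along (dy, dx)
    for r in range(h):
        for c in range(w):
            pr, pc = r - dy, c - dx
            if 0 <= pr < h and 0 <= pc < w and q[pr, pc] == q[r, c]:
                continue  # interior of a run
            length = 1
            nr, nc = r + dy, c + dx
            while 0 <= nr < h and 0 <= nc < w and q[nr, nc] == q[r, c]:
                length += 1
                nr += dy
                nc += dx
            mat[q[r, c] - 1, length - 1] += 1
    return mat


def glszm_matrix(q: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts over 8-connected constant-level zones (no direction)."""
    max_zone = q.size
    mat = np.zeros((n_levels, max_zone))
    structure = np.ones((3, 3), dtype=int)
    for level in range(1, n_levels + 1):
        binary = q == level
        if not binary.any():
            continue
        lab, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            mat[level - 1, s - 1] += 1
    return mat


def ngtdm_matrix(q: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level gray-tone difference sums ``s_i`` and occurrence counts ``n_i``.

    Every pixel contributes; the neighborhood average uses the available
    8-neighbors (border pixels use fewer).
    """
    h, w = q.shape
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    qf = q.astype(float)
    for r in range(h):
        for c in range(w):
            nb = qf[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
            total = nb.sum() - qf[r, c]
            count = nb.size - 1
            if count == 0:
                continue
            avg = total / count
            lvl = q[r, c] - 1
            s[lvl] += abs(qf[r, c] - avg)
            n[lvl] += 1
    return s, n


def texture_matrix(q: np.ndarray, kind: str, config: TextureConfig | None = None):
    """Dispatch to one of the four texture-matrix builders."""
    config = config or TextureConfig()
    n = config.n_gray_levels
    if kind == "GLCM":
        return [glcm_matrix(q, off, n) for off in config.offsets]
    if kind == "GLRLM":
        return [glrlm_matrix(q, d, n) for d in config.run_directions]
    if kind == "GLSZM":
        return glszm_matrix(q, n)
    if kind == "NGTDM":
        return ngtdm_matrix(q, n)
    raise ValueError(f"unknown texture matrix kind {kind!r}")


# ---------------------------------------------------------------- features


def glcm_features(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    var_i = float(((ii - mu_i) ** 2 * p).sum())
    var_j = float(((jj - mu_j) ** 2 * p).sum())
    sd = np.sqrt(var_i * var_j)
    if sd > _EPS:
        corr = float(((ii - mu_i) * (jj - mu_j) * p).sum() / sd)
    else:
        corr = 1.0  # flat region: perfectly correlated by convention
    nz = p[p > 0]
    return {
        "GLCM_Autocorrelation": float((ii * jj * p).sum()),
        "GLCM_ClusterProminence": float(((ii + jj - mu_i - mu_j) ** 4 * p).sum()),
        "GLCM_ClusterShade": float(((ii + jj - mu_i - mu_j) ** 3 * p).sum()),
        "GLCM_Contrast": float(((ii - jj) ** 2 * p).sum()),
        "GLCM_Correlation": corr,
        "GLCM_Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "GLCM_Energy": float((p ** 2).sum()),
        "GLCM_Entropy": float(-(nz * np.log2(nz)).sum()),
        "GLCM_Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "GLCM_SumAverage": float(((ii + jj) * p).sum()),
        "GLCM_Variance": var_i,
    }


def _run_zone_features(mat: np.ndarray, n_pixels: int, prefix: str,
                       names: list[str]) -> dict[str, float]:
    """Shared statistics for run-length and size-zone matrices."""
    n_runs = mat.sum()
    if n_runs == 0:
        return {name: 0.0 for name in names}
    i = np.arange(1, mat.shape[0] + 1, dtype=float)
    r = np.arange(1, mat.shape[1] + 1, dtype=float)
    ii, rr = np.meshgrid(i, r, indexing="ij")
    p = mat / n_runs
    gl_marg = mat.sum(axis=1)
    rl_marg = mat.sum(axis=0)
    mu_i = float((p * ii).sum())
    mu_r = float((p * rr).sum())
    vals = [
        float((mat / rr ** 2).sum() / n_runs),          # SRE / SAE
        float((mat * rr ** 2).sum() / n_runs),          # LRE / LAE
        float((gl_marg ** 2).sum() / n_runs),           # GLN
        float((rl_marg ** 2).sum() / n_runs),           # RLN / ZSN
        float(n_runs / n_pixels),                       # RP / ZP
        float((mat / ii ** 2).sum() / n_runs),          # LGRE / LGZE
        float((mat * ii ** 2).sum() / n_runs),          # HGRE / HGZE
        float((mat / (ii ** 2 * rr ** 2)).sum() / n_runs),
        float((mat * ii ** 2 / rr ** 2).sum() / n_runs),
        float((mat * rr ** 2 / ii ** 2).sum() / n_runs),
        float((mat * ii ** 2 * rr ** 2).sum() / n_runs),
        float((p * (ii - mu_i) ** 2).sum()),            # GLV
        float((p * (rr - mu_r) ** 2).sum()),            # RLV / ZSV
    ]
    return dict(zip(names, vals))


def ngtdm_features(s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    N = n.sum()
    p = n / N
    act = p > 0
    levels = np.arange(1, len(p) + 1, dtype=float)
    i = levels[act]
    pi = p[act]
    si = s[act]
    ngp = act.sum()
    denom = float((pi * si).sum())
    coarseness = 1.0 / denom if denom > _EPS else 1e6
    if ngp > 1:
        d_ij = (i[:, None] - i[None, :]) ** 2
        contrast = float((pi[:, None] * pi[None, :] * d_ij).sum()
                         / (ngp * (ngp - 1)) * si.sum() / N)
        busy_den = float(np.abs(i[:, None] * pi[:, None]
                                - i[None, :] * pi[None, :]).sum())
        busyness = denom / busy_den if busy_den > _EPS else 0.0
        pij = pi[:, None] + pi[None, :]
        complexity = float((np.abs(i[:, None] - i[None, :])
                            * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                            / pij).sum() / N)
        s_sum = float(si.sum())
        strength = float((pij * d_ij).sum() / s_sum) if s_sum > _EPS else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "NGTDM_Coarseness": coarseness,
        "NGTDM_Contrast": contrast,
        "NGTDM_Busyness": busyness,
        "NGTDM_Complexity": complexity,
        "NGTDM_Strength": strength,
    }


def texture_features(roi: np.ndarray, config: TextureConfig | None = None
                     ) -> dict[str, float]:
    """The 42 texture statistics of a rectangular ROI, in manifest order."""
    config = config or TextureConfig()
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or min(roi.shape) < 2:
        raise ValueError("ROI must be at least 2x2")
    q = quantize(roi, config.n_gray_levels)
    n = config.n_gray_levels
    n_pixels = q.size

    per_offset = [glcm_features(glcm_matrix(q, off, n)) for off in config.offsets]
    glcm = {k: float(np.mean([d[k] for d in per_offset])) for k in GLCM_NAMES}

    per_dir = [
        _run_zone_features(glrlm_matrix(q, d, n), n_pixels, "GLRLM", GLRLM_NAMES)
        for d in config.run_directions
    ]
    glrlm = {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}

    glszm = _run_zone_features(glszm_matrix(q, n), n_pixels, "GLSZM", GLSZM_NAMES)
    ngtdm = ngtdm_features(*ngtdm_matrix(q, n))

    out = {**glcm, **glrlm, **glszm, **ngtdm}
    return {name: out[name] for name in TEXTURE_NAMES}
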