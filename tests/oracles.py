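"""Independent brute-force oracles used by the texture tests.

Everything here is written as plain-Python loops straight from the textbook
definitions, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from collections import defaultdict


def oracle_glcm(q, offset):
    """Symmetric co-occurrence probabilities {(i, j): p} by pair enumeration."""
    dy, dx = offset
    h, w = len(q), len(q[0])
    counts = defaultdict(float)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[(q[r][c], q[r2][c2])] += 1
                counts[(q[r2][c2], q[r][c])] += 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()} if total else {}


def oracle_glcm_features(p):
    """The 11 GLCM statistics from a {(i,j): p} dict."""
    mu_i = sum(i * v for (i, _), v in p.items())
    mu_j = sum(j * v for (_, j), v in p.items())
    var_i = sum((i - mu_i) ** 2 * v for (i, _), v in p.items())
    var_j = sum((j - mu_j) ** 2 * v for (_, j), v in p.items())
    sd = math.sqrt(var_i * var_j)
    if sd > 1e-12:
        corr = sum((i - mu_i) * (j - mu_j) * v for (i, j), v in p.items()) / sd
    else:
        corr = 1.0
    return {
        "GLCM_Autocorrelation": sum(i * j * v for (i, j), v in p.items()),
        "GLCM_ClusterProminence": sum(
            (i + j - mu_i - mu_j) ** 4 * v for (i, j), v in p.items()),
        "GLCM_ClusterShade": sum(
            (i + j - mu_i - mu_j) ** 3 * v for (i, j), v in p.items()),
        "GLCM_Contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "GLCM_Correlation": corr,
        "GLCM_Dissimilarity": sum(abs(i - j) * v for (i, j), v in p.items()),
        "GLCM_Energy": sum(v * v for v in p.values()),
        "GLCM_Entropy": -sum(v * math.log2(v) for v in p.values() if v > 0),
        "GLCM_Homogeneity": sum(v / (1 + abs(i - j)) for (i, j), v in p.items()),
        "GLCM_SumAverage": sum((i + j) * v for (i, j), v in p.items()),
        "GLCM_Variance": var_i,
    }


def oracle_runs(q, direction):
    """Run counts {(level, length): n} along one direction, by line walking."""
    dy, dx = direction
    h, w = len(q), len(q[0])
    runs = defaultdict(int)
    for r in range(h):
        for c in range(w):
            pr, pc = r - dy, c - dx
            if 0 <= pr < h and 0 <= pc < w and q[pr][pc] == q[r][c]:
                continue
            length, nr, nc = 1, r + dy, c + dx
            while 0 <= nr < h and 0 <= nc < w and q[nr][nc] == q[r][c]:
                length += 1
                nr, nc = nr + dy, nc + dx
            runs[(q[r][c], length)] += 1
    return dict(runs)


def oracle_zones(q):
    """Zone counts {(level, size): n} via 8-connected flood fill."""
    h, w = len(q), len(q[0])
    seen = [[False] * w for _ in range(h)]
    zones = defaultdict(int)
    for r in range(h):
        for c in range(w):
            if seen[r][c]:
                continue
            level = q[r][c]
            stack, size = [(r, c)], 0
            seen[r][c] = True
            while stack:
                cr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = cr + dr, cc + dc
                        if (0 <= nr < h and 0 <= nc < w and not seen[nr][nc]
                                and q[nr][nc] == level):
                            seen[nr][nc] = True
                            stack.append((nr, nc))
            zones[(level, size)] += 1
    return dict(zones)


def oracle_run_zone_features(counts, n_pixels, names):
    """The 13 shared run/zone statistics from {(level, length): n}."""
    n_runs = sum(counts.values())
    if n_runs == 0:
        return {name: 0.0 for name in names}
    mu_i = sum(i * n for (i, _), n in counts.items()) / n_runs
    mu_r = sum(r * n for (_, r), n in counts.items()) / n_runs
    gl = defaultdict(float)
    rl = defaultdict(float)
    for (i, r), n in counts.items():
        gl[i] += n
        rl[r] += n
    vals = [
        sum(n / r ** 2 for (_, r), n in counts.items()) / n_runs,
        sum(n * r ** 2 for (_, r), n in counts.items()) / n_runs,
        sum(v ** 2 for v in gl.values()) / n_runs,
        sum(v ** 2 for v in rl.values()) / n_runs,
        n_runs / n_pixels,
        sum(n / i ** 2 for (i, _), n in counts.items()) / n_runs,
        sum(n * i ** 2 for (i, _), n in counts.items()) / n_runs,
        sum(n / (i ** 2 * r ** 2) for (i, r), n in counts.items()) / n_runs,
        sum(n * i ** 2 / r ** 2 for (i, r), n in counts.items()) / n_runs,
        sum(n * r ** 2 / i ** 2 for (i, r), n in counts.items()) / n_runs,
        sum(n * i ** 2 * r ** 2 for (i, r), n in counts.items()) / n_runs,
        sum(n * (i - mu_i) ** 2 for (i, _), n in counts.items()) / n_runs,
        sum(n * (r - mu_r) ** 2 for (_, r), n in counts.items()) / n_runs,
    ]
    return dict(zip(names, vals))


def oracle_ngtdm(q, n_levels):
    """Per-level difference sums and counts; every pixel contributes, using
    whichever of its 8 neighbors exist."""
    h, w = len(q), len(q[0])
    s = [0.0] * n_levels
    n = [0] * n_levels
    for r in range(h):
        for c in range(w):
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w:
                        nb.append(q[nr][nc])
            if not nb:
                continue
            avg = sum(nb) / len(nb)
            s[q[r][c] - 1] += abs(q[r][c] - avg)
            n[q[r][c] - 1] += 1
    return s, n


def oracle_ngtdm_features(s, n):
    N = sum(n)
    p = [ni / N for ni in n]
    act = [k for k in range(len(p)) if p[k] > 0]
    ngp = len(act)
    denom = sum(p[k] * s[k] for k in act)
    coarseness = 1.0 / denom if denom > 1e-12 else 1e6
    contrast = busyness = complexity = strength = 0.0
    if ngp > 1:
        lev = [k + 1 for k in act]
        contrast = (
            sum(p[a] * p[b] * (la - lb) ** 2
                for a, la in zip(act, lev) for b, lb in zip(act, lev))
            / (ngp * (ngp - 1)) * sum(s[k] for k in act) / N
        )
        busy_den = sum(abs(la * p[a] - lb * p[b])
                       for a, la in zip(act, lev) for b, lb in zip(act, lev))
        busyness = denom / busy_den if busy_den > 1e-12 else 0.0
        complexity = sum(
            abs(la - lb) * (p[a] * s[a] + p[b] * s[b]) / (p[a] + p[b])
            for a, la in zip(act, lev) for b, lb in zip(act, lev)
        ) / N
        s_sum = sum(s[k] for k in act)
        strength = (sum((p[a] + p[b]) * (la - lb) ** 2
                        for a, la in zip(act, lev) for b, lb in zip(act, lev))
                    / s_sum) if s_sum > 1e-12 else 0.0
    return {
        "NGTDM_Coarseness": coarseness,
        "NGTDM_Contrast": contrast,
        "NGTDM_Busyness": busyness,
        "NGTDM_Complexity": complexity,
        "NGTDM_Strength": strength,
    }


def oracle_texture_features(q, offsets, run_directions, n_levels, names42):
    """All 42 statistics of an already-quantized image, averaged like the
    implementation promises (per offset / per direction)."""
    n_pixels = len(q) * len(q[0])
    glcm_names = [n for n in names42 if n.startswith("GLCM")]
    glrlm_names = [n for n in names42 if n.startswith("GLRLM")]
    glszm_names = [n for n in names42 if n.startswith("GLSZM")]

    per_off = [oracle_glcm_features(oracle_glcm(q, off)) for off in offsets]
    out = {k: sum(d[k] for d in per_off) / len(per_off) for k in glcm_names}

    per_dir = [
        oracle_run_zone_features(oracle_runs(q, d), n_pixels, glrlm_names)
        for d in run_directions
    ]
    out.update({k: sum(d[k] for d in per_dir) / len(per_dir) for k in glrlm_names})

    out.update(oracle_run_zone_features(oracle_zones(q), n_pixels, glszm_names))
    out.update(oracle_ngtdm_features(*oracle_ngtdm(q, n_levels)))
    return out
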