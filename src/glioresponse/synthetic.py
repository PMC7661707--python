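"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Spectra are noisy convex nonnegative mixtures of metabolite-like source
profiles with class-dependent mixing; images carry class-dependent texture
(treated slices contain hypointense foci inside the tumor mask). Everything
is driven by one seeded generator hierarchy so cohorts are bitwise
reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from glioresponse.datatypes import CONTROL, TREATED, MRSIGrid, SliceRecord

# Metabolite-like peak templates: name -> list of (center ppm, width, amplitude).
# Each template has a distinct peak set so profiles are pairwise non-identical.
PEAK_TEMPLATES: list[tuple[str, list[tuple[float, float, float]]]] = [
    ("pufa_lac", [(2.8, 0.06, 0.7), (1.33, 0.05, 1.0), (0.9, 0.08, 0.35)]),
    ("glx_ala", [(2.35, 0.08, 0.8), (2.1, 0.08, 0.7), (1.47, 0.05, 1.0), (3.03, 0.05, 0.4)]),
    ("cho_cr", [(3.21, 0.04, 1.0), (3.03, 0.04, 0.8), (3.93, 0.05, 0.45)]),
    ("naa", [(2.02, 0.05, 1.0), (2.6, 0.07, 0.3)]),
    ("mi_tau", [(3.56, 0.05, 1.0), (3.42, 0.05, 0.6), (3.25, 0.04, 0.5)]),
    ("lip", [(1.3, 0.12, 1.0), (0.9, 0.1, 0.7), (2.05, 0.1, 0.3)]),
]

#: "normal tissue" profile used for voxels outside the tumor.
NORMAL_PEAKS: list[tuple[float, float, float]] = [
    (2.02, 0.05, 1.0),  # NAA-like
    (3.03, 0.04, 0.6),
    (3.21, 0.04, 0.5),
]


@dataclass
class GroundTruthSources:
    """K nonnegative unit-max source profiles on a shared descending ppm axis."""

    ppm_axis: np.ndarray
    profiles: np.ndarray  # (K, L)
    peak_spec: list[list[tuple[float, float, float]]]

    def __post_init__(self) -> None:
        if self.profiles.shape[0] < 2:
            raise ValueError("need K >= 2 sources")
        if (self.profiles < 0).any():
            raise ValueError("profiles must be nonnegative")
        if not np.all(np.diff(self.ppm_axis) < 0):
            raise ValueError("ppm axis must be strictly descending")

    @property
    def K(self) -> int:
        return self.profiles.shape[0]


@dataclass
class CohortSpec:
    """Configuration for a synthetic cohort.

    ``class_mixing`` maps each class to a length-K vector of Dirichlet-style
    concentrations. Entries may be exactly zero to carve out disjoint
    supports (the component then receives weight exactly 0); at least one
    entry per class must be positive.
    """

    n_control: int = 29
    n_treated: int = 34
    slices_per_subject: tuple[int, int] = (1, 4)
    grid_size: int = 10
    image_size: int = 256
    spectrum_length: int = 512
    noise_sd: float = 0.02
    class_mixing: dict[str, np.ndarray] | None = None
    holdout_fraction: float = 0.5
    focus_count: tuple[int, int] = (3, 7)  # hypointense foci per treated slice
    focus_contrast: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_treated < 1:
            raise ValueError("class counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.grid_size not in (10, 12):
            raise ValueError("grid_size must be 10 or 12")
        if self.class_mixing is not None:
            for lbl, alpha in self.class_mixing.items():
                alpha = np.asarray(alpha, dtype=float)
                if (alpha < 0).any() or not (alpha > 0).any():
                    raise ValueError(f"invalid mixing concentrations for {lbl!r}")
                self.class_mixing[lbl] = alpha


def _lorentzian(ppm: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + ((ppm - center) / width) ** 2)


def _profile_from_peaks(
    ppm: np.ndarray, peaks: list[tuple[float, float, float]]
) -> np.ndarray:
    prof = np.zeros_like(ppm)
    for center, width, amp in peaks:
        prof += amp * _lorentzian(ppm, center, width)
    m = prof.max()
    return prof / m if m > 0 else prof


def make_sources(
    K: int,
    L: int,
    ppm_range: tuple[float, float] = (0.5, 4.5),
    seed: int = 0,
) -> GroundTruthSources:
    """Build K ground-truth source profiles as sums of Lorentzian peaks.

    Peak positions come from fixed metabolite-like templates (Lac ~1.33 ppm,
    Ala ~1.47, Glx ~2.1-2.4, PUFA ~2.8, ...); the seed jitters amplitudes
    only, so the peak sets — and hence profile identities — are stable.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if L < 64:
        raise ValueError("L must be >= 64")
    if K > len(PEAK_TEMPLATES):
        raise ValueError(
            f"K={K} exceeds the {len(PEAK_TEMPLATES)} available peak templates"
        )
    rng = np.random.default_rng(seed)
    lo, hi = min(ppm_range), max(ppm_range)
    ppm = np.linspace(hi, lo, L)  # descending
    profiles = np.empty((K, L))
    peak_spec: list[list[tuple[float, float, float]]] = []
    for k in range(K):
        _, peaks = PEAK_TEMPLATES[k]
        jitter = rng.uniform(0.85, 1.15, size=len(peaks))
        peaks = [(c, w, a * j) for (c, w, a), j in zip(peaks, jitter)]
        profiles[k] = _profile_from_peaks(ppm, peaks)
        peak_spec.append(peaks)
    return GroundTruthSources(ppm_axis=ppm, profiles=profiles, peak_spec=peak_spec)


def default_class_mixing(K: int, effect: float = 6.0,
                         base: float = 0.4) -> dict[str, np.ndarray]:
    """Treated up-weights source 0 (PUFA/Lac-rich), control source 1 (Glx/Ala).

    The baseline concentration is < 1 so the Dirichlet draws are sparse and
    voxels dominated by a single tissue pattern occur — the regime a convex
    source-extraction model assumes.
    """
    treated = np.full(K, base)
    treated[0] = effect * base
    control = np.full(K, base)
    control[1 % K] = effect * base
    return {TREATED: treated, CONTROL: control}


def _draw_mixing(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet-style draw; zero concentrations yield exactly-zero weights."""
    h = np.zeros_like(alpha, dtype=float)
    pos = alpha > 0
    h[pos] = rng.dirichlet(alpha[pos])
    return h


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], radii: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _make_image(
    rng: np.random.Generator,
    spec: CohortSpec,
    mask: np.ndarray,
    label: str,
) -> np.ndarray:
    n = spec.image_size
    img = 0.35 + 0.08 * gaussian_filter(rng.standard_normal((n, n)), sigma=4)
    img[mask] += 0.35  # tumor hyperintense on T2w
    img += 0.02 * rng.standard_normal((n, n))
    if label == TREATED:
        # hypointense foci seeded inside the mask
        rs, cs = np.nonzero(mask)
        n_foci = rng.integers(spec.focus_count[0], spec.focus_count[1] + 1)
        for _ in range(n_foci):
            i = rng.integers(len(rs))
            rad = rng.uniform(0.015, 0.045) * n
            focus = _ellipse_mask(
                (n, n), (rs[i], cs[i]), (rad, rad * rng.uniform(0.6, 1.4))
            )
            img[focus & mask] -= spec.focus_contrast * rng.uniform(0.6, 1.0)
    return img.astype(np.float64)


def _make_grid(
    rng: np.random.Generator,
    spec: CohortSpec,
    sources: GroundTruthSources,
    mask: np.ndarray,
    label: str,
    mixing: dict[str, np.ndarray],
    normal_profile: np.ndarray,
) -> tuple[MRSIGrid, np.ndarray]:
    g = spec.grid_size
    n = spec.image_size
    block = n // (g + 2)
    if block < 1:
        raise ValueError("grid block exceeds image bounds")
    off = (n - g * block) // 2
    block_map = np.empty((g, g, 4), dtype=np.int64)
    for r in range(g):
        for c in range(g):
            block_map[r, c] = (
                off + r * block,
                off + (r + 1) * block,
                off + c * block,
                off + (c + 1) * block,
            )
    grid = MRSIGrid(
        dims=(g, g),
        spectra=np.zeros((g, g, sources.profiles.shape[1])),
        ppm_axis=sources.ppm_axis,
        block_map=block_map,
    )
    in_tumor = grid.in_tumor(mask)
    alpha = mixing[label]
    weights = np.zeros((g, g, sources.K))
    for r in range(g):
        for c in range(g):
            if in_tumor[r, c]:
                h = _draw_mixing(rng, alpha)
                weights[r, c] = h
                s = h @ sources.profiles
            else:
                s = rng.uniform(0.6, 1.0) * normal_profile
            if spec.noise_sd > 0:
                s = s + rng.normal(0.0, spec.noise_sd, size=s.shape)
            grid.spectra[r, c] = s
    return grid, weights


def make_cohort(
    spec: CohortSpec, sources: GroundTruthSources
) -> tuple[list[SliceRecord], dict[tuple[str, int, int, int], np.ndarray]]:
    """Generate a seeded cohort of slice records plus ground-truth mixing weights.

    Train subjects carry a single slice; holdout subjects one to four slices
    (mirroring the single-slice-train / multi-slice-holdout cohort layout).
    Returns the records and a dict keyed ``(subject, slice, row, col)`` of the
    true mixing weights of each in-tumor voxel.
    """
    rng = np.random.default_rng(spec.seed)
    mixing = spec.class_mixing or default_class_mixing(sources.K)
    for lbl in (CONTROL, TREATED):
        if len(mixing[lbl]) != sources.K:
            raise ValueError("class_mixing length must equal K")
    normal_profile = _profile_from_peaks(sources.ppm_axis, NORMAL_PEAKS)

    labels = [CONTROL] * spec.n_control + [TREATED] * spec.n_treated
    n_sub = len(labels)
    order = rng.permutation(n_sub)
    n_hold = int(round(spec.holdout_fraction * n_sub))
    splits = {}
    # stratified holdout assignment by label
    for lbl in (CONTROL, TREATED):
        idx = [i for i in order if labels[i] == lbl]
        k = int(round(len(idx) / n_sub * n_hold))
        for j, i in enumerate(idx):
            splits[i] = "holdout" if j < k else "train"

    records: list[SliceRecord] = []
    truth: dict[tuple[str, int, int, int], np.ndarray] = {}
    lo_s, hi_s = spec.slices_per_subject
    n = spec.image_size
    for i in range(n_sub):
        sid = f"S{i:03d}"
        label = labels[i]
        split = splits[i]
        n_slices = 1 if split == "train" else int(rng.integers(lo_s, hi_s + 1))
        for s in range(n_slices):
            center = (n / 2 + rng.uniform(-0.04, 0.04) * n,
                      n / 2 + rng.uniform(-0.04, 0.04) * n)
            radii = (rng.uniform(0.22, 0.34) * n, rng.uniform(0.22, 0.34) * n)
            mask = _ellipse_mask((n, n), center, radii)
            img = _make_image(rng, spec, mask, label)
            grid, w = _make_grid(rng, spec, sources, mask, label, mixing, normal_profile)
            rec = SliceRecord(
                subject_id=sid, slice_index=s, label=label,
                image=img, mask=mask, grid=grid, split=split,
            )
            records.append(rec)
            in_t = grid.in_tumor(mask)
            for r in range(grid.dims[0]):
                for c in range(grid.dims[1]):
                    if in_t[r, c]:
                        truth[(sid, s, r, c)] = w[r, c]
    return records, truth


def save_cohort(records: list[SliceRecord],
                truth: dict[tuple[str, int, int, int], np.ndarray],
                outdir: str | Path) -> None:
    """Write a cohort to disk as plain-text CSV/JSON artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "slice_index", "label", "split"])
        for rec in records:
            w.writerow([rec.subject_id, rec.slice_index, rec.label, rec.split])
    for rec in records:
        stem = f"{rec.subject_id}_s{rec.slice_index}"
        np.savetxt(outdir / f"{stem}_image.csv", rec.image, delimiter=",")
        np.savetxt(outdir / f"{stem}_mask.csv", rec.mask.astype(int),
                   delimiter=",", fmt="%d")
        if rec.grid is not None:
            g = rec.grid
            rows = []
            for r in range(g.dims[0]):
                for c in range(g.dims[1]):
                    rows.append([r, c, *g.spectra[r, c]])
            np.savetxt(outdir / f"{stem}_spectra.csv", np.array(rows), delimiter=",")
            np.savetxt(outdir / f"{stem}_ppm.csv", g.ppm_axis, delimiter=",")
            np.savetxt(outdir / f"{stem}_blocks.csv",
                       g.block_map.reshape(-1, 4), delimiter=",", fmt="%d")
    with open(outdir / "ground_truth_weights.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        first = next(iter(truth.values())) if truth else np.zeros(0)
        w.writerow(["subject_id", "slice_index", "row", "col"]
                   + [f"w{k}" for k in range(len(first))])
        for (sid, s, r, c), h in truth.items():
            w.writerow([sid, s, r, c, *h])
    meta = {"n_records": len(records), "n_truth_voxels": len(truth)}
    (outdir / "cohort_meta.json").write_text(json.dumps(meta, indent=2))
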