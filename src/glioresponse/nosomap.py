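"""Per-voxel classification certainty and nosological map rendering.

Certainty is the posterior probability of the predicted label. When the
training scores of the two classes are separable the posterior of the
positive class follows the piecewise rule

    P(s) = 0        if s <  max{s_k : y_k = -1}
    P(s) = pi       if max{s_k : y_k = -1} <= s <= min{s_k : y_k = +1}
    P(s) = 1        if s >  min{s_k : y_k = +1}

with ``pi`` the prior probability of the positive class. When the training
scores overlap the middle band is ill-defined and a Platt-style sigmoid
fitted on the training scores is used instead; both paths are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from glioresponse.datatypes import SliceRecord


@dataclass
class ScoreCalibration:
    """Training decision scores split by true class, plus the class prior."""

    neg_scores: np.ndarray
    pos_scores: np.ndarray
    prior: float
    _platt: LogisticRegression | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.neg_scores = np.asarray(self.neg_scores, dtype=float)
        self.pos_scores = np.asarray(self.pos_scores, dtype=float)
        if self.neg_scores.size == 0 or self.pos_scores.size == 0:
            raise ValueError("calibration requires scores from both classes")
        if not 0.0 <= self.prior <= 1.0:
            raise ValueError("prior must be in [0, 1]")
        if not self.separable:
            s = np.concatenate([self.neg_scores, self.pos_scores])
            y = np.concatenate(
                [np.zeros_like(self.neg_scores), np.ones_like(self.pos_scores)]
            )
            self._platt = LogisticRegression(C=1e6, max_iter=5000)
            self._platt.fit(s.reshape(-1, 1), y)

    @classmethod
    def from_scores(cls, scores: np.ndarray, y: np.ndarray,
                    prior: float | None = None) -> "ScoreCalibration":
        scores = np.asarray(scores, dtype=float)
        y = np.asarray(y)
        pos = scores[y > 0]
        neg = scores[y <= 0]
        if prior is None:
            prior = float(np.mean(y > 0))
        return cls(neg_scores=neg, pos_scores=pos, prior=prior)

    @property
    def separable(self) -> bool:
        return float(self.neg_scores.max()) < float(self.pos_scores.min())


def posterior(s, calibration: ScoreCalibration) -> np.ndarray | float:
    """Posterior probability of the positive class at score(s) ``s``."""
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if calibration.separable:
        lo = float(calibration.neg_scores.max())
        hi = float(calibration.pos_scores.min())
        out = np.where(s_arr < lo, 0.0,
                       np.where(s_arr > hi, 1.0, calibration.prior))
    else:
        out = calibration._platt.predict_proba(s_arr.reshape(-1, 1))[:, 1]
    return out if np.ndim(s) else float(out[0])


def certainty(s, predicted: np.ndarray | int,
              calibration: ScoreCalibration) -> np.ndarray | float:
    """Posterior of the *predicted* label: P if predicted +1, else 1 - P."""
    p = posterior(s, calibration)
    return np.where(np.asarray(predicted) > 0, p, 1.0 - p) if np.ndim(s) \
        else (p if predicted > 0 else 1.0 - p)


@dataclass
class NosologicalMap:
    """Per-voxel predictions, certainties and rendering metadata for a slice."""

    subject_id: str
    slice_index: int
    dims: tuple[int, int]
    voxels: list[tuple[int, int]]        # in-tumor voxel (row, col)
    predicted: np.ndarray                # signed label per voxel
    P: np.ndarray                        # certainty of the predicted label
    correct: np.ndarray                  # predicted == subject truth
    true_label: int
    pct_treated: float
    pct_control: float
    block_map: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.voxels)
        if not (len(self.predicted) == len(self.P) == len(self.correct) == n):
            raise ValueError("per-voxel array length mismatch")
        if n and not np.isclose(self.pct_treated + self.pct_control, 100.0):
            raise ValueError("class percentages must sum to 100")


def build_map(record: SliceRecord, voxel_scores: dict[tuple[int, int], float],
              calibration: ScoreCalibration) -> NosologicalMap:
    """Assemble the map for one slice from its in-tumor voxel decision scores."""
    if record.grid is None:
        raise ValueError("slice has no grid")
    voxels = sorted(voxel_scores)
    for r, c in voxels:
        if not (0 <= r < record.grid.dims[0] and 0 <= c < record.grid.dims[1]):
            raise ValueError(f"voxel {(r, c)} outside grid dims {record.grid.dims}")
    s = np.array([voxel_scores[v] for v in voxels], dtype=float)
    predicted = np.where(s >= 0, 1, -1)
    P = np.atleast_1d(certainty(s, predicted, calibration))
    n = len(voxels)
    n_treated = int((predicted > 0).sum())
    return NosologicalMap(
        subject_id=record.subject_id,
        slice_index=record.slice_index,
        dims=record.grid.dims,
        voxels=voxels,
        predicted=predicted,
        P=P,
        correct=predicted == record.y,
        true_label=record.y,
        pct_treated=100.0 * n_treated / n if n else 0.0,
        pct_control=100.0 * (n - n_treated) / n if n else 0.0,
        block_map=record.grid.block_map,
    )


def render_map(nmap: NosologicalMap, background: np.ndarray, path,
               cmap: str = "viridis") -> None:
    """Render the map over the anatomical image and save it as PNG.

    In-tumor voxel blocks are tinted by certainty (lighter = more reliable),
    misclassified voxels get a red contour, the bottom bar shows the true
    class and the top bar the treated/control voxel percentages.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors, patches

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(background, cmap="gray", interpolation="nearest")
    norm = colors.Normalize(vmin=0.0, vmax=1.0)
    mapper = cm.ScalarMappable(norm=norm, cmap=cmap)
    for (r, c), p, ok in zip(nmap.voxels, nmap.P, nmap.correct):
        r0, r1, c0, c1 = nmap.block_map[r, c]
        ax.add_patch(patches.Rectangle(
            (c0 - 0.5, r0 - 0.5), c1 - c0, r1 - r0,
            facecolor=mapper.to_rgba(p), alpha=0.6, edgecolor="none",
        ))
        if not ok:
            ax.add_patch(patches.Rectangle(
                (c0 - 0.5, r0 - 0.5), c1 - c0, r1 - r0,
                facecolor="none", edgecolor="red", linewidth=2.0,
            ))
    h, w = background.shape
    bar = 0.03 * h
    true_color = "tab:orange" if nmap.true_label > 0 else "tab:blue"
    ax.add_patch(patches.Rectangle((0, h), w, bar, facecolor=true_color,
                                   clip_on=False))
    split = w * nmap.pct_treated / 100.0
    ax.add_patch(patches.Rectangle((0, -bar), split, bar,
                                   facecolor="tab:orange", clip_on=False))
    ax.add_patch(patches.Rectangle((split, -bar), w - split, bar,
                                   facecolor="tab:blue", clip_on=False))
    fig.colorbar(mapper, ax=ax, label="certainty of predicted label")
    ax.set_title(f"{nmap.subject_id} slice {nmap.slice_index}")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def map_to_records(nmap: NosologicalMap) -> list[dict]:
    """Flatten the map for CSV/JSON export."""
    return [
        {
            "subject_id": nmap.subject_id,
            "slice_index": nmap.slice_index,
            "row": r,
            "col": c,
            "predicted": int(pred),
            "P": float(p),
            "correct": bool(ok),
        }
        for (r, c), pred, p, ok in zip(
            nmap.voxels, nmap.predicted, nmap.P, nmap.correct
        )
    ]
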