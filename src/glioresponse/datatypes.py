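"""Core data containers shared by the radiomics and MRSI pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Global label encoding: control is the negative class, treated the positive.
CONTROL, TREATED = "control", "treated"
LABEL_CODE = {CONTROL: -1, TREATED: +1}
CODE_LABEL = {v: k for k, v in LABEL_CODE.items()}


@dataclass
class MRSIGrid:
    """A rows x cols grid of voxel spectra registered onto an image.

    Parameters
    ----------
    dims
        Grid shape ``(rows, cols)``.
    spectra
        Array of shape ``(rows, cols, L)`` of real-valued spectra.
    ppm_axis
        Shared chemical-shift axis of length L, strictly descending.
    block_map
        Array of shape ``(rows, cols, 4)`` holding half-open pixel
        rectangles ``(r0, r1, c0, c1)`` — the image block each voxel covers.
    """

    dims: tuple[int, int]
    spectra: np.ndarray
    ppm_axis: np.ndarray
    block_map: np.ndarray

    def __post_init__(self) -> None:
        rows, cols = self.dims
        if self.spectra.shape[:2] != (rows, cols):
            raise ValueError("spectra shape does not match grid dims")
        if self.block_map.shape != (rows, cols, 4):
            raise ValueError("block_map shape must be (rows, cols, 4)")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("grid spectra contain non-finite values")
        if not np.all(np.diff(self.ppm_axis) < 0):
            raise ValueError("ppm axis must be strictly descending")

    def in_tumor(self, mask: np.ndarray) -> np.ndarray:
        """Boolean (rows, cols): voxel's full pixel block lies inside ``mask``."""
        rows, cols = self.dims
        out = np.zeros((rows, cols), dtype=bool)
        for r in range(rows):
            for c in range(cols):
                r0, r1, c0, c1 = self.block_map[r, c]
                out[r, c] = bool(mask[r0:r1, c0:c1].all())
        return out


@dataclass
class SliceRecord:
    """One image + tumor mask (+ optional MRSI grid) of one subject."""

    subject_id: str
    slice_index: int
    label: str
    image: np.ndarray
    mask: np.ndarray
    grid: MRSIGrid | None = None
    split: str = "train"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABEL_CODE:
            raise ValueError(f"unknown label {self.label!r}")
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        self.mask = self.mask.astype(bool)
        if not self.mask.any():
            raise ValueError(
                f"empty tumor mask for subject {self.subject_id} "
                f"slice {self.slice_index}"
            )
        if self.grid is not None:
            bm = self.grid.block_map
            if bm[..., 1].max() > self.image.shape[0] or bm[..., 3].max() > self.image.shape[1]:
                raise ValueError("grid block exceeds image bounds")

    @property
    def y(self) -> int:
        """Signed class code (-1 control, +1 treated)."""
        return LABEL_CODE[self.label]
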