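"""Threshold-based lung segmentation and mask-agreement metrics.

Aerated lung sits far below soft tissue on the HU scale; a threshold in
[-400, -200] HU captures normal parenchyma and most fibrotic lung.  The
threshold is exposed as a parameter (in practice it is adjusted per subject
to include fibrosis) — there is no auto-tuning rule here.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, Volume3D

__all__ = ["SegmentationParams", "segment_lung", "dice", "mask_volume"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclasses.dataclass
class SegmentationParams:
    lower_hu: float = -1024.0
    upper_hu: float = -200.0
    keep_components: int = 2
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.lower_hu >= self.upper_hu:
            raise ValueError("lower_hu must be below upper_hu")
        if self.keep_components < 1:
            raise ValueError("keep_components must be >= 1")


def segment_lung(v: Volume3D, p: SegmentationParams | None = None) -> BinaryMask:
    """Threshold to [lower_hu, upper_hu], keep the largest 26-connected
    components, close and fill holes (tubes and vessels inside the lung)."""
    if p is None:
        p = SegmentationParams()
    raw = (v.values >= p.lower_hu) & (v.values <= p.upper_hu)
    if not raw.any():
        raise ValueError("empty segmentation: no voxels inside the HU window")
    labels, n = ndimage.label(raw, structure=_STRUCT_26)
    if n > p.keep_components:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = np.argsort(counts)[::-1][: p.keep_components]
        raw = np.isin(labels, keep)
    if p.fill_holes:
        raw = ndimage.binary_closing(raw, structure=ndimage.generate_binary_structure(3, 1))
        raw = ndimage.binary_fill_holes(raw)
    return BinaryMask(raw, spacing=v.spacing, origin=v.origin)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A.B| / (|A|+|B|); 1.0 when both empty."""
    if not a.same_grid(b):
        raise ValueError("dice requires masks on the same grid")
    na, nb = a.n_foreground, b.n_foreground
    if na + nb == 0:
        return 1.0  # both-empty convention: perfect agreement
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


def mask_volume(m: BinaryMask) -> float:
    """Foreground volume in cm^3 (voxel count x voxel volume)."""
    voxel_mm3 = float(np.prod(m.spacing))
    return m.n_foreground * voxel_mm3 / 1000.0
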