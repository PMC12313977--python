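"""Mean gray-matter value within a binary region-of-interest mask.

A modulated gray-matter map and a binary mask must live on the identical
voxel grid (same shape, same affine); no resampling or registration is
performed here — upstream spatial normalisation is assumed.  The output is
the arithmetic mean of the map over mask voxels, a scalar suitable as a
per-subject mediator (e.g. ventral-striatum gray-matter volume).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

AFFINE_ATOL = 1e-4


class ROIError(ValueError):
    pass


@dataclass(frozen=True)
class VolumePair:
    gmv_map: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.gmv_map.ndim != 3 or self.mask.ndim != 3:
            raise ROIError("map and mask must be 3-D volumes")
        if self.gmv_map.shape != self.mask.shape:
            raise ROIError(
                f"grid mismatch: map {self.gmv_map.shape} vs mask "
                f"{self.mask.shape}"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ROIError(f"mask must be binary, found values {vals[:5]}")
        if not self.mask.any():
            raise ROIError("mask is empty")


def load_volume_pair(map_path: str | Path, mask_path: str | Path) -> VolumePair:
    """Load a NIfTI map/mask pair, checking shape and affine agreement."""
    img = nib.load(str(map_path))
    msk = nib.load(str(mask_path))
    if img.shape != msk.shape:
        raise ROIError(f"grid mismatch: map {img.shape} vs mask {msk.shape}")
    if not np.allclose(img.affine, msk.affine, atol=AFFINE_ATOL):
        raise ROIError("map and mask affines differ; no silent resampling")
    return VolumePair(
        gmv_map=np.asarray(img.get_fdata(), dtype=float),
        mask=np.asarray(msk.get_fdata()),
        affine=np.asarray(img.affine),
    )


def roi_mean(pair: VolumePair) -> float:
    """Arithmetic mean of the map over voxels where mask == 1."""
    return float(pair.gmv_map[pair.mask.astype(bool)].mean())
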