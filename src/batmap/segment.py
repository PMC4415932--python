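"""VOI segmentation on quantitative maps.

Crude (manually drawn or simulated) cervical-supraclavicular masks are
refined by inclusive thresholds — keep voxels with FF >= 40 % (removes
non-fatty tissue) and R2* <= 50 s^-1 (removes partial-volume boundary
voxels) — followed by one pass of 3D binary erosion with the
six-neighbourhood (face-connected) structuring element.  Posterior
subcutaneous fat (SAT) is segmented fully automatically, per axial
slice, as the fat-passing connected component touching the posterior
body surface within a shallow depth band, then eroded the same way.

Grids are (x, y, z) with posterior = +y (the anterior-posterior axis is
axis 1 by the package's axis convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .recon import QuantitativeMaps

FF_MIN_DEFAULT = 0.40
R2S_MAX_DEFAULT = 50.0  # s^-1, i.e. T2* >= 20 ms


@dataclass
class VoiMask:
    """A binary volume of interest with provenance."""

    mask: np.ndarray
    provenance: str  # crude_manual | refined_sbat | auto_sat | registered
    source_state: str = ""
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D binary volume")
        if not self.mask.any():
            self.flagged_empty = True

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class VoiSummary:
    mean_ff: float  # percent
    sd_ff: float  # percent
    mean_r2s: float  # s^-1
    sd_r2s: float
    voxel_count: int
    volume_ml: float


_STRUCT_6N = ndimage.generate_binary_structure(3, 1)


def erode_6n(mask) -> np.ndarray:
    """3D erosion with the six-neighbourhood structuring element.

    A voxel survives iff it and all six face neighbours are in the input;
    grid borders count as out-of-mask neighbours, so the outer shell of a
    full-grid mask is always removed.
    """
    m = mask.mask if isinstance(mask, VoiMask) else np.asarray(mask).astype(bool)
    return ndimage.binary_erosion(m, structure=_STRUCT_6N, border_value=0)


def _as_mask_array(crude) -> np.ndarray:
    return crude.mask if isinstance(crude, VoiMask) else np.asarray(crude).astype(bool)


def refine_voi(
    crude,
    maps: QuantitativeMaps,
    ff_min: float = FF_MIN_DEFAULT,
    r2s_max: float = R2S_MAX_DEFAULT,
    source_state: str = "",
) -> VoiMask:
    """Refine a crude VOI by inclusive FF/R2* thresholds plus one erosion.

    Keeps crude voxels with FF >= ff_min and R2* <= r2s_max (both
    inclusive), then applies one pass of :func:`erode_6n`.  An empty
    result is permitted but flagged.
    """
    crude_mask = _as_mask_array(crude)
    if crude_mask.shape != maps.ff.shape:
        raise ValueError(
            f"crude mask grid {crude_mask.shape} does not match maps grid {maps.ff.shape}"
        )
    kept = crude_mask & (maps.ff >= ff_min) & (maps.r2s <= r2s_max)
    return VoiMask(
        mask=erode_6n(kept), provenance="refined_sbat", source_state=source_state
    )


def _body_mask(maps: QuantitativeMaps) -> np.ndarray:
    total = maps.water + maps.fat
    vals = total.ravel()
    if np.ptp(vals) <= 0:
        return np.zeros_like(total, dtype=bool)
    thr = threshold_otsu(vals)
    return total > thr


def segment_posterior_sat(
    maps: QuantitativeMaps,
    ff_min: float = FF_MIN_DEFAULT,
    r2s_max: float = R2S_MAX_DEFAULT,
    depth_mm: float = 10.0,
    source_state: str = "",
) -> VoiMask:
    """Fully automatic posterior subcutaneous fat VOI.

    The body is masked by Otsu thresholding of W+F.  In each axial slice
    the fat-passing (FF >= ff_min, R2* <= r2s_max) connected components
    touching the posterior skin are kept, restricted to voxels within
    ``depth_mm`` of the posterior body surface; the union over slices is
    eroded once with the six-neighbourhood element.  Deterministic; an
    empty result is flagged.
    """
    body = _body_mask(maps)
    fat_ok = body & (maps.ff >= ff_min) & (maps.r2s <= r2s_max)
    nx, ny, nz = maps.ff.shape
    vy = maps.voxel_size[1]
    out = np.zeros_like(body)
    ys = np.arange(ny)
    for k in range(nz):
        body2d = body[:, :, k]
        if not body2d.any():
            continue
        # posterior skin height per right-left column (posterior = +y)
        has_body = body2d.any(axis=1)
        y_skin = np.where(has_body, ny - 1 - np.argmax(body2d[:, ::-1], axis=1), -1)
        depth_vox = depth_mm / vy
        band = (
            has_body[:, None]
            & (ys[None, :] <= y_skin[:, None])
            & ((y_skin[:, None] - ys[None, :]) <= depth_vox)
        )
        fat2d = fat_ok[:, :, k]
        labels, n = ndimage.label(fat2d, structure=np.ones((3, 3), bool))
        if n == 0:
            continue
        skin_layer = has_body[:, None] & (ys[None, :] == y_skin[:, None])
        touching = np.unique(labels[skin_layer & fat2d])
        touching = touching[touching > 0]
        if touching.size == 0:
            continue
        keep = np.isin(labels, touching) & band
        out[:, :, k] = keep
    return VoiMask(mask=erode_6n(out), provenance="auto_sat", source_state=source_state)


def voi_statistics(mask, maps: QuantitativeMaps) -> VoiSummary:
    """Arithmetic mean/SD of FF (percent) and R2* over the VOI.

    SDs are population SDs over the masked voxels (a single-voxel VOI has
    SD 0).  Volume is voxel count times the voxel volume.
    """
    m = _as_mask_array(mask)
    if m.shape != maps.ff.shape:
        raise ValueError("mask and maps grids differ")
    if not m.any():
        raise ValueError("cannot summarise an empty VOI")
    ff = maps.ff[m]
    r2s = maps.r2s[m]
    voxel_ml = float(np.prod(maps.voxel_size)) / 1000.0
    return VoiSummary(
        mean_ff=float(100.0 * ff.mean()),
        sd_ff=float(100.0 * ff.std(ddof=0)),
        mean_r2s=float(r2s.mean()),
        sd_r2s=float(r2s.std(ddof=0)),
        voxel_count=int(m.sum()),
        volume_ml=float(m.sum()) * voxel_ml,
    )
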