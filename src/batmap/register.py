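"""Rigid alignment of FF maps across scan states and VOI transfer.

Volumes are numpy arrays indexed (x, y, z); physical coordinates are
index * voxel_size (mm) with a zero origin and identity orientation.

A :class:`RigidTransform` maps physical points of the *fixed* image's
space into the *moving* image's space (the resampling convention):

    p_moving = R (p_fixed - c) + c + t

with rotation matrix R (extrinsic x-y-z Euler angles, degrees),
rotation centre c and translation t in mm.  Registration itself is done
with SimpleITK: normalised cross-correlation metric, multi-resolution,
regular-step gradient descent, dense (all-voxel) sampling so results are
deterministic given the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import SimpleITK as sitk
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    rotation_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        translation_mm,
        center_mm=(0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        angles = Rotation.from_matrix(np.asarray(matrix)).as_euler("xyz", degrees=True)
        return cls(
            rotation_deg=tuple(float(a) for a in angles),
            translation_mm=tuple(float(t) for t in translation_mm),
            center_mm=tuple(float(c) for c in center_mm),
        )

    def apply_points(self, points_mm: np.ndarray) -> np.ndarray:
        """Transform an (..., 3) array of physical points."""
        p = np.asarray(points_mm, dtype=float)
        c = np.array(self.center_mm)
        t = np.array(self.translation_mm)
        return (p - c) @ self.matrix.T + c + t

    def inverse(self) -> "RigidTransform":
        m = self.matrix
        t = np.array(self.translation_mm)
        return RigidTransform.from_matrix(m.T, -(m.T @ t), self.center_mm)

    @property
    def is_identity(self) -> bool:
        return (
            np.allclose(self.rotation_deg, 0.0, atol=1e-12)
            and np.allclose(self.translation_mm, 0.0, atol=1e-12)
        )

    def to_dict(self) -> dict:
        return {
            "rotation_deg": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation_deg=tuple(d["rotation_deg"]),
            translation_mm=tuple(d["translation_mm"]),
            center_mm=tuple(d["center_mm"]),
        )


def _to_sitk(vol: np.ndarray, voxel_size) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.T, dtype=np.float64))
    img.SetSpacing(tuple(float(v) for v in voxel_size))
    return img


def register_rigid(
    fixed_ff: np.ndarray,
    moving_ff: np.ndarray,
    voxel_size=(1.0, 1.0, 2.0),
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving_ff`` to ``fixed_ff``.

    The returned transform maps fixed-space points into moving space, so
    :func:`transfer_voi` with it resamples a mask living on the moving
    grid onto the fixed grid.  FF maps are the registration channel: they
    are quantitative, so normalised cross-correlation is robust to the
    small global FF shifts between states.
    """
    for name, vol in (("fixed", fixed_ff), ("moving", moving_ff)):
        if float(np.ptp(vol)) < 1e-12:
            raise ValueError(f"{name} image is constant; registration is degenerate")

    fimg = _to_sitk(fixed_ff, voxel_size)
    mimg = _to_sitk(moving_ff, voxel_size)

    initial = sitk.CenteredTransformInitializer(
        fimg,
        mimg,
        sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense sampling: deterministic
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=150,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=False)

    result = reg.Execute(fimg, mimg)
    if hasattr(result, "Downcast"):
        result = result.Downcast()
    if isinstance(result, sitk.CompositeTransform):
        result = result.GetNthTransform(0)
        if hasattr(result, "Downcast"):
            result = result.Downcast()
    final = sitk.Euler3DTransform(result)
    matrix = np.array(final.GetMatrix()).reshape(3, 3)
    return RigidTransform.from_matrix(matrix, final.GetTranslation(), final.GetCenter())


def transfer_voi(
    mask: np.ndarray,
    transform: RigidTransform,
    output_shape: Optional[Tuple[int, int, int]] = None,
    voxel_size=(1.0, 1.0, 2.0),
) -> np.ndarray:
    """Resample a binary mask through a rigid transform (nearest neighbour).

    ``mask`` lives on the transform's moving grid; the result lives on the
    fixed grid of shape ``output_shape`` (default: same shape).  Voxels
    mapping outside the source grid are dropped, so masks straddling the
    grid border shrink — mirroring the slightly smaller registered VOIs
    seen when scan coverage differs between states.
    """
    mask = np.asarray(mask).astype(bool)
    shape = output_shape or mask.shape
    vs = np.array(voxel_size, dtype=float)
    idx = np.stack(
        np.meshgrid(*(np.arange(n) for n in shape), indexing="ij"), axis=-1
    ).astype(float)
    src = transform.apply_points(idx * vs) / vs
    nearest = np.round(src).astype(int)
    inside = np.all(
        (nearest >= 0) & (nearest < np.array(mask.shape)), axis=-1
    )
    out = np.zeros(shape, dtype=bool)
    valid = nearest[inside]
    out[inside] = mask[valid[:, 0], valid[:, 1], valid[:, 2]]
    return out
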