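"""Rigid CT-to-CT registration and resampling.

Both PET sessions come with a low-dose CT that shares the session's frame of
reference, so inter-session alignment is driven entirely by the two CTs.
Alignment is two-step: a global skeletal rigid registration followed by a
per-lesion rigid refinement restricted to a world-aligned box around the
lesion.  The similarity metric is mean squared HU difference evaluated on
bone voxels (HU above a threshold); both scans are CT of the same subject so
a mono-modal metric suffices.  Optimization is multi-resolution gradient
descent with deterministic initialization, so results are reproducible for
identical inputs.

Transform convention: SimpleITK / ITK resampling convention, i.e. the
transform maps points of the *fixed* (reference) frame into the *moving*
frame.  ``resample(moving, T, reference)`` therefore pulls moving-image
values onto the reference grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk

from .volume_io import Volume

__all__ = [
    "RigidTransform",
    "LesionBox",
    "RegistrationError",
    "register_global",
    "register_local",
    "resample",
    "volume_to_sitk",
    "sitk_to_volume",
]

DEFAULT_BONE_HU = 100.0
MIN_BONE_VOXELS = 50


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """A rigid (6-DOF) transform: Euler angles (deg), translation and center in mm.

    The identity transform has all-zero parameters.  Angle convention follows
    ITK's Euler3DTransform (rotations about the fixed x, y, z world axes).
    The mapping is ``x' = R (x - c) + c + t``.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    # -- conversions -------------------------------------------------------
    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter([float(c) for c in self.center_mm])
        t.SetRotation(*(np.deg2rad(self.rotation_deg)))
        t.SetTranslation([float(v) for v in self.translation_mm])
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "RigidTransform":
        if not isinstance(t, sitk.Euler3DTransform):
            t = sitk.Euler3DTransform(t)
        ax, ay, az, tx, ty, tz = t.GetParameters()
        cx, cy, cz = t.GetFixedParameters()[:3]
        return cls(
            rotation_deg=tuple(np.rad2deg([ax, ay, az])),
            translation_mm=(tx, ty, tz),
            center_mm=(cx, cy, cz),
        )

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix acting on world points."""
        t = self.to_sitk()
        R = np.array(t.GetMatrix()).reshape(3, 3)
        c = np.array(self.center_mm)
        tr = np.array(self.translation_mm)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + tr - R @ c
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        t = sitk.Euler3DTransform()
        t.SetCenter([0.0, 0.0, 0.0])
        t.SetMatrix([float(v) for v in np.asarray(M)[:3, :3].ravel()])
        t.SetTranslation([float(v) for v in np.asarray(M)[:3, 3]])
        return cls.from_sitk(t)

    # -- algebra -----------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform.from_matrix(self.as_matrix() @ other.as_matrix())

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.as_matrix()))

    def apply_to_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        M = self.as_matrix()
        out = pts @ M[:3, :3].T + M[:3, 3]
        return out[0] if out.shape[0] == 1 else out

    # -- magnitudes --------------------------------------------------------
    def rotation_magnitude_deg(self) -> float:
        R = self.as_matrix()[:3, :3]
        c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.rad2deg(np.arccos(c)))

    def translation_error_at(self, pts: np.ndarray) -> float:
        """Max displacement (mm) of ``pts`` under this transform; used to
        measure how far a recovered transform is from a ground-truth one
        after composing with its inverse."""
        mapped = self.apply_to_points(pts)
        return float(np.max(np.linalg.norm(np.atleast_2d(mapped) - np.atleast_2d(pts), axis=1)))

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "rotation_deg": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
            "convention": "itk-euler3d-fixed-xyz",
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RigidTransform":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            rotation_deg=tuple(d["rotation_deg"]),
            translation_mm=tuple(d["translation_mm"]),
            center_mm=tuple(d["center_mm"]),
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


@dataclass(frozen=True)
class LesionBox:
    """World-aligned bounding box around one lesion (mm)."""

    min_mm: tuple[float, float, float]
    max_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.min_mm), np.asarray(self.max_mm)
        if not np.all(lo < hi):
            raise ValueError("box min must be strictly below max on every axis")

    @classmethod
    def from_seed(
        cls,
        seed_world: Sequence[float],
        radius_mm: float = 10.0,
        margin_mm: float = 15.0,
    ) -> "LesionBox":
        if margin_mm < 0:
            raise ValueError("margin must be non-negative")
        seed = np.asarray(seed_world, dtype=float)
        half = radius_mm + margin_mm
        return cls(tuple(seed - half), tuple(seed + half))

    def index_slices(self, vol: Volume) -> tuple[slice, slice, slice]:
        """Voxel-index slices of ``vol`` covered by the box (clipped)."""
        corners = np.array(
            [
                [x, y, z]
                for x in (self.min_mm[0], self.max_mm[0])
                for y in (self.min_mm[1], self.max_mm[1])
                for z in (self.min_mm[2], self.max_mm[2])
            ]
        )
        idx = vol.world_to_voxel(corners)
        lo = np.clip(np.floor(idx.min(axis=0)).astype(int), 0, None)
        hi = np.minimum(np.ceil(idx.max(axis=0)).astype(int) + 1, vol.shape)
        if np.any(lo >= hi):
            raise RegistrationError("lesion box does not intersect the volume")
        return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))  # type: ignore[return-value]

    def mask(self, vol: Volume) -> np.ndarray:
        m = np.zeros(vol.shape, dtype=bool)
        m[self.index_slices(vol)] = True
        return m

    def center(self) -> np.ndarray:
        return (np.asarray(self.min_mm) + np.asarray(self.max_mm)) / 2.0


# ---------------------------------------------------------------------------
# SimpleITK conversion
# ---------------------------------------------------------------------------

def volume_to_sitk(vol: Volume) -> sitk.Image:
    spacing = vol.spacing
    direction = vol.affine[:3, :3] / spacing[np.newaxis, :]
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0)), dtype=np.float64))
    img.SetSpacing([float(s) for s in spacing])
    img.SetOrigin([float(o) for o in vol.affine[:3, 3]])
    img.SetDirection([float(v) for v in direction.ravel()])
    return img


def sitk_to_volume(img: sitk.Image, modality: str = "SUV") -> Volume:
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    spacing = np.array(img.GetSpacing())
    direction = np.array(img.GetDirection()).reshape(3, 3)
    affine = np.eye(4)
    affine[:3, :3] = direction * spacing[np.newaxis, :]
    affine[:3, 3] = img.GetOrigin()
    return Volume(data, affine, modality)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def _geometric_center(vol: Volume) -> np.ndarray:
    return np.asarray(vol.voxel_to_world((np.array(vol.shape, dtype=float) - 1) / 2.0))


def _run_registration(
    fixed: sitk.Image,
    moving: sitk.Image,
    fixed_mask: sitk.Image,
    init: sitk.Euler3DTransform,
    shrink_factors: Sequence[int],
    smoothing_sigmas_mm: Sequence[float],
    iterations: int,
) -> sitk.Euler3DTransform:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricFixedMask(fixed_mask)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetMetricSamplingStrategy(reg.NONE)  # all voxels: deterministic
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0,
        minStep=1e-5,
        numberOfIterations=iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-7,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([int(s) for s in shrink_factors])
    reg.SetSmoothingSigmasPerLevel([float(s) for s in smoothing_sigmas_mm])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(init, inPlace=False)
    out = reg.Execute(fixed, moving)
    if isinstance(out, sitk.CompositeTransform):
        out = out.GetNthTransform(0)
    out = out.Downcast() if hasattr(out, "Downcast") else out
    return sitk.Euler3DTransform(out)


def register_global(
    fixed_ct: Volume,
    moving_ct: Volume,
    bone_hu: float = DEFAULT_BONE_HU,
    iterations: int = 150,
    shrink_factors: Sequence[int] = (4, 2, 1),
    smoothing_sigmas_mm: Sequence[float] = (4.0, 2.0, 0.0),
) -> RigidTransform:
    """Global skeletal rigid alignment of two CT volumes.

    Minimizes mean squared HU difference over fixed-image voxels with
    HU > ``bone_hu`` (skeleton-weighted), multi-resolution, initialized at
    the identity (geometric-center aligned).  Raises
    :class:`RegistrationError` when too few bone voxels are present.
    """
    if fixed_ct.modality != "HU" or moving_ct.modality != "HU":
        raise ValueError("registration expects HU volumes")
    bone = fixed_ct.data > bone_hu
    if int(bone.sum()) < MIN_BONE_VOXELS:
        raise RegistrationError(
            f"insufficient bone voxels in fixed CT ({int(bone.sum())} < {MIN_BONE_VOXELS})"
        )
    f_img = volume_to_sitk(fixed_ct)
    m_img = volume_to_sitk(moving_ct)
    mask = sitk.Cast(volume_to_sitk(Volume(bone.astype(np.float64), fixed_ct.affine, "HU")), sitk.sitkUInt8)

    init = sitk.Euler3DTransform()
    init.SetCenter([float(c) for c in _geometric_center(fixed_ct)])
    result = _run_registration(
        f_img, m_img, mask, init, shrink_factors, smoothing_sigmas_mm, iterations
    )
    return RigidTransform.from_sitk(result)


def register_local(
    fixed_ct: Volume,
    moving_ct: Volume,
    box: LesionBox,
    init: RigidTransform,
    bone_hu: float = DEFAULT_BONE_HU,
    iterations: int = 120,
    min_bone_voxels: int = 20,
) -> RigidTransform:
    """Per-lesion rigid refinement restricted to ``box``.

    The metric is evaluated only on bone voxels of the fixed CT inside the
    box; the optimization starts from the global transform.
    """
    sl = box.index_slices(fixed_ct)
    box_mask = np.zeros(fixed_ct.shape, dtype=bool)
    box_mask[sl] = True
    bone = box_mask & (fixed_ct.data > bone_hu)
    if int(bone.sum()) < min_bone_voxels:
        raise RegistrationError(
            f"lesion box contains too few bone voxels ({int(bone.sum())})"
        )
    f_img = volume_to_sitk(fixed_ct)
    m_img = volume_to_sitk(moving_ct)
    mask = sitk.Cast(volume_to_sitk(Volume(bone.astype(np.float64), fixed_ct.affine, "HU")), sitk.sitkUInt8)

    result = _run_registration(
        f_img, m_img, mask, init.to_sitk(), (2, 1), (2.0, 0.0), iterations
    )
    return RigidTransform.from_sitk(result)


def resample(
    vol: Volume,
    transform: RigidTransform,
    reference: Volume,
    interpolation: str = "linear",
    fill_value: float = 0.0,
) -> Volume:
    """Resample ``vol`` onto the grid of ``reference`` through ``transform``.

    ``transform`` maps reference-frame points into the frame of ``vol``
    (ITK resampling convention).  Linear interpolation for intensities,
    nearest for masks/labels; out-of-field voxels take ``fill_value``.
    """
    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}.get(
        interpolation
    )
    if interp is None:
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    out = sitk.Resample(
        volume_to_sitk(vol),
        volume_to_sitk(reference),
        transform.to_sitk(),
        interp,
        float(fill_value),
        sitk.sitkFloat64,
    )
    res = sitk_to_volume(out, vol.modality)
    # keep the reference affine verbatim (sitk round-trips can perturb lsb)
    return Volume(res.data, reference.affine.copy(), vol.modality)
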