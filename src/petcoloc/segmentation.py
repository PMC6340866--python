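"""Per-lesion ROI derivation: gradient boundary, fractional-SUVmax, CT.

The primary PET ROI is gradient-based, in the spirit of edge-seeking PET
segmentation tools: rays are cast from the lesion's local uptake maximum and
the boundary is placed where the along-ray uptake gradient magnitude peaks.
For an isotropic Gaussian uptake blob of scale ``sigma`` the radial gradient
``A r / sigma^2 * exp(-r^2 / 2 sigma^2)`` peaks at ``r = sigma``, which gives
an analytic boundary to validate against.

Nested fractional ROIs keep the voxels of the gradient ROI whose SUV is at
least 60/70/80% of the lesion-specific SUVmax, so by construction
``f80 ⊆ f70 ⊆ f60 ⊆ gradient``.  The CT ROI captures radiographically
visible sclerosis with a threshold over the local bone median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import (
    binary_closing,
    gaussian_filter,
    generate_binary_structure,
    label,
    map_coordinates,
)

from .registration import LesionBox
from .volume_io import Volume

__all__ = [
    "ROI",
    "SegmentationError",
    "find_suvmax",
    "segment_gradient",
    "segment_fraction",
    "segment_ct",
    "GradientConfig",
]

LEVELS = ("gradient", "f60", "f70", "f80", "ct")
FRACTION_LEVELS = {0.60: "f60", 0.70: "f70", 0.80: "f80"}


class SegmentationError(RuntimeError):
    pass


@dataclass
class ROI:
    """A binary lesion mask on a reference grid."""

    mask: np.ndarray
    affine: np.ndarray
    level: str
    tracer: str = ""
    lesion_id: str = ""
    empty: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.level not in LEVELS:
            raise ValueError(f"unknown ROI level {self.level!r}")
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3D")
        self.empty = self.empty or not bool(self.mask.any())

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * abs(np.linalg.det(self.affine[:3, :3])) / 1000.0

    def indices(self) -> np.ndarray:
        return np.argwhere(self.mask)

    def world_coords(self) -> np.ndarray:
        idx = self.indices().astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass(frozen=True)
class GradientConfig:
    """Tunables of the ray-cast gradient segmentation."""

    smoothing_sigma_voxels: float = 1.0     # stabilizes the gradient under noise
    max_radius_mm: float = 25.0
    step_mm: float = 0.8
    min_seed_suv: float = 1.0               # background floor
    min_valid_ray_fraction: float = 0.5
    rise_tolerance: float = 0.05            # stop rays once uptake re-rises by 5%
    max_climb_mm: float = 30.0
    gradient_floor: float = 1e-6


def _tie_break_order(indices: np.ndarray) -> np.ndarray:
    """Sort voxel indices by (z, y, x) so ties resolve deterministically."""
    order = np.lexsort((indices[:, 0], indices[:, 1], indices[:, 2]))
    return indices[order]


def find_suvmax(suv: Volume, roi: ROI) -> tuple[tuple[int, int, int], np.ndarray, float]:
    """Location (voxel index and world mm) and value of the ROI's SUVmax.

    Ties are broken by the lowest (z, y, x) index so the result is stable
    across runs.
    """
    if roi.empty or not roi.mask.any():
        raise SegmentationError("cannot take SUVmax of an empty ROI")
    vals = suv.data[roi.mask]
    vmax = vals.max()
    tied = np.argwhere(roi.mask & (suv.data == vmax))
    best = _tie_break_order(tied)[0]
    world = np.asarray(suv.voxel_to_world(best.astype(float)))
    return tuple(int(v) for v in best), world, float(vmax)


# ---------------------------------------------------------------------------
# gradient-based segmentation
# ---------------------------------------------------------------------------

def _ray_directions() -> np.ndarray:
    """26 cube-neighbor directions plus a once-subdivided icosahedron."""
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx or dy or dz:
                    v = np.array([dx, dy, dz], dtype=float)
                    dirs.append(v / np.linalg.norm(v))
    phi = (1 + np.sqrt(5)) / 2
    ico = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    ico /= np.linalg.norm(ico, axis=1)[:, None]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    for a, b, c in faces:
        for p, q in ((a, b), (b, c), (a, c)):
            m = ico[p] + ico[q]
            dirs.append(m / np.linalg.norm(m))
    dirs.extend(ico)
    arr = np.array(dirs)
    # dedupe within tolerance
    uniq: list[np.ndarray] = []
    for d in arr:
        if all(np.linalg.norm(d - u) > 1e-6 for u in uniq):
            uniq.append(d)
    return np.array(uniq)


_RAY_DIRS = _ray_directions()


def _sample_along_ray(
    smoothed: np.ndarray,
    vol: Volume,
    origin_world: np.ndarray,
    direction: np.ndarray,
    radii: np.ndarray,
) -> np.ndarray:
    pts = origin_world[None, :] + radii[:, None] * direction[None, :]
    inv = np.linalg.inv(vol.affine)
    idx = pts @ inv[:3, :3].T + inv[:3, 3]
    return map_coordinates(smoothed, idx.T, order=1, mode="nearest")


def _hill_climb(smoothed: np.ndarray, start: np.ndarray, max_steps: int) -> np.ndarray:
    """Greedy ascent to the local maximum nearest the seed (26-neighborhood)."""
    shape = smoothed.shape
    pos = np.clip(start, 0, np.array(shape) - 1)
    offsets = np.array(
        [
            [dx, dy, dz]
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if dx or dy or dz
        ]
    )
    for _ in range(max_steps):
        nb = pos + offsets
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb = nb[ok]
        vals = smoothed[tuple(nb.T)]
        best = np.argmax(vals)
        if vals[best] <= smoothed[tuple(pos)]:
            return pos
        pos = nb[best]
    return pos


def segment_gradient(
    suv: Volume,
    seed_world: Sequence[float],
    config: GradientConfig | None = None,
    lesion_id: str = "",
    tracer: str = "",
) -> ROI:
    """Gradient-boundary ROI seeded at ``seed_world``.

    Rays are cast from the local SUVmax nearest the seed; per ray the
    boundary radius is where the along-ray gradient magnitude of a smoothed
    copy peaks, searched only while uptake keeps falling (so a neighboring
    lesion's rising flank terminates the search).  Rays without a usable
    peak take the median boundary radius of valid rays; if more than half
    the rays fail the lesion is considered indistinct.
    """
    cfg = config or GradientConfig()
    if not suv.contains_world(seed_world):
        raise SegmentationError("seed lies outside the volume")
    smoothed = gaussian_filter(np.asarray(suv.data, dtype=np.float64), cfg.smoothing_sigma_voxels)

    seed_idx = np.round(suv.world_to_voxel(seed_world)).astype(int)
    max_steps = int(np.ceil(cfg.max_climb_mm / float(min(suv.spacing))))
    center_idx = _hill_climb(smoothed, seed_idx, max_steps)
    center_world = np.asarray(suv.voxel_to_world(center_idx.astype(float)))
    center_val = float(smoothed[tuple(center_idx)])
    if center_val < cfg.min_seed_suv:
        raise SegmentationError(
            f"uptake at seed ({center_val:.2f}) below background floor "
            f"({cfg.min_seed_suv:.2f})"
        )

    radii = np.arange(0.0, cfg.max_radius_mm + cfg.step_mm, cfg.step_mm)
    boundary = np.full(len(_RAY_DIRS), np.nan)
    for k, direction in enumerate(_RAY_DIRS):
        prof = _sample_along_ray(smoothed, suv, center_world, direction, radii)
        # search window: stop once the profile re-rises materially above its
        # running minimum (entering another structure)
        run_min = np.minimum.accumulate(prof)
        rise = prof - run_min
        limit = len(prof)
        bad = np.where(rise > cfg.rise_tolerance * np.maximum(prof[0] - run_min, 1e-12))[0]
        if bad.size:
            limit = int(bad[0])
        if limit < 3:
            continue
        grad = np.abs(np.gradient(prof[:limit], cfg.step_mm))
        grad[0] = 0.0  # boundary cannot sit on the center
        peak = int(np.argmax(grad))
        if grad[peak] < cfg.gradient_floor or peak == 0 or peak >= limit - 1:
            continue
        boundary[k] = radii[peak]

    valid = ~np.isnan(boundary)
    if valid.sum() < cfg.min_valid_ray_fraction * len(_RAY_DIRS):
        raise SegmentationError(
            f"no gradient boundary on {int((~valid).sum())}/{len(_RAY_DIRS)} rays; "
            "lesion indistinct"
        )
    boundary[~valid] = np.median(boundary[valid])

    mask = _voxelize_star_shape(suv, center_world, boundary)
    struct = generate_binary_structure(3, 1)
    mask = binary_closing(mask, structure=struct)
    # keep the component containing the center
    lab, n = label(mask)
    if n > 1:
        mask = lab == lab[tuple(center_idx)]
    mask[tuple(center_idx)] = True
    return ROI(mask, suv.affine.copy(), "gradient", tracer=tracer, lesion_id=lesion_id)


def _voxelize_star_shape(
    vol: Volume, center_world: np.ndarray, boundary_radii: np.ndarray
) -> np.ndarray:
    """Voxels whose center lies inside the star-shaped surface defined by
    per-ray boundary radii (angular nearest-ray interpolation, k=4)."""
    r_max = float(np.nanmax(boundary_radii))
    half = r_max + 2.0 * float(max(vol.spacing))
    inv = np.linalg.inv(vol.affine)
    lo = np.floor(
        (np.asarray(vol.world_to_voxel(center_world - half))).astype(float)
    ).astype(int)
    hi = np.ceil(
        (np.asarray(vol.world_to_voxel(center_world + half))).astype(float)
    ).astype(int)
    lo = np.clip(lo, 0, np.array(vol.shape) - 1)
    hi = np.clip(hi, 0, np.array(vol.shape) - 1)
    ii, jj, kk = np.meshgrid(
        *[np.arange(a, b + 1) for a, b in zip(lo, hi)], indexing="ij"
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    pts = idx @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    vec = pts - center_world
    r = np.linalg.norm(vec, axis=1)
    inside = np.zeros(len(vec), dtype=bool)
    inside[r < 1e-9] = True
    far = r >= 1e-9
    dirs = vec[far] / r[far, None]
    # angular distance to every ray direction; blend k nearest rays
    cosang = np.clip(dirs @ _RAY_DIRS.T, -1.0, 1.0)
    k = 4
    nearest = np.argpartition(-cosang, k, axis=1)[:, :k]
    ang = np.arccos(np.take_along_axis(cosang, nearest, axis=1))
    w = 1.0 / (ang + 1e-3)
    rb = np.take_along_axis(
        np.broadcast_to(boundary_radii, (len(dirs), len(boundary_radii))), nearest, axis=1
    )
    r_bound = (w * rb).sum(axis=1) / w.sum(axis=1)
    inside[far] = r[far] <= r_bound
    mask = np.zeros(vol.shape, dtype=bool)
    mask[tuple(idx[inside].astype(int).T)] = True
    return mask


# ---------------------------------------------------------------------------
# fractional and CT ROIs
# ---------------------------------------------------------------------------

def segment_fraction(suv: Volume, parent: ROI, fraction: float) -> ROI:
    """Voxels of ``parent`` with SUV >= fraction x lesion SUVmax.

    The SUVmax voxel itself always survives, so the result is never empty.
    """
    if parent.empty:
        raise SegmentationError("parent ROI is empty")
    if fraction not in FRACTION_LEVELS:
        raise ValueError(f"fraction must be one of {sorted(FRACTION_LEVELS)}")
    _, _, vmax = find_suvmax(suv, parent)
    mask = parent.mask & (suv.data >= fraction * vmax)
    return ROI(
        mask,
        parent.affine.copy(),
        FRACTION_LEVELS[fraction],
        tracer=parent.tracer,
        lesion_id=parent.lesion_id,
    )


def segment_ct(
    ct: Volume,
    box: LesionBox,
    delta_hu: float = 150.0,
    bone_floor_hu: float = 100.0,
    lesion_id: str = "",
) -> ROI:
    """Sclerosis ROI: box voxels exceeding the local bone median by ``delta_hu``.

    The reference level is the median HU of bone voxels (HU > ``bone_floor_hu``)
    inside the box, falling back to the box median when the box holds no bone.
    The largest connected component above threshold is kept and closed.  A
    lesion with no voxels above threshold (e.g. osteolytic, radiographically
    invisible) yields an ROI flagged ``empty``.
    """
    sl = box.index_slices(ct)
    sub = ct.data[sl]
    bone = sub[sub > bone_floor_hu]
    ref_level = float(np.median(bone)) if bone.size else float(np.median(sub))
    thr = ref_level + delta_hu
    mask_sub = sub >= thr
    full = np.zeros(ct.shape, dtype=bool)
    if not mask_sub.any():
        return ROI(full, ct.affine.copy(), "ct", tracer="CT", lesion_id=lesion_id, empty=True)
    lab, n = label(mask_sub)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    mask_sub = lab == largest
    mask_sub = binary_closing(mask_sub, structure=generate_binary_structure(3, 1))
    full[sl] = mask_sub
    return ROI(full, ct.affine.copy(), "ct", tracer="CT", lesion_id=lesion_id)
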