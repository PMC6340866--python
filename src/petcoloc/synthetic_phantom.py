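"""Synthetic dual-tracer PET/CT phantom cohorts with known ground truth.

Each simulated patient carries two PET/CT sessions: a bone-remodeling
("NaF-like") tracer A session and a tumor-targeted ("PSMA-like") tracer B
session.  Lesions are osteosclerotic: a sphere of elevated HU embedded in a
bone-density sphere within soft tissue.  Tracer-A uptake is an isotropic
Gaussian blob centered on the sclerosis; tracer-B uptake is a blob displaced
from the sclerosis center by a random offset whose mean depends on disease
status — small for castration-sensitive (CSPC) patients, large for
castration-resistant (CRPC) — so a two-group cohort reproduces the contrast
the downstream colocalization analysis is designed to detect.  Uptake is
PSF-blurred and carries additive Gaussian noise; session B is resampled
through a random small rigid transform to emulate inter-session patient
repositioning (PET and CT of one session share a frame, as on a PET/CT
scanner).

Everything is deterministic given the master seed; per-patient and
per-lesion RNG streams are derived by seed-sequence spawning so changing the
cohort size never reshuffles earlier patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .registration import RigidTransform, resample
from .volume_io import (
    INCLUDED_REGIONS,
    LesionRecord,
    Volume,
    write_lesion_manifest,
    write_volume,
)

__all__ = [
    "PhantomParams",
    "LesionTruth",
    "PhantomStudy",
    "generate_patient",
    "generate_cohort",
    "write_study",
]


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one simulated cohort.

    Lesion geometry is expressed through the tracer blob standard deviation
    ``sigma`` (mm): the sclerotic CT sphere radius is
    ``sclerosis_radius_factor * sigma`` and the surrounding bone sphere
    ``bone_radius_factor * sigma``.
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    n_lesions: int = 5
    blob_sigma_range_mm: tuple[float, float] = (3.5, 5.5)
    #: mean / sd of the tracer-B displacement magnitude (mm) per status
    offset_mean_mm: dict = field(
        default_factory=lambda: {"CSPC": 1.5, "CRPC": 7.0}
    )
    offset_sd_mm: dict = field(default_factory=lambda: {"CSPC": 1.0, "CRPC": 2.5})
    peak_suv_a: tuple[float, float] = (8.0, 15.0)
    peak_suv_b: tuple[float, float] = (6.0, 12.0)
    background_suv: float = 0.3
    sclerosis_hu: float = 400.0
    sclerosis_radius_factor: float = 1.6
    sclerosis_edge_mm: float = 2.0
    bone_hu: float = 250.0
    soft_tissue_hu: float = 40.0
    bone_radius_factor: float = 3.0
    psf_fwhm_mm: float = 6.0
    noise_sd_suv: float = 0.1
    ct_noise_sd_hu: float = 5.0
    intersession_translation_mm: float = 3.0
    intersession_rotation_deg: float = 2.0
    min_lesion_separation_mm: float = 40.0
    edge_margin_mm: float = 25.0
    max_placement_attempts: int = 2000

    def __post_init__(self) -> None:
        if self.blob_sigma_range_mm[0] <= 0:
            raise ValueError("blob sigma must be positive")
        if any(m < 0 for m in self.offset_mean_mm.values()):
            raise ValueError("offset means must be non-negative")
        if self.psf_fwhm_mm < 0 or self.noise_sd_suv < 0 or self.ct_noise_sd_hu < 0:
            raise ValueError("PSF FWHM and noise scales must be non-negative")
        if self.n_lesions < 1:
            raise ValueError("need at least one lesion per patient")

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing_mm)
        return A

    def fov_mm(self) -> np.ndarray:
        return np.array(self.shape) * np.array(self.spacing_mm)


@dataclass(frozen=True)
class LesionTruth:
    """Ground truth for one simulated lesion."""

    lesion_id: str
    center_mm: tuple[float, float, float]        # sclerosis / tracer-A center
    tracer_a_center_mm: tuple[float, float, float]
    tracer_b_center_mm: tuple[float, float, float]
    offset_mm: float
    blob_sigma_mm: float
    sclerosis_radius_mm: float
    peak_suv_a: float
    peak_suv_b: float
    region: str


@dataclass
class PhantomStudy:
    """One simulated patient: four volumes plus ground truth.

    ``intersession`` is the rigid transform used to resample the
    patient-frame fields onto the session-B grid, i.e. it maps session-B
    grid points into the patient (session-A) frame.  A registration of
    ``ct_b`` onto ``ct_a`` recovers its *inverse*:
    ``intersession.compose(recovered)`` is close to the identity.
    """

    patient_id: str
    status: str
    cohort: str
    pet_a: Volume
    pet_b: Volume
    ct_a: Volume
    ct_b: Volume
    truth: list[LesionTruth]
    intersession: RigidTransform
    manifest: list[LesionRecord]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _world_grid(params: PhantomParams) -> tuple[np.ndarray, ...]:
    axes = [
        np.arange(n) * s for n, s in zip(params.shape, params.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _add_smooth_sphere(
    field_: np.ndarray,
    grid: tuple[np.ndarray, ...],
    center: np.ndarray,
    radius: float,
    amplitude: float,
    edge_mm: float,
) -> None:
    """Add a sphere with a raised-cosine shell of half-width ``edge_mm``."""
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grid, center)))
    inner, outer = radius - edge_mm, radius + edge_mm
    profile = np.zeros_like(r)
    profile[r <= inner] = 1.0
    shell = (r > inner) & (r < outer)
    profile[shell] = 0.5 * (1.0 + np.cos(np.pi * (r[shell] - inner) / (2.0 * edge_mm)))
    field_ += amplitude * profile


def _add_gaussian_blob(
    field_: np.ndarray,
    grid: tuple[np.ndarray, ...],
    center: np.ndarray,
    sigma: float,
    amplitude: float,
    truncate_sigma: float = 3.0,
) -> None:
    r2 = sum((g - c) ** 2 for g, c in zip(grid, center))
    blob = amplitude * np.exp(-r2 / (2.0 * sigma**2))
    blob[r2 > (truncate_sigma * sigma) ** 2] = 0.0
    field_ += blob


def _psf_blur(data: np.ndarray, fwhm_mm: float, spacing: Sequence[float]) -> np.ndarray:
    if fwhm_mm <= 0:
        return data
    sigma_mm = fwhm_mm / 2.3548200450309493  # FWHM -> sigma
    return gaussian_filter(data, sigma=[sigma_mm / s for s in spacing])


def _draw_lesion_centers(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    fov = params.fov_mm()
    lo = np.full(3, params.edge_margin_mm)
    hi = fov - params.edge_margin_mm
    if np.any(hi <= lo):
        raise ValueError("grid too small for the requested edge margin")
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < params.n_lesions:
        if attempts >= params.max_placement_attempts:
            raise RuntimeError(
                f"could not place {params.n_lesions} lesions with "
                f"{params.min_lesion_separation_mm} mm separation"
            )
        attempts += 1
        cand = rng.uniform(lo, hi)
        if all(
            np.linalg.norm(cand - c) >= params.min_lesion_separation_mm
            for c in centers
        ):
            centers.append(cand)
    return np.array(centers)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _draw_intersession(params: PhantomParams, rng: np.random.Generator) -> RigidTransform:
    rot = rng.uniform(
        -params.intersession_rotation_deg, params.intersession_rotation_deg, size=3
    )
    tra = rng.uniform(
        -params.intersession_translation_mm,
        params.intersession_translation_mm,
        size=3,
    )
    center = params.fov_mm() / 2.0
    return RigidTransform(tuple(rot), tuple(tra), tuple(center))


_REGION_CYCLE = sorted(INCLUDED_REGIONS)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_patient(
    params: PhantomParams,
    status: str,
    seed: int | np.random.SeedSequence,
    patient_id: str = "P01",
    cohort: str = "DCFPyL",
) -> PhantomStudy:
    """Simulate one patient (both sessions) deterministically from ``seed``."""
    if status not in ("CSPC", "CRPC"):
        raise ValueError(f"unknown status {status!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    grid = _world_grid(params)
    affine = params.affine

    centers = _draw_lesion_centers(params, rng)

    ct_true = np.full(params.shape, params.soft_tissue_hu, dtype=np.float64)
    pet_a_true = np.full(params.shape, params.background_suv, dtype=np.float64)
    pet_b_true = np.full(params.shape, params.background_suv, dtype=np.float64)

    truth: list[LesionTruth] = []
    manifest: list[LesionRecord] = []
    for i, center in enumerate(centers):
        sigma = rng.uniform(*params.blob_sigma_range_mm)
        peak_a = rng.uniform(*params.peak_suv_a)
        peak_b = rng.uniform(*params.peak_suv_b)
        off_mag = abs(
            rng.normal(params.offset_mean_mm[status], params.offset_sd_mm[status])
        )
        off_dir = _random_unit_vector(rng)
        b_center = center + off_mag * off_dir
        # keep the displaced blob inside the usable field of view
        fov = params.fov_mm()
        b_center = np.clip(b_center, params.edge_margin_mm / 2, fov - params.edge_margin_mm / 2)
        off_mag = float(np.linalg.norm(b_center - center))

        scler_r = params.sclerosis_radius_factor * sigma
        bone_r = params.bone_radius_factor * sigma
        _add_smooth_sphere(
            ct_true, grid, center, bone_r, params.bone_hu - params.soft_tissue_hu, 2.0
        )
        _add_smooth_sphere(
            ct_true, grid, center, scler_r, params.sclerosis_hu, params.sclerosis_edge_mm
        )
        _add_gaussian_blob(pet_a_true, grid, center, sigma, peak_a)
        _add_gaussian_blob(pet_b_true, grid, b_center, sigma, peak_b)

        lesion_id = f"{patient_id}_L{i + 1:02d}"
        region = _REGION_CYCLE[int(rng.integers(len(_REGION_CYCLE)))]
        truth.append(
            LesionTruth(
                lesion_id=lesion_id,
                center_mm=tuple(center),
                tracer_a_center_mm=tuple(center),
                tracer_b_center_mm=tuple(b_center),
                offset_mm=off_mag,
                blob_sigma_mm=float(sigma),
                sclerosis_radius_mm=float(scler_r),
                peak_suv_a=float(peak_a),
                peak_suv_b=float(peak_b),
                region=region,
            )
        )
        manifest.append(
            LesionRecord(
                patient_id=patient_id,
                lesion_id=lesion_id,
                region=region,
                status=status,
                cohort=cohort,
                seed_world=tuple(float(c) for c in center),
            )
        )

    pet_a_true = _psf_blur(pet_a_true, params.psf_fwhm_mm, params.spacing_mm)
    pet_b_true = _psf_blur(pet_b_true, params.psf_fwhm_mm, params.spacing_mm)

    ref = Volume(ct_true, affine, "HU")
    intersession = _draw_intersession(params, rng)

    # session B volumes: the patient-frame fields sampled through the
    # inter-session transform (patient repositioned between sessions)
    ct_b = resample(
        Volume(ct_true, affine, "HU"), intersession, ref, "linear",
        fill_value=params.soft_tissue_hu,
    )
    pet_b = resample(
        Volume(pet_b_true, affine, "SUV"), intersession, ref, "linear",
        fill_value=params.background_suv,
    )

    # independent measurement noise per session, after blur and resampling
    pet_a_data = pet_a_true + rng.normal(0.0, params.noise_sd_suv, params.shape) if params.noise_sd_suv > 0 else pet_a_true
    pet_b_data = pet_b.data + rng.normal(0.0, params.noise_sd_suv, params.shape) if params.noise_sd_suv > 0 else pet_b.data
    ct_a_data = ct_true + rng.normal(0.0, params.ct_noise_sd_hu, params.shape) if params.ct_noise_sd_hu > 0 else ct_true
    ct_b_data = ct_b.data + rng.normal(0.0, params.ct_noise_sd_hu, params.shape) if params.ct_noise_sd_hu > 0 else ct_b.data

    return PhantomStudy(
        patient_id=patient_id,
        status=status,
        cohort=cohort,
        pet_a=Volume(pet_a_data, affine.copy(), "SUV"),
        pet_b=Volume(pet_b_data, affine.copy(), "SUV"),
        ct_a=Volume(ct_a_data, affine.copy(), "HU"),
        ct_b=Volume(ct_b_data, affine.copy(), "HU"),
        truth=truth,
        intersession=intersession,
        manifest=manifest,
    )


def generate_cohort(
    params: PhantomParams,
    n_cspc: int,
    n_crpc: int,
    seed: int,
) -> list[PhantomStudy]:
    """Simulate a two-group cohort; per-patient streams are spawned from the
    master seed so each patient's data is independent of the cohort size."""
    if n_cspc < 0 or n_crpc < 0:
        raise ValueError("cohort counts must be non-negative")
    if n_cspc + n_crpc == 0:
        raise ValueError("cohort must contain at least one patient")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_cspc + n_crpc)
    studies: list[PhantomStudy] = []
    statuses = ["CSPC"] * n_cspc + ["CRPC"] * n_crpc
    for i, (status, child) in enumerate(zip(statuses, children)):
        studies.append(
            generate_patient(
                params, status, child, patient_id=f"P{i + 1:02d}",
                cohort="DCFPyL" if status == "CSPC" else "DCFBC",
            )
        )
    return studies


def write_study(study: PhantomStudy, out_dir: str | Path) -> Path:
    """Write one study to disk: NIfTI volumes, manifest CSV, truth JSON."""
    out = Path(out_dir) / study.patient_id
    out.mkdir(parents=True, exist_ok=True)
    write_volume(study.pet_a, out / "pet_a_suv.nii.gz")
    write_volume(study.pet_b, out / "pet_b_suv.nii.gz")
    write_volume(study.ct_a, out / "ct_a_hu.nii.gz")
    write_volume(study.ct_b, out / "ct_b_hu.nii.gz")
    write_lesion_manifest(study.manifest, out / "manifest.csv")
    payload = {
        "patient_id": study.patient_id,
        "status": study.status,
        "cohort": study.cohort,
        "intersession": json.loads(study.intersession.to_json()),
        "lesions": [asdict(t) for t in study.truth],
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2))
    return out
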