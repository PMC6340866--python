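"""Volumes, lesion manifests and SUV conversion.

A :class:`Volume` is a 3D scalar grid (PET uptake, CT attenuation, or raw
activity concentration) together with a voxel-to-world affine in millimetres.
Arrays are indexed ``(i, j, k)`` with ``i`` varying fastest along the world
x-ish axis, matching the NIfTI convention used by nibabel.  All seed points
and distances in this package are expressed in world millimetres; voxel
indices are 0-based and a voxel belongs wholly to a mask or not at all.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LesionRecord",
    "read_volume",
    "write_volume",
    "compute_suv",
    "load_lesion_manifest",
    "write_lesion_manifest",
    "MODALITIES",
    "REGIONS",
    "INCLUDED_REGIONS",
    "STATUSES",
    "COHORTS",
    "MANIFEST_COLUMNS",
]

MODALITIES = ("SUV", "HU", "ACTIVITY")

#: Skeletal regions a lesion may be annotated with.  Pelvis and spine regions
#: are eligible for spatial analysis; motion-prone sites (ribs, extremities,
#: skull) are carried in the manifest but excluded by the pipeline.
REGIONS = (
    "ilium",
    "thoracic_spine",
    "lumbar_spine",
    "sacrum",
    "pubis_ischium",
    "acetabulum",
    "cervical_spine",
    "humeral_head",
    "femoral_head",
    "rib",
    "skull",
    "extremity",
)

INCLUDED_REGIONS = frozenset(
    {
        "ilium",
        "thoracic_spine",
        "lumbar_spine",
        "sacrum",
        "pubis_ischium",
        "acetabulum",
        "cervical_spine",
    }
)

STATUSES = ("CSPC", "CRPC")
COHORTS = ("DCFBC", "DCFPyL")

MANIFEST_COLUMNS = (
    "patient_id",
    "lesion_id",
    "region",
    "status",
    "cohort",
    "seed_x_mm",
    "seed_y_mm",
    "seed_z_mm",
)


@dataclass
class Volume:
    """A 3D scalar grid with world geometry.

    Parameters
    ----------
    data:
        3D array of voxel values.
    affine:
        4x4 voxel-index to world-mm transform.
    modality:
        One of ``SUV``, ``HU``, ``ACTIVITY``.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = "SUV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (mm) along the three index axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_ml(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    def voxel_to_world(self, idx: Sequence[float]) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        pts = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return pts[0] if pts.shape[0] == 1 else pts

    def world_to_voxel(self, xyz: Sequence[float]) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        idx = xyz @ inv[:3, :3].T + inv[:3, 3]
        return idx[0] if idx.shape[0] == 1 else idx

    def contains_world(self, xyz: Sequence[float]) -> bool:
        idx = self.world_to_voxel(xyz)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array(self.shape) - 0.5))

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy(), self.modality)


@dataclass(frozen=True)
class LesionRecord:
    """One row of the lesion manifest."""

    patient_id: str
    lesion_id: str
    region: str
    status: str
    cohort: str
    seed_world: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.patient_id or not self.lesion_id:
            raise ValueError("patient_id and lesion_id must be non-empty")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")


def read_volume(path: str | Path, modality: str = "SUV") -> Volume:
    """Load a 3D NIfTI image; spacing and affine come from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}D; a 3D image is required")
    return Volume(np.asarray(data, dtype=np.float64), np.asarray(img.affine), modality)


def write_volume(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    nib.save(img, str(path))
    return path


def compute_suv(activity: Volume, injected_dose_kbq: float, body_weight_g: float) -> Volume:
    """Convert an activity-concentration volume (kBq/mL) to SUV.

    SUV is the ratio of measured activity concentration to injected dose per
    body weight, with tissue density taken as 1 g/mL, so
    ``SUV = activity * body_weight_g / injected_dose_kbq`` (dimensionless).
    """
    if activity.modality != "ACTIVITY":
        raise ValueError("input volume must have modality ACTIVITY")
    if injected_dose_kbq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    suv = activity.data * (body_weight_g / injected_dose_kbq)
    return Volume(suv, activity.affine.copy(), "SUV")


def load_lesion_manifest(path: str | Path) -> list[LesionRecord]:
    """Read a lesion manifest CSV and validate every row.

    Required columns: ``patient_id, lesion_id, region, status, cohort,
    seed_x_mm, seed_y_mm, seed_z_mm``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[LesionRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                rec = LesionRecord(
                    patient_id=row["patient_id"].strip(),
                    lesion_id=row["lesion_id"].strip(),
                    region=row["region"].strip(),
                    status=row["status"].strip(),
                    cohort=row["cohort"].strip(),
                    seed_world=(
                        float(row["seed_x_mm"]),
                        float(row["seed_y_mm"]),
                        float(row["seed_z_mm"]),
                    ),
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"manifest row {i}: {exc}") from exc
            records.append(rec)
    return records


def write_lesion_manifest(records: Iterable[LesionRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in records:
            writer.writerow(
                [r.patient_id, r.lesion_id, r.region, r.status, r.cohort]
                + [repr(float(c)) for c in r.seed_world]
            )
    return path
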