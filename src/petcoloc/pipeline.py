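"""End-to-end study orchestration.

One call runs the whole analysis on a cohort of dual-tracer studies:
per-patient global CT registration, per-lesion local refinement, gradient
and fractional-SUVmax segmentation for both tracers, CT sclerosis ROI,
concordance metrics, the voxel HU table, and the cohort statistics
(clustered signed-rank across segmentation levels, patient-level permutation
tests between disease-status groups, the nested HU mixed model with its
paired-scan ICC, and Spearman correlations).

Lesions that fail any stage (outside the included skeletal regions, seed in
background, indistinct boundary, failed local registration, empty ROI) are
excluded and logged with a reason; every manifest lesion ends up exactly
once in either the results table or the exclusion log.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cluster_stats as cs
from .colocalization import (
    CATEGORY_NAMES,
    average_pairwise_distance,
    centroid_distance,
    classify_voxels,
    hu_by_category,
    overlap_volume,
    suvmax_distance,
)
from .registration import (
    LesionBox,
    RegistrationError,
    RigidTransform,
    register_global,
    register_local,
    resample,
)
from .segmentation import (
    GradientConfig,
    ROI,
    SegmentationError,
    find_suvmax,
    segment_ct,
    segment_fraction,
    segment_gradient,
)
from .synthetic_phantom import PhantomParams, PhantomStudy, generate_cohort
from .volume_io import INCLUDED_REGIONS, LesionRecord

logger = logging.getLogger("petcoloc.pipeline")

__all__ = ["StudyConfig", "StudyResult", "run_study", "validate_inclusion"]

FRACTIONS = (0.60, 0.70, 0.80)
LEVELS = ("gradient", "f60", "f70", "f80")


@dataclass
class StudyConfig:
    """Configuration of one cohort analysis run."""

    # cohort: either phantom parameters (simulate) or a directory of studies
    phantom: PhantomParams = field(default_factory=PhantomParams)
    n_cspc: int = 6
    n_crpc: int = 13
    cohort_seed: int = 7041
    # registration
    bone_hu: float = 100.0
    box_radius_mm: float = 10.0
    box_margin_mm: float = 15.0
    registration_iterations: int = 150
    # segmentation
    gradient: GradientConfig = field(default_factory=GradientConfig)
    ct_delta_hu: float = 150.0
    # statistics
    n_perm: int = 2000
    n_boot: int = 2000
    alpha: float = 0.05
    stats_seed: int = 20061
    # output
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    # -- (de)serialization --------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = d["phantom"]
            for key in ("shape", "spacing_mm", "blob_sigma_range_mm",
                        "peak_suv_a", "peak_suv_b"):
                if key in ph and isinstance(ph[key], list):
                    ph[key] = tuple(ph[key])
            d["phantom"] = PhantomParams(**ph)
        if "gradient" in d and isinstance(d["gradient"], dict):
            d["gradient"] = GradientConfig(**d["gradient"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class StudyResult:
    """Everything a cohort run produces."""

    lesions: pd.DataFrame               # one row per analyzed lesion
    hu_table: pd.DataFrame              # long voxel HU table
    ov_by_level: pd.DataFrame
    table2_style: pd.DataFrame
    table3_style: pd.DataFrame
    correlations: pd.DataFrame
    exclusions: pd.DataFrame            # lesion_id, patient_id, reason
    icc: float
    lrt_p: float
    roi_voxel_indices: dict             # (lesion_id, tracer, level) -> flat indices

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.6g"
        self.lesions.to_csv(out / "lesions.csv", index=False, float_format=fmt)
        self.ov_by_level.to_csv(out / "ov_by_level.csv", index=False, float_format=fmt)
        self.table2_style.to_csv(out / "table2_style.csv", index=False, float_format=fmt)
        self.table3_style.to_csv(out / "table3_style.csv", index=False, float_format=fmt)
        self.correlations.to_csv(out / "correlations.csv", index=False, float_format=fmt)
        with open(out / "exclusions.log", "w") as fh:
            for _, row in self.exclusions.iterrows():
                fh.write(f"{row.patient_id}\t{row.lesion_id}\t{row.reason}\n")
        return out


def validate_inclusion(
    manifest: Sequence[LesionRecord],
) -> tuple[list[LesionRecord], list[tuple[LesionRecord, str]]]:
    """Keep pelvis/spine lesions; motion-prone regions are excluded."""
    kept: list[LesionRecord] = []
    excluded: list[tuple[LesionRecord, str]] = []
    for rec in manifest:
        if rec.region in INCLUDED_REGIONS:
            kept.append(rec)
        else:
            excluded.append((rec, f"motion-prone region '{rec.region}'"))
    return kept, excluded


# ---------------------------------------------------------------------------
# per-lesion analysis
# ---------------------------------------------------------------------------

def _analyze_lesion(
    study: PhantomStudy,
    rec: LesionRecord,
    config: StudyConfig,
    t_global: RigidTransform,
) -> tuple[dict, pd.DataFrame, dict]:
    """Run registration refinement, segmentation and concordance for one lesion."""
    seed = np.asarray(rec.seed_world, float)
    box = LesionBox.from_seed(seed, config.box_radius_mm, config.box_margin_mm)
    t_local = register_local(
        study.ct_a, study.ct_b, box, t_global, bone_hu=config.bone_hu
    )
    ref = study.ct_a
    pet_b_reg = resample(
        study.pet_b, t_local, ref, "linear", fill_value=0.0
    )
    ct_b_reg = resample(study.ct_b, t_local, ref, "linear", fill_value=-1000.0)

    roi_a = segment_gradient(
        study.pet_a, seed, config.gradient, lesion_id=rec.lesion_id, tracer="NaF"
    )
    roi_b = segment_gradient(
        pet_b_reg, seed, config.gradient, lesion_id=rec.lesion_id, tracer="PSMA"
    )
    rois_a = {"gradient": roi_a}
    rois_b = {"gradient": roi_b}
    for frac in FRACTIONS:
        rois_a[f"f{int(frac * 100)}"] = segment_fraction(study.pet_a, roi_a, frac)
        rois_b[f"f{int(frac * 100)}"] = segment_fraction(pet_b_reg, roi_b, frac)
    # nesting is structural; assert it as a pipeline sanity check
    for rois, vol in ((rois_a, study.pet_a), (rois_b, pet_b_reg)):
        assert np.all(~rois["f80"].mask | rois["f70"].mask)
        assert np.all(~rois["f70"].mask | rois["f60"].mask)
        assert np.all(~rois["f60"].mask | rois["gradient"].mask)

    roi_ct = segment_ct(
        study.ct_a, box, delta_hu=config.ct_delta_hu, lesion_id=rec.lesion_id
    )

    _, loc_a, suvmax_a = find_suvmax(study.pet_a, roi_a)
    _, loc_b, suvmax_b = find_suvmax(pet_b_reg, roi_b)

    row: dict = {
        "patient_id": rec.patient_id,
        "lesion_id": rec.lesion_id,
        "region": rec.region,
        "status": rec.status,
        "cohort": rec.cohort,
        "suvmax_a": suvmax_a,
        "suvmax_b": suvmax_b,
    }
    for lvl in LEVELS:
        row[f"ov_{lvl}"] = overlap_volume(rois_b[lvl], rois_a[lvl])
        row[f"n_vox_a_{lvl}"] = rois_a[lvl].voxel_count
        row[f"n_vox_b_{lvl}"] = rois_b[lvl].voxel_count
    row["vol_a_ml"] = rois_a["gradient"].volume_ml
    row["vol_b_ml"] = rois_b["gradient"].volume_ml
    if roi_ct.empty:
        row["ov_naf_ct"] = np.nan
        row["ov_psma_ct"] = np.nan
        row["hu_mean_ct_roi"] = np.nan
    else:
        row["ov_naf_ct"] = overlap_volume(rois_a["gradient"], roi_ct)
        row["ov_psma_ct"] = overlap_volume(rois_b["gradient"], roi_ct)
        row["hu_mean_ct_roi"] = float(study.ct_a.data[roi_ct.mask].mean())
    row["n_vox_ct"] = roi_ct.voxel_count
    row["d_suvmax_mm"] = suvmax_distance(loc_a, loc_b)
    row["d_centroid80_mm"] = centroid_distance(rois_a["f80"], rois_b["f80"])
    row["d_pairwise80_mm"] = average_pairwise_distance(
        rois_a["f80"], rois_b["f80"], seed=config.stats_seed
    )

    cmap = classify_voxels(rois_b["gradient"], rois_a["gradient"], roi_ct)
    hu_rows = hu_by_category(study.ct_a, ct_b_reg, cmap, rec)

    masks = {}
    for tracer, rois in (("NaF", rois_a), ("PSMA", rois_b)):
        for lvl in LEVELS:
            masks[(rec.lesion_id, tracer, lvl)] = np.flatnonzero(rois[lvl].mask)
    masks[(rec.lesion_id, "CT", "ct")] = np.flatnonzero(roi_ct.mask)
    return row, hu_rows, masks


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def _cohort_statistics(
    lesions: pd.DataFrame, hu_table: pd.DataFrame, config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, float, float]:
    groups_present = lesions["status"].nunique() == 2

    # OV by segmentation level: per-group medians, permutation p, and the
    # clustered signed-rank p of each fraction level against the gradient level
    ov_rows = []
    for lvl in LEVELS:
        col = f"ov_{lvl}"
        entry = {"level": lvl}
        for status in ("CSPC", "CRPC"):
            sub = lesions.loc[lesions.status == status, col].dropna()
            entry[f"median_{status.lower()}"] = sub.median() if len(sub) else np.nan
        entry["median_all"] = lesions[col].median()
        if groups_present:
            sample = cs.GroupedLesionSample.from_arrays(
                lesions.patient_id, lesions.status, lesions[col]
            )
            _, entry["perm_p"] = cs.patient_permutation_test(
                sample, n_perm=config.n_perm, seed=config.stats_seed
            )
        else:
            entry["perm_p"] = np.nan
        if lvl != "gradient":
            paired = cs.PairedClusteredSample.from_arrays(
                lesions.patient_id, lesions[col], lesions["ov_gradient"]
            )
            try:
                _, entry["signed_rank_p_vs_gradient"] = cs.clustered_signed_rank(paired)
            except ValueError:
                entry["signed_rank_p_vs_gradient"] = np.nan
        else:
            entry["signed_rank_p_vs_gradient"] = np.nan
        ov_rows.append(entry)
    ov_by_level = pd.DataFrame(ov_rows)

    # distance metrics by group with permutation p (Table-3-like layout)
    t3_rows = []
    for col, label in (
        ("d_suvmax_mm", "distance between SUVmax"),
        ("d_centroid80_mm", "distance between 80%-SUVmax ROI centroids"),
        ("d_pairwise80_mm", "average pairwise distance between 80%-SUVmax ROIs"),
    ):
        entry = {"measure": label}
        for status in ("CSPC", "CRPC"):
            sub = lesions.loc[lesions.status == status, col].dropna()
            entry[f"median_{status.lower()}"] = sub.median() if len(sub) else np.nan
            entry[f"min_{status.lower()}"] = sub.min() if len(sub) else np.nan
            entry[f"max_{status.lower()}"] = sub.max() if len(sub) else np.nan
        if groups_present:
            sample = cs.GroupedLesionSample.from_arrays(
                lesions.patient_id, lesions.status, lesions[col]
            )
            _, entry["perm_p"] = cs.patient_permutation_test(
                sample, n_perm=config.n_perm, seed=config.stats_seed + 1
            )
        else:
            entry["perm_p"] = np.nan
        t3_rows.append(entry)
    table3 = pd.DataFrame(t3_rows)

    # nested HU mixed model (Table-2-like layout) + paired-scan ICC
    icc = np.nan
    lrt_p = np.nan
    t2 = pd.DataFrame(
        columns=["category", "estimate", "se", "reference"]
    )
    if hu_table["category"].nunique() >= 2:
        try:
            model = cs.fit_hu_mixed_model(hu_table)
            icc, lrt_p = model.icc, model.lrt_p
            rows = [
                {
                    "category": model.reference_category,
                    "estimate": model.intercept,
                    "se": np.nan,
                    "reference": True,
                }
            ]
            for cat, est in model.fixed_effects.items():
                rows.append(
                    {
                        "category": cat,
                        "estimate": est,
                        "se": model.fixed_se[cat],
                        "reference": False,
                    }
                )
            t2 = pd.DataFrame(rows)
        except Exception as exc:  # singular fits on degenerate cohorts
            logger.warning("HU mixed model failed: %s", exc)

    # Spearman correlations of OV with uptake and CT characteristics
    corr_rows = []
    for lvl in LEVELS:
        for other, name in (
            ("suvmax_a", "SUVmax NaF"),
            ("suvmax_b", "SUVmax PSMA"),
            ("vol_a_ml", "NaF ROI volume"),
            ("vol_b_ml", "PSMA ROI volume"),
            ("hu_mean_ct_roi", "HU mean CT ROI"),
        ):
            sub = lesions[[f"ov_{lvl}", other]].dropna()
            try:
                rho, p = cs.spearman_corr(sub[f"ov_{lvl}"], sub[other])
            except ValueError:
                rho, p = np.nan, np.nan
            corr_rows.append({"ov_level": lvl, "versus": name, "rho": rho, "p": p})
    correlations = pd.DataFrame(corr_rows)

    return ov_by_level, t2, table3, correlations, float(icc), float(lrt_p)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_study(
    config: StudyConfig,
    studies: Iterable[PhantomStudy] | None = None,
) -> StudyResult:
    """Run the full analysis; simulates a phantom cohort unless ``studies``
    are supplied.  Deterministic for a fixed config."""
    if studies is None:
        studies = generate_cohort(
            config.phantom, config.n_cspc, config.n_crpc, config.cohort_seed
        )
    lesion_rows: list[dict] = []
    hu_frames: list[pd.DataFrame] = []
    exclusions: list[dict] = []
    roi_indices: dict = {}

    for study in studies:
        kept, excluded = validate_inclusion(study.manifest)
        for rec, reason in excluded:
            exclusions.append(
                {"patient_id": rec.patient_id, "lesion_id": rec.lesion_id, "reason": reason}
            )
        if not kept:
            continue
        try:
            t_global = register_global(
                study.ct_a, study.ct_b, bone_hu=config.bone_hu,
                iterations=config.registration_iterations,
            )
        except RegistrationError as exc:
            for rec in kept:
                exclusions.append(
                    {
                        "patient_id": rec.patient_id,
                        "lesion_id": rec.lesion_id,
                        "reason": f"global registration failed: {exc}",
                    }
                )
            continue
        for rec in kept:
            try:
                row, hu_rows, masks = _analyze_lesion(study, rec, config, t_global)
            except (SegmentationError, RegistrationError, ValueError) as exc:
                exclusions.append(
                    {
                        "patient_id": rec.patient_id,
                        "lesion_id": rec.lesion_id,
                        "reason": str(exc),
                    }
                )
                continue
            lesion_rows.append(row)
            hu_frames.append(hu_rows)
            roi_indices.update(masks)
            logger.info("lesion %s analyzed", rec.lesion_id)

    lesions = pd.DataFrame(lesion_rows)
    hu_table = (
        pd.concat(hu_frames, ignore_index=True) if hu_frames else pd.DataFrame()
    )
    if lesions.empty:
        raise RuntimeError("no lesion survived the pipeline")

    ov_by_level, t2, t3, corr, icc, lrt_p = _cohort_statistics(
        lesions, hu_table, config
    )
    result = StudyResult(
        lesions=lesions,
        hu_table=hu_table,
        ov_by_level=ov_by_level,
        table2_style=t2,
        table3_style=t3,
        correlations=corr,
        exclusions=pd.DataFrame(
            exclusions, columns=["patient_id", "lesion_id", "reason"]
        ),
        icc=icc,
        lrt_p=lrt_p,
        roi_voxel_indices=roi_indices,
    )
    if config.out_dir:
        result.write(config.out_dir)
    return result
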