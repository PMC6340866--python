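"""Spatial concordance measures on registered ROI triplets.

The central statistic is the overlap volume OV = |A ∩ B| / min(|A|, |B|):
the fraction of the smaller lesion volume shared with the other tracer's
volume.  Voxels of the union of the PSMA, NaF and CT ROIs are additionally
assigned to one of seven concordance categories (every non-empty membership
combination), and three distance measures quantify the separation of the
regions of highest uptake.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .segmentation import ROI
from .volume_io import LesionRecord, Volume

__all__ = [
    "CategoryMap",
    "ConcordanceResult",
    "CATEGORY_NAMES",
    "overlap_volume",
    "classify_voxels",
    "suvmax_distance",
    "centroid_distance",
    "average_pairwise_distance",
    "hu_by_category",
]

#: Category codes keyed by membership (in_psma, in_naf, in_ct).
CATEGORY_CODES = {
    (False, False, True): 1,
    (False, True, True): 2,
    (True, True, True): 3,
    (True, False, True): 4,
    (False, True, False): 5,
    (True, True, False): 6,
    (True, False, False): 7,
}

CATEGORY_NAMES = {
    0: "outside",
    1: "CT exclusive",
    2: "NaF-CT only",
    3: "all matching",
    4: "PSMA-CT only",
    5: "NaF exclusive",
    6: "PSMA-NaF only",
    7: "PSMA exclusive",
}


@dataclass
class CategoryMap:
    """Integer voxel labeling of the ROI-triplet union (codes 1-7, 0 outside)."""

    labels: np.ndarray
    affine: np.ndarray

    def counts(self) -> dict[int, int]:
        vals, cnts = np.unique(self.labels[self.labels > 0], return_counts=True)
        out = {code: 0 for code in range(1, 8)}
        out.update(dict(zip(vals.tolist(), cnts.tolist())))
        return out

    def union_size(self) -> int:
        return int((self.labels > 0).sum())


@dataclass
class ConcordanceResult:
    """Per-lesion concordance summary."""

    lesion_id: str
    ov: dict  # level -> OV of PSMA vs NaF (gradient/f60/f70/f80)
    ov_naf_ct: float
    ov_psma_ct: float
    d_suvmax_mm: float
    d_centroid80_mm: float
    d_pairwise80_mm: float
    suvmax_a: float
    suvmax_b: float
    hu_mean_ct_roi: float

    def __post_init__(self) -> None:
        for lvl, v in self.ov.items():
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"OV out of [0,1] at level {lvl}: {v}")


def _check_same_grid(*rois: ROI) -> None:
    first = rois[0]
    for r in rois[1:]:
        if r.mask.shape != first.mask.shape or not np.allclose(
            r.affine, first.affine, atol=1e-6
        ):
            raise ValueError("ROIs are not on the same grid")


def overlap_volume(a: ROI, b: ROI) -> float:
    """|a ∩ b| / min(|a|, |b|), by voxel count on the shared grid."""
    _check_same_grid(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 or nb == 0:
        raise ValueError("overlap volume of an empty mask is undefined")
    inter = int((a.mask & b.mask).sum())
    return inter / min(na, nb)


def classify_voxels(psma: ROI, naf: ROI, ct: ROI) -> CategoryMap:
    """Assign every union voxel to its concordance category."""
    _check_same_grid(psma, naf, ct)
    p, n, c = psma.mask, naf.mask, ct.mask
    # code lookup indexed by p*4 + n*2 + c
    table = np.zeros(8, dtype=np.int8)
    for (ip, inaf, ict), code in CATEGORY_CODES.items():
        table[ip * 4 + inaf * 2 + ict] = code
    labels = table[
        p.astype(np.int8) * 4 + n.astype(np.int8) * 2 + c.astype(np.int8)
    ]
    return CategoryMap(labels, psma.affine.copy())


def suvmax_distance(loc_a: Sequence[float], loc_b: Sequence[float]) -> float:
    """Euclidean distance (mm) between the two tracers' SUVmax locations."""
    return float(np.linalg.norm(np.asarray(loc_a, float) - np.asarray(loc_b, float)))


def centroid_distance(a: ROI, b: ROI) -> float:
    """Distance between unweighted voxel-center centroids, world mm."""
    _check_same_grid(a, b)
    if a.voxel_count == 0 or b.voxel_count == 0:
        raise ValueError("centroid of an empty mask is undefined")
    ca = a.world_coords().mean(axis=0)
    cb = b.world_coords().mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def average_pairwise_distance(
    a: ROI,
    b: ROI,
    max_pairs: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Mean Euclidean distance (mm) over all cross-mask voxel pairs.

    Masks whose pair count exceeds ``max_pairs`` are subsampled with a fixed
    seed so the estimate stays deterministic.
    """
    _check_same_grid(a, b)
    if a.voxel_count == 0 or b.voxel_count == 0:
        raise ValueError("pairwise distance of an empty mask is undefined")
    pa, pb = a.world_coords(), b.world_coords()
    if len(pa) * len(pb) > max_pairs:
        rng = np.random.default_rng(seed)
        cap = int(np.sqrt(max_pairs))
        if len(pa) > cap:
            pa = pa[rng.choice(len(pa), cap, replace=False)]
        if len(pb) > cap:
            pb = pb[rng.choice(len(pb), cap, replace=False)]
    return float(cdist(pa, pb).mean())


def hu_by_category(
    ct_a: Volume,
    ct_b: Volume,
    cmap: CategoryMap,
    lesion: LesionRecord,
) -> pd.DataFrame:
    """Long-format HU table: one row per union voxel per CT scan.

    Feeds the nested mixed model of HU by concordance category and the
    paired-scan ICC.  ``voxel_id`` is the flat index on the reference grid,
    shared between the two scans of one voxel.
    """
    if ct_a.data.shape != cmap.labels.shape or ct_b.data.shape != cmap.labels.shape:
        raise ValueError("CT volumes and category map are not on the same grid")
    sel = cmap.labels > 0
    flat_ids = np.flatnonzero(sel)
    cats = cmap.labels[sel]
    rows = []
    for scan, vol in (("A", ct_a), ("B", ct_b)):
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": lesion.patient_id,
                    "lesion_id": lesion.lesion_id,
                    "region": lesion.region,
                    "status": lesion.status,
                    "cohort": lesion.cohort,
                    "voxel_id": flat_ids,
                    "category": [CATEGORY_NAMES[c] for c in cats],
                    "scan": scan,
                    "hu": vol.data[sel],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
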