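import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petcoloc.colocalization import (
    CATEGORY_NAMES,
    average_pairwise_distance,
    centroid_distance,
    classify_voxels,
    hu_by_category,
    overlap_volume,
    suvmax_distance,
)
from petcoloc.segmentation import ROI
from petcoloc.volume_io import LesionRecord, Volume

AFF = np.diag([2.5, 2.5, 2.5, 1.0])


def roi_from(mask: np.ndarray, level: str = "gradient") -> ROI:
    return ROI(np.asarray(mask, bool), AFF, level)


def random_roi(rng: np.random.Generator, shape=(8, 8, 8), p=0.3) -> ROI:
    mask = rng.random(shape) < p
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    return roi_from(mask)


def brute_force_ov(a: ROI, b: ROI) -> float:
    sa = {tuple(i) for i in np.argwhere(a.mask)}
    sb = {tuple(i) for i in np.argwhere(b.mask)}
    return len(sa & sb) / min(len(sa), len(sb))


class TestOverlapVolume:
    def test_identical_masks_give_one(self):
        rng = np.random.default_rng(0)
        a = random_roi(rng)
        assert overlap_volume(a, a) == 1.0

    def test_disjoint_masks_give_zero(self):
        m1 = np.zeros((6, 6, 6), bool)
        m2 = np.zeros((6, 6, 6), bool)
        m1[:2], m2[4:] = True, True
        assert overlap_volume(roi_from(m1), roi_from(m2)) == 0.0

    def test_half_overlap_cube(self):
        """2x2x2 cube vs 4 shared + 4 outside voxels -> 4/8 = 0.5."""
        a = np.zeros((6, 6, 6), bool)
        a[0:2, 0:2, 0:2] = True
        b = np.zeros((6, 6, 6), bool)
        b[0:2, 0:2, 0] = True  # 4 voxels inside a
        b[4:6, 4:6, 4] = True  # 4 voxels outside a
        assert overlap_volume(roi_from(a), roi_from(b)) == 0.5

    def test_symmetry_and_range_random(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b = random_roi(rng), random_roi(rng)
            ov = overlap_volume(a, b)
            assert ov == overlap_volume(b, a)
            assert 0.0 <= ov <= 1.0
            assert ov == pytest.approx(brute_force_ov(a, b))

    def test_subset_iff_one(self):
        rng = np.random.default_rng(7)
        big = random_roi(rng, p=0.5)
        idx = np.argwhere(big.mask)
        sub = np.zeros_like(big.mask)
        sub[tuple(idx[: len(idx) // 2].T)] = True
        assert overlap_volume(roi_from(sub), big) == 1.0

    def test_empty_mask_rejected(self):
        a = roi_from(np.ones((4, 4, 4), bool))
        b = roi_from(np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError, match="empty"):
            overlap_volume(a, b)

    def test_grid_mismatch_rejected(self):
        a = roi_from(np.ones((4, 4, 4), bool))
        b = ROI(np.ones((4, 4, 4), bool), np.diag([2.0, 2.0, 2.0, 1.0]), "gradient")
        with pytest.raises(ValueError, match="grid"):
            overlap_volume(a, b)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_property(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_roi(rng), random_roi(rng)
        assert overlap_volume(a, b) == pytest.approx(brute_force_ov(a, b))


class TestClassifyVoxels:
    def test_membership_triples(self):
        shape = (3, 3, 3)
        p = np.zeros(shape, bool); p[0, 0, 0] = p[1, 1, 1] = True
        n = np.zeros(shape, bool); n[0, 0, 0] = n[2, 2, 2] = True
        c = np.zeros(shape, bool); c[0, 0, 0] = c[0, 1, 0] = True
        cmap = classify_voxels(roi_from(p), roi_from(n), roi_from(c))
        assert cmap.labels[0, 0, 0] == 3   # all matching
        assert cmap.labels[1, 1, 1] == 7   # PSMA exclusive
        assert cmap.labels[2, 2, 2] == 5   # NaF exclusive
        assert cmap.labels[0, 1, 0] == 1   # CT exclusive
        assert cmap.labels[1, 0, 0] == 0   # outside

    def test_counts_match_truth_table_tally(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p, n, c = (random_roi(rng, shape=(10, 10, 10)) for _ in range(3))
            cmap = classify_voxels(p, n, c)
            counts = cmap.counts()
            # independent 8-way tally over every voxel
            tally = {k: 0 for k in range(1, 8)}
            from petcoloc.colocalization import CATEGORY_CODES

            for idx in itertools.product(*(range(s) for s in p.mask.shape)):
                key = (bool(p.mask[idx]), bool(n.mask[idx]), bool(c.mask[idx]))
                if any(key):
                    tally[CATEGORY_CODES[key]] += 1
            assert counts == tally
            assert sum(counts.values()) == cmap.union_size()
            union = p.mask | n.mask | c.mask
            assert cmap.union_size() == int(union.sum())

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_union_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        p, n, c = (random_roi(rng, shape=(6, 6, 6), p=0.4) for _ in range(3))
        cmap = classify_voxels(p, n, c)
        assert sum(cmap.counts().values()) == int((p.mask | n.mask | c.mask).sum())


class TestDistances:
    def test_suvmax_distance_trivial(self):
        assert suvmax_distance((1.0, 2.0, 3.0), (1.0, 2.0, 3.0)) == 0.0
        assert suvmax_distance((0.0, 0.0, 0.0), (3.0, 4.0, 0.0)) == 5.0

    def test_suvmax_distance_anisotropic_spacing(self):
        """One voxel along x and one along z at PET spacing 2.73/2.73/3.27."""
        d = suvmax_distance((0.0, 0.0, 0.0), (2.73, 0.0, 3.27))
        assert d == pytest.approx(np.sqrt(2.73**2 + 3.27**2))
        assert d == pytest.approx(4.2600, abs=5e-4)

    def test_centroid_distance_identical_masks(self):
        rng = np.random.default_rng(1)
        a = random_roi(rng)
        assert centroid_distance(a, a) == 0.0

    def test_centroid_distance_single_voxels(self):
        a = np.zeros((5, 5, 5), bool); a[1, 1, 1] = True
        b = np.zeros((5, 5, 5), bool); b[2, 1, 1] = True
        assert centroid_distance(roi_from(a, "f80"), roi_from(b, "f80")) == pytest.approx(2.5)

    def test_centroid_matches_mean_of_coordinates(self):
        rng = np.random.default_rng(2)
        a, b = random_roi(rng), random_roi(rng)
        ca = (np.argwhere(a.mask) * 2.5).mean(axis=0)
        cb = (np.argwhere(b.mask) * 2.5).mean(axis=0)
        assert centroid_distance(a, b) == pytest.approx(np.linalg.norm(ca - cb), abs=1e-9)

    def test_pairwise_single_voxels_equal_point_distance(self):
        a = np.zeros((5, 5, 5), bool); a[0, 0, 0] = True
        b = np.zeros((5, 5, 5), bool); b[3, 4, 0] = True
        d = average_pairwise_distance(roi_from(a), roi_from(b))
        assert d == pytest.approx(2.5 * 5.0)
        assert average_pairwise_distance(roi_from(a), roi_from(a)) == 0.0

    def test_pairwise_matches_exhaustive_enumeration(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        pa = [(0, 0, 0), (1, 2, 0), (4, 4, 4)]
        pb = [(2, 2, 2), (0, 4, 1)]
        for v in pa:
            a[v] = True
        for v in pb:
            b[v] = True
        expected = np.mean(
            [
                np.linalg.norm((np.array(x) - np.array(y)) * 2.5)
                for x in pa
                for y in pb
            ]
        )
        assert average_pairwise_distance(roi_from(a), roi_from(b)) == pytest.approx(expected)

    def test_pairwise_subsampling_is_deterministic_and_close(self):
        rng = np.random.default_rng(9)
        a = random_roi(rng, shape=(12, 12, 12), p=0.5)
        b = random_roi(rng, shape=(12, 12, 12), p=0.5)
        exact = average_pairwise_distance(a, b)
        sub1 = average_pairwise_distance(a, b, max_pairs=10_000, seed=1)
        sub2 = average_pairwise_distance(a, b, max_pairs=10_000, seed=1)
        assert sub1 == sub2
        assert sub1 == pytest.approx(exact, rel=0.1)


class TestHuByCategory:
    def _setup(self):
        rng = np.random.default_rng(4)
        shape = (6, 6, 6)
        p, n, c = (random_roi(rng, shape=shape) for _ in range(3))
        cmap = classify_voxels(p, n, c)
        ct_a = Volume(rng.normal(300, 50, shape), AFF, "HU")
        ct_b = Volume(rng.normal(300, 50, shape), AFF, "HU")
        rec = LesionRecord("P01", "P01_L01", "ilium", "CRPC", "DCFBC", (0, 0, 0))
        return ct_a, ct_b, cmap, rec

    def test_row_count_is_two_scans_per_union_voxel(self):
        ct_a, ct_b, cmap, rec = self._setup()
        table = hu_by_category(ct_a, ct_b, cmap, rec)
        assert len(table) == 2 * cmap.union_size()
        assert set(table["scan"]) == {"A", "B"}

    def test_single_category_map(self):
        shape = (4, 4, 4)
        m = np.zeros(shape, bool)
        m[1:3, 1:3, 1:3] = True
        p = roi_from(m)
        empty = ROI(np.zeros(shape, bool), AFF, "ct", empty=True)
        n_empty = ROI(np.zeros(shape, bool), AFF, "gradient")
        cmap = classify_voxels(p, n_empty, empty)
        rng = np.random.default_rng(0)
        ct = Volume(rng.normal(size=shape), AFF, "HU")
        rec = LesionRecord("P", "L", "sacrum", "CSPC", "DCFPyL", (0, 0, 0))
        table = hu_by_category(ct, ct, cmap, rec)
        assert set(table["category"]) == {"PSMA exclusive"}

    def test_hu_values_match_volumes(self):
        ct_a, ct_b, cmap, rec = self._setup()
        table = hu_by_category(ct_a, ct_b, cmap, rec)
        row = table[table.scan == "A"].iloc[0]
        assert ct_a.data.ravel()[int(row.voxel_id)] == pytest.approx(row.hu)
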