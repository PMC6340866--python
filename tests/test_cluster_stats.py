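import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from petcoloc.cluster_stats import (
    GroupedLesionSample,
    PairedClusteredSample,
    clustered_signed_rank,
    fit_hu_mixed_model,
    paired_icc,
    patient_bootstrap_ci,
    patient_permutation_test,
    spearman_corr,
)


def grouped(pid, grp, val):
    return GroupedLesionSample.from_arrays(pid, grp, val)


def two_group_ids(n_a=6, n_b=13, lesions=5):
    pid = np.repeat(np.arange(n_a + n_b), lesions)
    grp = np.repeat(["CSPC"] * n_a + ["CRPC"] * n_b, lesions)
    return pid, grp


class TestClusteredSignedRank:
    def test_singleton_clusters_reduce_to_classical_wilcoxon(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=10)
        sample = PairedClusteredSample.from_arrays(np.arange(10), d, np.zeros(10))
        z, p = clustered_signed_rank(sample)
        ranks = st.rankdata(np.abs(d))
        T = float((np.sign(d) * ranks).sum())
        var = 10 * 11 * 21 / 6  # = 385, the classical variance
        assert z == pytest.approx(T / np.sqrt(var), abs=1e-12)
        assert p == pytest.approx(2 * st.norm.sf(abs(z)), abs=1e-12)

    def test_all_zero_differences(self):
        sample = PairedClusteredSample.from_arrays([1, 1, 2, 2], [3.0] * 4, [3.0] * 4)
        assert clustered_signed_rank(sample) == (0.0, 1.0)

    def test_single_cluster_rejected(self):
        sample = PairedClusteredSample.from_arrays([1, 1, 1], [1.0, 2.0, 3.0], [0.0] * 3)
        with pytest.raises(ValueError, match="two clusters"):
            clustered_signed_rank(sample)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=20)
        cid = np.repeat(np.arange(5), 4)
        z1, p1 = clustered_signed_rank(
            PairedClusteredSample.from_arrays(cid, d, np.zeros(20))
        )
        z2, p2 = clustered_signed_rank(
            PairedClusteredSample.from_arrays(cid, np.zeros(20), d)
        )
        assert z2 == pytest.approx(-z1)
        assert p2 == pytest.approx(p1)

    def test_detects_shift_with_intra_cluster_correlation(self):
        rng = np.random.default_rng(2)
        b = rng.normal(0, 0.5, size=15)
        d = 1.0 + b[:, None] + rng.normal(0, 0.5, size=(15, 6))
        cid = np.repeat(np.arange(15), 6)
        _, p = clustered_signed_rank(
            PairedClusteredSample.from_arrays(cid, d.ravel(), np.zeros(90))
        )
        assert p < 0.001


class TestPermutationTest:
    def test_seed_determinism(self):
        pid, grp = two_group_ids()
        rng = np.random.default_rng(0)
        val = rng.normal(size=len(pid))
        s = grouped(pid, grp, val)
        r1 = patient_permutation_test(s, n_perm=300, seed=5)
        r2 = patient_permutation_test(s, n_perm=300, seed=5)
        assert r1 == r2

    def test_invariant_to_lesion_ordering(self):
        pid, grp = two_group_ids()
        rng = np.random.default_rng(3)
        val = rng.normal(size=len(pid))
        order = rng.permutation(len(pid))
        s1 = grouped(pid, grp, val)
        s2 = grouped(pid[order], grp[order], val[order])
        _, p1 = patient_permutation_test(s1, n_perm=300, seed=9)
        _, p2 = patient_permutation_test(s2, n_perm=300, seed=9)
        assert p1 == p2

    def test_complete_separation_attains_minimum_p(self):
        pid, grp = two_group_ids()
        rng = np.random.default_rng(4)
        val = np.where(grp == "CSPC", 10 + rng.uniform(0, 1, len(pid)),
                       rng.uniform(0, 1, len(pid)))
        _, p = patient_permutation_test(grouped(pid, grp, val), n_perm=2000, seed=0)
        assert p == pytest.approx(1.0 / 2001.0)

    def test_patient_in_two_groups_rejected(self):
        with pytest.raises(ValueError, match="more than one group"):
            grouped([1, 1], ["CSPC", "CRPC"], [0.0, 1.0])

    def test_power_against_beta_shifted_groups(self):
        """Concordant vs discordant overlap distributions are separated with
        power > 0.8 at the 6-vs-13-patient cohort size."""
        rng = np.random.default_rng(11)
        pid, grp = two_group_ids()
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            val = np.where(
                grp == "CSPC",
                rng.beta(3.1, 1.9, len(pid)),   # mean 0.62
                rng.beta(1.1, 3.9, len(pid)),   # mean 0.22
            )
            _, p = patient_permutation_test(
                grouped(pid, grp, val), n_perm=499, seed=int(rng.integers(2**31))
            )
            rejections += p < 0.05
        assert rejections / n_rep > 0.8


class TestBootstrap:
    def test_constant_data_gives_degenerate_ci(self):
        pid, grp = two_group_ids()
        s = grouped(pid, grp, np.full(len(pid), 3.3))
        se, (lo, hi) = patient_bootstrap_ci(
            s, lambda v, p: float(np.mean(v)), n_boot=200, seed=0
        )
        assert se == 0.0
        assert lo == pytest.approx(3.3) and hi == pytest.approx(3.3)

    def test_seed_determinism(self):
        pid, grp = two_group_ids()
        rng = np.random.default_rng(1)
        s = grouped(pid, grp, rng.normal(size=len(pid)))
        fn = lambda v, p: float(np.median(v))
        r1 = patient_bootstrap_ci(s, fn, n_boot=150, seed=7)
        r2 = patient_bootstrap_ci(s, fn, n_boot=150, seed=7)
        assert r1 == r2

    def test_single_patient_rejected(self):
        s = grouped([1, 1, 1], ["CSPC"] * 3, [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="two patients"):
            patient_bootstrap_ci(s, lambda v, p: float(np.mean(v)), n_boot=10, seed=0)


class TestIcc:
    def test_noiseless_pairs_give_icc_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 3, 500)
        assert paired_icc(a, a) >= 0.999

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(6)
        n = 50 * 200
        mu = rng.normal(0, 3.0, n)          # between-voxel sd 3 -> var 9
        a = mu + rng.normal(0, 1.0, n)      # residual var 1
        b = mu + rng.normal(0, 1.0, n)
        assert paired_icc(a, b) == pytest.approx(0.9, abs=0.03)

    def test_independent_pairs_give_icc_near_zero(self):
        rng = np.random.default_rng(7)
        assert abs(paired_icc(rng.normal(size=2000), rng.normal(size=2000))) < 0.1


def simulate_hu_table(seed=0, n_patients=8, n_lesions=4, n_vox=40,
                      offsets=None):
    """Category-structured HU data with patient and lesion random effects."""
    offsets = offsets or {
        "CT exclusive": 40.0,
        "all matching": 0.0,
        "PSMA-CT only": -30.0,
        "NaF exclusive": -180.0,
        "PSMA-NaF only": -200.0,
        "PSMA exclusive": -270.0,
    }
    rng = np.random.default_rng(seed)
    cats = list(offsets)
    rows = []
    for p in range(n_patients):
        bp = rng.normal(0, 30)
        for l in range(n_lesions):
            bl = rng.normal(0, 20)
            for v in range(n_vox):
                cat = cats[int(rng.integers(len(cats)))]
                base = 500 + bp + bl + offsets[cat]
                for scan in ("A", "B"):
                    rows.append(
                        {
                            "patient_id": f"P{p}",
                            "lesion_id": f"P{p}_L{l}",
                            "region": "ilium",
                            "cohort": "DCFBC",
                            "voxel_id": p * 10_000 + l * 1000 + v,
                            "category": cat,
                            "scan": scan,
                            "hu": base + rng.normal(0, 25),
                        }
                    )
    return pd.DataFrame(rows), offsets


class TestHuMixedModel:
    def test_category_offsets_recovered_within_two_se(self):
        table, offsets = simulate_hu_table(seed=3)
        res = fit_hu_mixed_model(table)
        assert res.reference_category == "all matching"
        for cat, true_off in offsets.items():
            if cat == "all matching":
                continue
            est, se = res.fixed_effects[cat], res.fixed_se[cat]
            assert abs(est - true_off) < 2 * se, (cat, est, true_off, se)
        assert res.lrt_p < 1e-6

    def test_icc_reported_from_paired_scans(self):
        table, _ = simulate_hu_table(seed=4)
        res = fit_hu_mixed_model(table)
        # per-voxel base varies across categories/patients, residual sd 25
        assert 0.5 < res.icc <= 1.0

    def test_single_category_rejected(self):
        table, _ = simulate_hu_table(seed=5)
        only = table[table.category == "all matching"]
        with pytest.raises(ValueError, match="two concordance categories"):
            fit_hu_mixed_model(only)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10, dtype=float)
        rho, _ = spearman_corr(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_corr(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_five_points(self):
        x = [10.0, 20.0, 30.0, 40.0, 50.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        # ranks of y: 1,3,2,5,4 ; d = (0,1,-1,1,-1); rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman_corr(x, y)
        assert rho == pytest.approx(0.8)

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
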