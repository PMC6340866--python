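"""Clustered statistical inference for lesion-level data.

Lesions are nested within patients, so naive tests that treat lesions as
independent are anti-conservative.  This module provides the
cluster-respecting tools used by the pipeline:

* a clustered Wilcoxon signed-rank test (Rosner–Glynn–Lee construction:
  signed ranks are pooled across all observations, the variance of their sum
  is estimated from within-cluster signed-rank sums, and the statistic is
  normal-referenced);
* a patient-level permutation test for two-group comparisons (whole patients
  swap group labels);
* a patient-level bootstrap for standard errors and percentile CIs;
* a nested linear mixed model of voxel HU by concordance category with a
  paired-scan ICC as a registration-quality surrogate;
* Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "PairedClusteredSample",
    "GroupedLesionSample",
    "HuModelResult",
    "clustered_signed_rank",
    "patient_permutation_test",
    "patient_bootstrap_ci",
    "paired_icc",
    "fit_hu_mixed_model",
    "spearman_corr",
]


@dataclass(frozen=True)
class PairedClusteredSample:
    """Paired observations with a cluster (patient) id per observation."""

    cluster_id: tuple
    value_a: tuple
    value_b: tuple

    @classmethod
    def from_arrays(
        cls, cluster_id: Sequence, value_a: Sequence[float], value_b: Sequence[float]
    ) -> "PairedClusteredSample":
        a = np.asarray(value_a, float)
        b = np.asarray(value_b, float)
        cid = np.asarray(cluster_id)
        if not (len(a) == len(b) == len(cid)):
            raise ValueError("cluster_id, value_a, value_b must have equal length")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("values must be finite")
        return cls(tuple(cid.tolist()), tuple(a.tolist()), tuple(b.tolist()))

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.value_a, float) - np.asarray(self.value_b, float)


@dataclass(frozen=True)
class GroupedLesionSample:
    """Per-lesion values with patient id and a two-level group label."""

    patient_id: tuple
    group: tuple
    value: tuple

    @classmethod
    def from_arrays(
        cls, patient_id: Sequence, group: Sequence[str], value: Sequence[float]
    ) -> "GroupedLesionSample":
        pid = np.asarray(patient_id)
        grp = np.asarray(group)
        val = np.asarray(value, float)
        if not (len(pid) == len(grp) == len(val)):
            raise ValueError("patient_id, group, value must have equal length")
        # every patient must sit in exactly one group
        df = pd.DataFrame({"p": pid, "g": grp})
        if (df.groupby("p")["g"].nunique() > 1).any():
            raise ValueError("a patient appears in more than one group")
        return cls(tuple(pid.tolist()), tuple(grp.tolist()), tuple(val.tolist()))


def clustered_signed_rank(sample: PairedClusteredSample) -> tuple[float, float]:
    """Clustered Wilcoxon signed-rank test; returns (z, two-sided p).

    Zero differences are dropped (Wilcoxon convention) and ties in |d|
    receive average ranks.  T is the sum of signed ranks; its variance is
    estimated as the sum over clusters of the squared within-cluster
    signed-rank sum, which reduces to the classical normal-approximation
    variance n(n+1)(2n+1)/6 when every cluster holds a single observation.
    """
    d = sample.differences
    cid = np.asarray(sample.cluster_id)
    nz = d != 0
    if not nz.any():
        return 0.0, 1.0
    d, cid = d[nz], cid[nz]
    if len(np.unique(cid)) < 2:
        raise ValueError("need at least two clusters with nonzero differences")
    ranks = stats.rankdata(np.abs(d))
    signed = np.sign(d) * ranks
    T = float(signed.sum())
    var = 0.0
    for c in np.unique(cid):
        var += float(signed[cid == c].sum()) ** 2
    if var <= 0:
        return 0.0, 1.0
    z = T / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def _median_difference(values: np.ndarray, groups: np.ndarray, labels: tuple) -> float:
    a, b = labels
    return float(np.median(values[groups == a]) - np.median(values[groups == b]))


def patient_permutation_test(
    sample: GroupedLesionSample,
    n_perm: int = 2000,
    seed: int = 0,
    stat_fn: Callable[[np.ndarray, np.ndarray, tuple], float] = _median_difference,
) -> tuple[float, float]:
    """Two-group comparison by permuting group labels at the patient level.

    All lesions of one patient move together.  The default statistic is the
    difference of group medians of lesion-level values.  Returns
    (observed statistic, p) with ``p = (1 + #{|perm| >= |obs|}) / (n_perm + 1)``.
    """
    pid = np.asarray(sample.patient_id)
    grp = np.asarray(sample.group)
    val = np.asarray(sample.value, float)
    labels = tuple(pd.unique(grp))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    patients = np.sort(pd.unique(pid))  # canonical order: invariant to input ordering
    pat_group = np.array([grp[pid == p][0] for p in patients])
    if (pat_group == labels[0]).sum() == 0 or (pat_group == labels[1]).sum() == 0:
        raise ValueError("both groups must contain at least one patient")

    obs = stat_fn(val, grp, labels)
    rng = np.random.default_rng(seed)
    pat_index = {p: np.flatnonzero(pid == p) for p in patients}
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pat_group)
        perm_groups = np.empty(len(val), dtype=grp.dtype)
        for p, g in zip(patients, perm):
            perm_groups[pat_index[p]] = g
        if abs(stat_fn(val, perm_groups, labels)) >= abs(obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return obs, float(p)


def patient_bootstrap_ci(
    sample: GroupedLesionSample,
    stat_fn: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Patient-level bootstrap SE and percentile CI for ``stat_fn``.

    Patients are resampled with replacement and all their lesions kept;
    ``stat_fn(values, patient_ids)`` is evaluated on each resample.
    """
    pid = np.asarray(sample.patient_id)
    val = np.asarray(sample.value, float)
    patients = np.sort(pd.unique(pid))
    if len(patients) < 2:
        raise ValueError("bootstrap needs at least two patients")
    pat_index = {p: np.flatnonzero(pid == p) for p in patients}
    rng = np.random.default_rng(seed)
    stats_out = np.empty(n_boot)
    for b in range(n_boot):
        chosen = rng.choice(patients, size=len(patients), replace=True)
        idx = np.concatenate([pat_index[p] for p in chosen])
        # re-label duplicated patients so downstream grouping stays valid
        pids = np.concatenate(
            [np.full(len(pat_index[p]), f"{p}~{j}") for j, p in enumerate(chosen)]
        )
        stats_out[b] = stat_fn(val[idx], pids)
    alpha = 1.0 - level
    lo, hi = np.quantile(stats_out, [alpha / 2, 1 - alpha / 2])
    return float(stats_out.std(ddof=1)), (float(lo), float(hi))


def paired_icc(a: Sequence[float], b: Sequence[float]) -> float:
    """One-way random-effects ICC(1,1) for paired measurements.

    Decomposes paired-scan HU into a between-voxel and a residual variance
    component (the balanced two-replicate ANOVA estimator, identical to the
    REML solution of a random-intercept-per-voxel model):
    ``ICC = (MSB - MSW) / (MSB + MSW)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two aligned measurement vectors, length >= 2")
    n = len(a)
    pair_mean = (a + b) / 2.0
    grand = pair_mean.mean()
    msb = 2.0 * np.sum((pair_mean - grand) ** 2) / (n - 1)
    msw = np.sum((a - b) ** 2 / 2.0) / n
    denom = msb + msw
    if denom <= 0:
        return 1.0
    return float((msb - msw) / denom)


@dataclass
class HuModelResult:
    """Nested mixed-model summary of voxel HU by concordance category."""

    fixed_effects: pd.Series          # category offsets vs the reference
    fixed_se: pd.Series
    reference_category: str
    intercept: float
    lrt_p: float
    icc: float
    converged: bool
    n_obs: int


def fit_hu_mixed_model(
    table: pd.DataFrame,
    reference_category: str = "all matching",
) -> HuModelResult:
    """Linear mixed model of voxel HU with nested random intercepts.

    Fixed effects: concordance category (treatment-coded against the
    triple-overlap reference) plus skeletal region and tracer cohort as
    covariates when they vary.  Random effects: intercepts for patient and
    for lesion within patient.  The category effect is tested by a
    likelihood-ratio test against the no-category model (ML fits).  The
    companion paired-scan ICC is computed from the two scans' HU per voxel.

    Skeletal region and tracer cohort enter as fixed covariates rather than
    random effects: with a handful of levels each, variance components for
    them are not estimable with any stability.
    """
    required = {"patient_id", "lesion_id", "category", "scan", "voxel_id", "hu"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"HU table missing columns: {sorted(missing)}")
    cats = table["category"].unique()
    if len(cats) < 2:
        raise ValueError("need at least two concordance categories")
    if reference_category not in cats:
        # fall back to the largest category so the contrast stays defined
        reference_category = table["category"].value_counts().idxmax()

    df = table.copy()
    df["lesion_key"] = df["patient_id"].astype(str) + "/" + df["lesion_id"].astype(str)

    terms = [f"C(category, Treatment('{reference_category}'))"]
    for cov in ("region", "cohort"):
        if cov in df.columns and df[cov].nunique() > 1:
            terms.append(f"C({cov})")
    formula = "hu ~ " + " + ".join(terms)
    null_formula = "hu ~ " + " + ".join(terms[1:]) if terms[1:] else "hu ~ 1"

    vc = {"lesion": "0 + C(lesion_key)"}
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = MixedLM.from_formula(
            formula, groups="patient_id", vc_formula=vc, re_formula="1", data=df
        ).fit(reml=False, method="lbfgs", maxiter=200)
        null = MixedLM.from_formula(
            null_formula, groups="patient_id", vc_formula=vc, re_formula="1", data=df
        ).fit(reml=False, method="lbfgs", maxiter=200)

    lrt = 2.0 * (full.llf - null.llf)
    df_diff = len(cats) - 1
    lrt_p = float(stats.chi2.sf(max(lrt, 0.0), df_diff))

    prefix = f"C(category, Treatment('{reference_category}'))[T."
    fe = {}
    se = {}
    for name, coef in full.fe_params.items():
        if name.startswith(prefix):
            cat = name[len(prefix):-1]
            fe[cat] = float(coef)
            se[cat] = float(full.bse[name])

    # paired-scan ICC on voxels measured by both CTs
    wide = df.pivot_table(
        index=["patient_id", "lesion_id", "voxel_id"], columns="scan", values="hu"
    ).dropna()
    icc = paired_icc(wide["A"].values, wide["B"].values) if {"A", "B"} <= set(
        wide.columns
    ) and len(wide) >= 2 else float("nan")

    return HuModelResult(
        fixed_effects=pd.Series(fe),
        fixed_se=pd.Series(se),
        reference_category=reference_category,
        intercept=float(full.fe_params.get("Intercept", np.nan)),
        lrt_p=lrt_p,
        icc=icc,
        converged=bool(full.converged),
        n_obs=len(df),
    )


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; (rho, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
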