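"""Shared fixtures: analytic volumes and one full phantom-cohort run.

The cohort run (6 castration-sensitive + 13 castration-resistant patients,
5 lesions each) is expensive, so it is computed once per session and shared
by the end-to-end, nesting and ground-truth-correlation tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from petcoloc.pipeline import StudyConfig, run_study
from petcoloc.synthetic_phantom import generate_cohort
from petcoloc.volume_io import Volume

COHORT_SEED = 7041


def gaussian_blob_volume(
    sigma_mm: float = 4.0,
    spacing: float = 2.5,
    shape: tuple[int, int, int] = (48, 48, 48),
    center_mm: tuple[float, float, float] | None = None,
    peak: float = 10.0,
    background: float = 0.0,
) -> tuple[Volume, np.ndarray]:
    """Noiseless isotropic Gaussian uptake blob; returns (volume, center)."""
    affine = np.diag([spacing, spacing, spacing, 1.0])
    axes = [np.arange(n) * spacing for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    if center_mm is None:
        center_mm = tuple((np.array(shape) - 1) * spacing / 2.0)
    c = np.asarray(center_mm, float)
    r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
    data = background + peak * np.exp(-r2 / (2.0 * sigma_mm**2))
    return Volume(data, affine, "SUV"), c


@pytest.fixture(scope="session")
def cohort_config() -> StudyConfig:
    return StudyConfig(cohort_seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_result(cohort_config):
    """Full pipeline run on the default two-group phantom cohort."""
    return run_study(cohort_config)


@pytest.fixture(scope="session")
def cohort_truth(cohort_config):
    """Ground-truth lesion records of the same cohort, keyed by lesion id."""
    studies = generate_cohort(
        cohort_config.phantom,
        cohort_config.n_cspc,
        cohort_config.n_crpc,
        cohort_config.cohort_seed,
    )
    return {t.lesion_id: t for s in studies for t in s.truth}
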