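"""Shared fixtures: calibrated simulated arteries and a small cohort.

Calibration costs ~1 s per artery, so ground-truth objects are built once
per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from arterymech.cohort import CohortConfig, GroupSpec, generate_cohort
from arterymech.simulate import default_artery


@pytest.fixture(scope="session")
def wt_artery():
    """Control-like artery calibrated to ground-truth IVS 1.85."""
    return default_artery(ivs_target=1.85, seed=1)


@pytest.fixture(scope="session")
def stiff_artery():
    """Stiffened artery (2x collagen-like fiber stiffness), IVS 1.79."""
    return default_artery(ivs_target=1.79, fiber_multiplier=2.0, seed=2)


@pytest.fixture(scope="session")
def small_cohort():
    """Two groups x 4 samples with biological jitter and instrument noise."""
    config = CohortConfig(
        groups=[
            GroupSpec(name="control", n=4, ivs_target=1.85),
            GroupSpec(name="stiff", n=4, fiber_multiplier=2.0, ivs_target=1.79),
        ],
        seed=42,
        geometry_jitter_frac=0.03,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    small_cohort.write(d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
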