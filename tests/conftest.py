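"""Shared fixtures.

Heavyweight objects (stimulus runs, IRF/HRF kernels, simulated datasets)
are session-scoped so the expensive forward simulations run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from stprf import prf_models as pm
from stprf.hemodynamics import HRFParams, double_gamma_hrf
from stprf.stimulus import RunDesign, generate_seqsim_pair, generate_seqsim_run
from stprf.synthetic import AreaProfile, sample_population, simulate_dataset


@pytest.fixture(scope="session")
def design():
    return RunDesign(seed=7)


@pytest.fixture(scope="session")
def run0(design):
    return generate_seqsim_run(design, 0)


@pytest.fixture(scope="session")
def run_pair(design):
    return generate_seqsim_pair(design)


@pytest.fixture(scope="session")
def hrf_kernel():
    return double_gamma_hrf(HRFParams())


@pytest.fixture(scope="session")
def irf_kernels():
    return pm.make_temporal_irfs()


@pytest.fixture(scope="session")
def lss_null_dataset():
    """Onset-matched single-square LSS population: the linear-summation null."""
    design = RunDesign(seed=7, onset_matched=True)
    records = []
    for p in range(3):
        profile = AreaProfile(
            name="V1null",
            model="lss",
            n_voxels=40,
            sigma_range=(0.05, 0.2),
            center_square=0,
            gain_range=(0.5, 2.0),
        )
        records.extend(sample_population(profile, seed=100 + p, participant=f"S{p + 1}"))
    return simulate_dataset(records, design, target_reliability=0.98, seed=11)


@pytest.fixture(scope="session")
def cst_noiseless_dataset():
    """Small noiseless population generated by the spatiotemporal model."""
    design = RunDesign(seed=7)
    profile = AreaProfile(
        name="id",
        model="cst",
        n_voxels=8,
        sigma_range=(2.0, 6.0),
        exponent_range=(0.45, 0.45),
    )
    records = sample_population(profile, seed=5, participant="S1")
    return simulate_dataset(records, design, target_reliability=1.0, seed=5)
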