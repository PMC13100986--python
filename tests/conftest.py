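"""Shared fixtures.

Heavy simulation studies are session-scoped so the acceptance-style checks
and unit-level assertions reuse one simulation run each. The base seed is
fixed: every test is deterministic.
"""

import numpy as np
import pytest

from fcskit.simulate import (DetectionSpec, SimConfig, SpeciesSpec,
                             simulate_photon_stream)

BASE_SEED = 7


@pytest.fixture(scope="session")
def small_stream():
    """A cheap single-species Brownian stream reused by several tests."""
    det = DetectionSpec(r0=0.25, w=2.0)
    sp = SpeciesSpec("green_only", n_particles=310, D=25.0,
                     brightness_green=150e3)
    cfg = SimConfig(species=[sp], detection=det, box_side=6 * det.z0,
                    dt=40e-6, duration=4.0, seed=BASE_SEED)
    return cfg, simulate_photon_stream(cfg)


@pytest.fixture(scope="session")
def dual_stream():
    """A bright dual-labeled stream for channel-correlation checks."""
    det = DetectionSpec(r0=0.25, w=2.0)
    sp = SpeciesSpec("dual", n_particles=50, D=25.0,
                     brightness_green=1e6, brightness_red=1e6)
    cfg = SimConfig(species=[sp], detection=det, box_side=6 * det.z0,
                    dt=40e-6, duration=3.0, seed=BASE_SEED + 1)
    return cfg, simulate_photon_stream(cfg)


@pytest.fixture(scope="session")
def recovery_df():
    from fcskit.studies import recovery_study
    return recovery_study(n_seeds=5, seed=BASE_SEED)


@pytest.fixture(scope="session")
def anomalous_df():
    from fcskit.studies import anomalous_recovery_study
    return anomalous_recovery_study(n_seeds=5, seed=BASE_SEED)


@pytest.fixture(scope="session")
def calibration_df():
    from fcskit.studies import calibration_study
    return calibration_study(n_seeds=5, seed=BASE_SEED)


@pytest.fixture(scope="session")
def mixture_df():
    from fcskit.studies import mixture_ratio_study
    return mixture_ratio_study(n_seeds=3, seed=BASE_SEED)


@pytest.fixture(scope="session")
def crosstalk_df():
    from fcskit.studies import crosstalk_study
    return crosstalk_study(n_seeds=2, seed=BASE_SEED)


@pytest.fixture(scope="session")
def monomer_pool():
    from fcskit.studies import simulate_cohort
    return simulate_cohort(n_cells=20, f_dual=0.0, seed=BASE_SEED)


@pytest.fixture(scope="session")
def oligomer_pool():
    from fcskit.studies import simulate_cohort
    return simulate_cohort(n_cells=8, f_dual=0.8, seed=BASE_SEED + 2)
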