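import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netrack import MotionModel, SimConfig
from netrack.simulate import photon_budget_for_snr, simulate_ne_movie

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def eval_scenario(seed: int, n_aggregates: int = 4, snr: float = 12.0) -> tuple[SimConfig, MotionModel]:
    """Well-separated mobile foci at the default acquisition geometry.

    The standard parameter-recovery condition: medium foci (0.5-0.8 µm) whose
    initial peak SNR is set analytically, so that photobleaching over the
    15 min movie keeps every spot above SNR ~5; motion mixes 190 nm/s runs
    with slow surface diffusion; no fusion or splitting.
    """
    cfg = SimConfig(
        aggregates_per_nucleus=(n_aggregates, n_aggregates),
        aggregate_diameter_um=(0.5, 0.8),
        seed=seed,
    )
    cfg = dataclasses.replace(cfg, photon_budget=photon_budget_for_snr(cfg, snr, 0.5))
    motion = MotionModel(
        run_speed_nm_s=190.0,
        pause_fraction=0.35,
        run_persistence_s=20.0,
        diffusion_um2_s=2e-4,
    )
    return cfg, motion


@pytest.fixture(scope="session")
def eval_movie():
    """One simulated movie + ground truth under the recovery condition."""
    cfg, motion = eval_scenario(seed=5)
    movie, gt = simulate_ne_movie(cfg, motion)
    return cfg, motion, movie, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
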