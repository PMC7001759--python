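"""Shared synthetic fixtures.

Heavy fixtures (the 600 s random-walk track and the tuned spike trains on
it) are session-scoped: they are deterministic pure functions of their
seeds, so sharing them across tests changes nothing but runtime.
"""

import numpy as np
import pytest

from spikespatial import synthetic as syn

ARENA = syn.ArenaSpec(shape="square", extent=100.0, rate=50.0, duration=600.0)

PLACE_GT = syn.GroundTruth(kind="place", centre=(15.0, -10.0), width=10.0,
                           peak_rate=12.0, baseline=0.3)
HD_GT = syn.GroundTruth(kind="hd", preferred_direction=120.0, kappa=2.0,
                        peak_rate=12.0, baseline=0.0)
GRID_GT = syn.GroundTruth(kind="grid", spacing=40.0, orientation=0.0,
                          peak_rate=15.0, baseline=0.2)
BORDER_GT = syn.GroundTruth(kind="border", decay=10.0, peak_rate=12.0,
                            baseline=0.2)
SPEED_GT = syn.GroundTruth(kind="speed", slope=0.3, baseline=1.0,
                           peak_rate=30.0)
UNIFORM_GT = syn.GroundTruth(kind="uniform", peak_rate=10.0)


@pytest.fixture(scope="session")
def track600():
    return syn.simulate_trajectory(ARENA, seed=1)


def _train(track, gt, seed):
    return syn.simulate_from_rate(track, syn.rate_function(gt), seed=seed)


@pytest.fixture(scope="session")
def place_train(track600):
    return _train(track600, PLACE_GT, seed=11)


@pytest.fixture(scope="session")
def hd_train(track600):
    return _train(track600, HD_GT, seed=12)


@pytest.fixture(scope="session")
def grid_train(track600):
    return _train(track600, GRID_GT, seed=13)


@pytest.fixture(scope="session")
def border_train(track600):
    return _train(track600, BORDER_GT, seed=14)


@pytest.fixture(scope="session")
def speed_train(track600):
    return _train(track600, SPEED_GT, seed=15)


@pytest.fixture(scope="session")
def uniform_train(track600):
    return _train(track600, UNIFORM_GT, seed=16)


@pytest.fixture(scope="session")
def theta_pair():
    """Theta-locked unit and LFP: phase 195 deg, kappa 4, 8 Hz."""
    return syn.simulate_theta_unit_and_lfp(duration=120.0, theta_f=8.0,
                                           locking_phase=195.0,
                                           locking_kappa=4.0, mean_rate=10.0,
                                           seed=4)
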