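import numpy as np
import pytest
from hypothesis import settings

from morphodyn.simulate import (
    HiddenStateSimSpec,
    MovieSimSpec,
    render_movie,
    simulate_feature_trajectories,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def easy_movie():
    """Sparse, slowly-moving cells without divisions: the easy tracking regime."""
    spec = MovieSimSpec(
        image_size=(192, 192),
        n_cells=5,
        cell_radius_mean=7.0,
        motion_sd_px=2.0,
        division_prob=0.0,
        background_noise_sd=0.05,
        n_frames=12,
        seed=42,
    )
    images, masks, truth = render_movie(spec)
    return spec, images, masks, truth


@pytest.fixture(scope="session")
def two_state_sim():
    """Persistent 2-state hidden-Markov feature trajectories (well separated)."""
    spec = HiddenStateSimSpec(
        n_states=2,
        state_means=[[-2.0], [2.0]],
        relaxation_rate=1.0,
        noise_sd=0.2,
        transition_matrix=[[0.85, 0.15], [0.1, 0.9]],
        n_cells=500,
        n_frames=201,
        seed=5,
    )
    traj, truth = simulate_feature_trajectories(spec)
    return spec, traj, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
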