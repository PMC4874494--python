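"""Shared fixtures: rendered synthetic phantoms (expensive, session-scoped)."""

import numpy as np
import pytest

from niqa.pipeline import run_volumes
from niqa.synthetic_phantom import Bubble, PhantomConfig, render_noiseless


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free default phantom."""
    return PhantomConfig(ct_noise_sd_hu=0.0, pet_noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_truth(clean_config):
    return render_noiseless(clean_config)


@pytest.fixture(scope="session")
def noisy_base_truth():
    """Default (noisy) config rendered once; realizations add seeded noise."""
    return render_noiseless(PhantomConfig())


@pytest.fixture(scope="session")
def bubbled_truth():
    """Noise-free phantom with air bubbles in spheres 2-5 (largest and
    smallest spheres left bubble-free, like the paper-style position C)."""
    cfg = PhantomConfig(
        ct_noise_sd_hu=0.0,
        pet_noise_sd=0.0,
        bubbles=(
            Bubble(2, 4.0),
            Bubble(3, 5.0),
            Bubble(4, 6.0),
            Bubble(5, 8.0),
        ),
    )
    return render_noiseless(cfg)


@pytest.fixture(scope="session")
def clean_result(clean_truth):
    """Full pipeline run on the noise-free fixture."""
    return run_volumes(clean_truth.pet_noiseless, ct=clean_truth.ct_noiseless)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
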