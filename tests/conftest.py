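"""Shared fixtures: small protomers, filaments and smooth test volumes."""

import numpy as np
import pytest

from helixsub.core import VolumeGrid
from helixsub.scene import (
    assemble_filament,
    build_protomer,
    default_protomer,
    render_volume,
    sample_pitch_profile,
)

PIXEL = 3.0  # Å/px used by most small fixtures


@pytest.fixture(scope="session")
def protomer():
    return default_protomer()


@pytest.fixture(scope="session")
def protomer_volume(protomer):
    return build_protomer(protomer, 48, PIXEL)


@pytest.fixture(scope="session")
def constant_filament(protomer):
    profile = sample_pitch_profile(
        (47.2, 47.2), (26.75, 26.75), "constant", 10, np.random.default_rng(0)
    )
    return assemble_filament(protomer, profile, 45.0)


@pytest.fixture(scope="session")
def constant_filament_volume(constant_filament):
    return render_volume(constant_filament, 96, 4.5, clip_tolerance=1.0)


@pytest.fixture(scope="session")
def smooth_compact_volume():
    """Random smooth density with compact (apodized) support."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(7)
    n = 48
    data = gaussian_filter(rng.normal(size=(n, n, n)), 3.5)
    zz, yy, xx = np.indices((n, n, n)) - n / 2
    r = np.sqrt(zz**2 + yy**2 + xx**2)
    apod = 0.5 - 0.5 * np.cos(np.pi * np.clip((n / 2 - 4 - r) / 6, 0, 1))
    return VolumeGrid(data * apod, PIXEL)
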