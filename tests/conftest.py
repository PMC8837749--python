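"""Shared fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neuroscreen.imaging import SegmentationParams
from neuroscreen.synth import OpticsParams, make_field_truth, render_field

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_optics() -> OpticsParams:
    """Noise-free optics: no read noise, no shot noise, no blur."""
    return OpticsParams(noise_sd=0.0, shot_noise=False, psf_sigma=0.0)


@pytest.fixture(scope="session")
def params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def planted_field(clean_optics):
    """One noise-free field with every object type planted, plus its image."""
    truth = make_field_truth(
        n_cells=10,
        optics=clean_optics,
        seed=21,
        frac_th=0.5,
        frac_marker_positive=0.3,
        neurites_per_cell=2,
        n_fragments=2,
        n_aggregates=2,
        n_mcherry_puncta=3,
        n_gfp_puncta=2,
    )
    return truth, render_field(truth)


def assert_close(a, b, tol=1e-9):
    assert abs(a - b) <= tol, f"{a} != {b} (tol {tol})"
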