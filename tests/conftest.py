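import numpy as np
import pytest

from isletquant.synthgen import GeometryParams, IntensityModel, generate_truth, render_image, render_probability_map


@pytest.fixture(scope="session")
def small_geometry() -> GeometryParams:
    """Compact field that keeps segmentation tests fast."""
    return GeometryParams(field_shape=(256, 256), islet_radius_px=100.0, n_cells=10)


@pytest.fixture(scope="session")
def noiseless_model() -> IntensityModel:
    return IntensityModel(cell_level_cv=0.0, gaussian_noise_sd=0.0, background_level=0.0)


@pytest.fixture(scope="session")
def noiseless_field(small_geometry, noiseless_model):
    """(truth, image, probability map) for one clean small field."""
    truth = generate_truth(small_geometry, seed=11)
    image = render_image(truth, noiseless_model, seed=12)
    prob_map = render_probability_map(truth, blur_sigma_px=5, noise_sd=0, seed=13)
    return truth, image, prob_map
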