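import numpy as np
import pytest

from octstiff.biomech import AirJetProtocol
from octstiff.phantom import PhantomConfig, generate_series


def small_phantom_config(k_true=1.0, seed=0, **overrides):
    """96x96 phantom at 15 um axial pitch (1.44 mm depth budget)."""
    kwargs = dict(image_height_px=96, image_width_px=96, axial_pitch_um=15.0,
                  sc_top_depth_mm=0.3, sc_thickness_mm=0.2,
                  k_true_n_per_mm=k_true, seed=seed)
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def sweep_protocol():
    """5/5/5 s protocol at 80 kPa: largest sweep dent fits the small raster."""
    return AirJetProtocol(pressure_pa=80_000.0)


@pytest.fixture(scope="session")
def small_series(sweep_protocol):
    """One deforming phantom series with truth, shared across read-only tests."""
    return generate_series(small_phantom_config(k_true=1.0, seed=7), sweep_protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
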