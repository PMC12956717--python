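import numpy as np
import pytest

from ctquant import phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The full noiseless thorax phantom (seed 7), generated once per session."""
    spec = phantom.default_spec(seed=7)
    volume, truth = phantom.generate_phantom(spec)
    return volume, truth, spec


def mini_spec(seed=0, emphysema_fraction=0.30, noise_sd=0.0):
    """A small, fast phantom: one lung, one airway, two vessels, tiny LV."""
    return phantom.PhantomSpec(
        shape=(48, 64, 96),
        spacing=(1.0, 1.0, 1.0),
        emphysema_fraction=emphysema_fraction,
        lungs=[phantom.LungSpec(center=(24.0, 32.0, 28.0), semi_axes=(20.0, 24.0, 20.0))],
        airways=[phantom.AirwaySpec(center=(24.0, 32.0, 24.0), length_mm=24.0,
                                    lumen_radius_mm=2.0, wall_thickness_mm=1.0)],
        vessels=[phantom.VesselCylinder(center=(24.0, 24.0, 36.0), length_mm=24.0,
                                        radius_mm=1.0),
                 phantom.VesselCylinder(center=(24.0, 42.0, 36.0), length_mm=16.0,
                                        radius_mm=2.0)],
        lv=phantom.LVSpec(center=(24.0, 32.0, 72.0), edv_target_ml=20.0,
                          esv_target_ml=8.0, myo_thickness_mm=4.0),
        plaques=[phantom.PlaqueSpec(slice_index=8, center_yx=(6, 80),
                                    area_mm2=4.0, peak_hu=250.0)],
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mini_phantom():
    volume, truth = phantom.generate_phantom(mini_spec(seed=3))
    return volume, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
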