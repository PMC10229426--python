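import numpy as np
import pytest

import lumipipe as lp


@pytest.fixture(scope="session")
def camera():
    return lp.CameraModel()


@pytest.fixture(scope="session")
def kinetics():
    return lp.SubstrateKinetics()


@pytest.fixture(scope="session")
def small_geom():
    return lp.HeadGeometry(shape=(32, 32), semi_axes=(9.0, 12.0))


@pytest.fixture(scope="session")
def tiny_geom():
    return lp.HeadGeometry(shape=(16, 16), semi_axes=(4.5, 6.0))


@pytest.fixture(scope="session")
def short_schedule():
    """Nine 20-s stimulation cycles starting 60 s in (fits 240 s)."""
    return lp.make_stimulus_schedule(9, 1.0, 19.0, 60.0)


@pytest.fixture(scope="session")
def default_kernels():
    return [lp.ResponseKernel.hemodynamic(), lp.ResponseKernel.calcium()]


@pytest.fixture(scope="session")
def noiseless_sim(kinetics, camera, short_schedule, small_geom,
                  default_kernels):
    """Noiseless recording with both response kernels and a 60 s tail."""
    return lp.simulate_video(kinetics, camera, short_schedule,
                             geometry=small_geom, kernels=default_kernels,
                             seed=0, duration=300.0, noise=False)


@pytest.fixture(scope="session")
def noisy_null_sim(kinetics, camera, short_schedule, small_geom):
    """Default-noise recording with no stimulus-locked component."""
    return lp.simulate_video(kinetics, camera, short_schedule,
                             geometry=small_geom, seed=7, duration=240.0)
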