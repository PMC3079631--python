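import numpy as np
import pytest

from ooperm import (
    BathSolution,
    KKParameters,
    make_geometry,
    simulate,
)


@pytest.fixture(scope="session")
def geom():
    """Standard oocyte geometry: 1.2 mm apparent diameter."""
    return make_geometry(0.12)


@pytest.fixture(scope="session")
def sucrose_bath():
    """Hypertonic 0.9 M sucrose step, 1460 mOsm impermeant."""
    return BathSolution(osm_impermeant=1460.0)


@pytest.fixture(scope="session")
def eg_bath():
    """Hypertonic 1.3 M ethylene glycol plus 200 mOsm impermeant."""
    return BathSolution(
        osm_impermeant=200.0, conc_permeant=1.3, permeant_id="ethylene_glycol"
    )


@pytest.fixture(scope="session")
def t85a_eg_params():
    """Published ethylene-glycol row used as a round-trip anchor."""
    return KKParameters(Lp=2.64, Ps=25.49e-3, sigma=0.8)


@pytest.fixture(scope="session")
def t85a_eg_traj(geom, eg_bath, t85a_eg_params):
    """Noise-free 10-min shrink-swell trajectory, 10-s sampling."""
    return simulate(
        t85a_eg_params, geom, eg_bath, duration=10.0, sample_interval=10.0 / 60.0
    )


def linear_trajectory(slope, v0, t_end=1.0, n=61):
    """Exactly linear relative-volume trajectory (oracle input)."""
    from ooperm import VolumeTrajectory

    t = np.linspace(0.0, t_end, n)
    return VolumeTrajectory(times=t, rel_volumes=1.0 + slope * t, V0=v0)
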