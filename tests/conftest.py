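import numpy as np
import pytest

from dmliner import LinerSpec, NoiseSpec, ProtocolSpec, simulate_scan


@pytest.fixture(scope="session")
def liner():
    """28/63 mm liner, the largest commercial dual-mobility size."""
    return LinerSpec()


@pytest.fixture(scope="session")
def coarse_protocol():
    """Coarser sampling than the measurement default, for fast unit tests."""
    return ProtocolSpec(azimuth_step=10.0, point_pitch=1.0)


@pytest.fixture(scope="session")
def unworn_internal(liner, coarse_protocol):
    return simulate_scan(liner, "internal_concave", coarse_protocol)


@pytest.fixture(scope="session")
def unworn_external(liner, coarse_protocol):
    return simulate_scan(liner, "external_convex", coarse_protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def sphere_points(rng, centre, radius, n=200, cap_deg=180.0):
    """Random exact points on a (partial) sphere."""
    u = rng.uniform(np.cos(np.deg2rad(cap_deg)), 1.0, n)
    th = np.arccos(u)
    ph = rng.uniform(0, 2 * np.pi, n)
    st = np.sin(th)
    return np.asarray(centre) + radius * np.column_stack(
        [st * np.cos(ph), st * np.sin(ph), np.cos(th)]
    )
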