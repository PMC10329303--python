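import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_geometry():
    from tmjload import build_geometry

    return build_geometry()


@pytest.fixture(scope="session")
def fast_geometry():
    from tmjload import GeometryParams, build_geometry

    return build_geometry(GeometryParams(surface_resolution=7))


@pytest.fixture(scope="session")
def baseline_result(baseline_geometry):
    """Full two-cycle baseline run at the default timestep (shared; ~30 s)."""
    from tmjload import simulate_open_close

    return simulate_open_close(baseline_geometry, dt=5e-5)


@pytest.fixture(scope="session")
def fast_sweep():
    """Baseline + eight right-side shortenings at the fast preset (~90 s)."""
    from tmjload.config import RunConfig
    from tmjload.pipeline import run_sweep

    sweep, manifest = run_sweep(RunConfig.fast_preset(), write=False)
    return sweep, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
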