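import warnings

import numpy as np
import pytest

import feathermorph as fm
from feathermorph.grid import SpatialGrid

warnings.filterwarnings("ignore", message="D_A >= D_B")


@pytest.fixture(scope="session")
def grid200():
    return SpatialGrid(200)


@pytest.fixture(scope="session")
def steady_states(grid200):
    """Steady regulatory profiles for the presets the tests compare.

    Computed once per session; each entry is a (preset, SteadyState) pair.
    """
    out = {}
    for name in (
        "symmetric_no_RA",
        "high_RA",
        "low_RA",
        "gradient_steep",
        "gradient_intermediate",
        "gradient_shallow",
    ):
        preset = fm.load_preset(name)
        ss = fm.solve_preset_state(
            preset.mrf, grid200, seed=0,
            noise_amplitude=float(preset.run["mrf_noise_amplitude"]),
            dt=float(preset.run["mrf_dt"]),
            tol=float(preset.run["mrf_tol"]),
            max_steps=int(preset.run["mrf_max_steps"]),
        )
        assert ss.converged, f"preset {name} did not converge"
        out[name] = (preset, ss)
    return out


@pytest.fixture(scope="session")
def coupled_kymograph(grid200, steady_states):
    """Travelling-wave kymograph of the symmetric feather (long run)."""
    preset, ss = steady_states["symmetric_no_RA"]
    A, B, C = fm.pb.initial_pb_fields(
        preset.pb, grid200,
        noise_amplitude=float(preset.run["pb_noise_amplitude"]), seed=0,
    )
    return fm.run_pb(
        A, B, C, ss.profile("GREM"), ss.profile("GDF"), preset.pb, grid200,
        n_steps=120_000, record_every=200, seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
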