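import numpy as np
import pytest

import matbgc as m
from matbgc.synth import downsample_profile


@pytest.fixture(scope="session")
def library():
    return m.scenario_library()


@pytest.fixture(scope="session")
def ap_recovery_solution(library):
    """Solved three-zone oracle scenario (AP consumption / inert / production)."""
    sc = library["ap_recovery"]
    return sc, m.solve_steady_state(sc)


@pytest.fixture(scope="session")
def ap_recovery_downsampled(ap_recovery_solution):
    """The S_tot profile resampled at microsensor resolution (180/450 µm)."""
    sc, res = ap_recovery_solution
    return sc, res, downsample_profile(res.profiles.s_tot)


@pytest.fixture(scope="session")
def diel_sip_result(library):
    return m.simulate_diel_sip(library["diel_sip"])


@pytest.fixture(scope="session")
def op_lightdark(library):
    """Light–dark transient of the oxygenic-photosynthesis scenario."""
    sc = library["op_sob_below"]
    return sc, m.simulate_lightdark(sc, switch_time_s=0.0, duration_s=15.0, dt_s=0.05)


def sample_series(times, values, dt=0.5):
    """Pick samples on a regular dt grid from a finer simulated series."""
    keep = np.isclose(np.mod(times, dt), 0, atol=1e-9) | np.isclose(
        np.mod(times, dt), dt, atol=1e-9
    )
    return times[keep], values[keep]
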