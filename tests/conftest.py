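import warnings

import numpy as np
import pandas as pd
import pytest

from hmatch import crosstalk as ct
from hmatch.design import RunDesign
from hmatch.emulator import FitConfig
from hmatch.history_match import WaveConfig, WaveState, run_wave


@pytest.fixture(scope="session")
def quadratic_2d():
    """A cheap analytic 2-output simulator on [-1, 1]^2 with a known target.

    f1 = x1 + x1^2 + x2, f2 = x1 - x2; the observation is the truth at
    x* = (0.3, -0.2) with modest uncertainties, so a one-wave match must keep
    a neighbourhood of x*.
    """
    ranges = np.array([[-1.0, 1.0], [-1.0, 1.0]])
    names = ("x1", "x2")
    x_star = np.array([0.3, -0.2])

    def simulate(native):
        native = np.atleast_2d(native)
        return pd.DataFrame({
            "f1": native[:, 0] + native[:, 0] ** 2 + native[:, 1],
            "f2": native[:, 0] - native[:, 1],
        })

    from hmatch.linkage import Observation

    truth = simulate(x_star[None, :])
    obs = {
        "f1": Observation("f1", float(truth["f1"][0]), var_e=0.05**2),
        "f2": Observation("f2", float(truth["f2"][0]), var_e=0.05**2),
    }
    return dict(ranges=ranges, names=names, simulate=simulate, obs=obs, x_star=x_star)


# ---------------------------------------------------------------------------
# the Arabidopsis wave fixtures (shared across acceptance tests; the problem
# sizes are the package's desk-scale study conditions)
# ---------------------------------------------------------------------------

W1_RUNS = 1000
W1_DIAG = 200
LATER_RUNS = 250
LATER_DIAG = 80


def _crosstalk_wave_config(n_runs, n_diag, policy, n_mc):
    return WaveConfig(
        n_runs=n_runs,
        n_diagnostic=n_diag,
        policy=policy,
        fit=FitConfig(order=3, theta=0.35, nugget_proportion=0.1),
        n_mc_volume=n_mc,
        maximin_candidates=100,
    )


@pytest.fixture(scope="session")
def arabidopsis_wave1():
    """Wave 1 of the crosstalk history match at desk scale (1000 runs)."""
    ranges, names = ct.input_ranges("full")
    obs = ct.arabidopsis_observations()
    state = WaveState(ranges=ranges, names=names, observations=obs)
    sim = ct.make_simulator("full")
    cfg = _crosstalk_wave_config(W1_RUNS, W1_DIAG, {"c_2max": 3.25, "c_3max": 3.0}, 40000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state = run_wave(state, sim, cfg, seed=11)
    return state


@pytest.fixture(scope="session")
def arabidopsis_waves(arabidopsis_wave1):
    """Waves 2 and 3 continued from the wave-1 fixture (300 runs each)."""
    sim = ct.make_simulator("full")
    state = arabidopsis_wave1
    schedules = [
        {"c_2max": 3.1, "c_3max": 2.8},
        {"c_max": 5.0, "c_2max": 2.9, "c_3max": 2.7},
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, pol in enumerate(schedules, start=2):
            cfg = _crosstalk_wave_config(LATER_RUNS, LATER_DIAG, pol, 20000)
            state = run_wave(state, sim, cfg, seed=11 + k)
            if state.status == "empty":
                break
    return state
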