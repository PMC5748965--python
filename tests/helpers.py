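"""Shared test doubles: exact analytic 'emulators' with zero variance."""

import numpy as np

from hmatch.implausibility import CutoffPolicy
from hmatch.linkage import Observation


class _StubEmulator:
    """predict_batch returns one coordinate with zero variance."""

    def __init__(self, dim):
        self.dim = dim

    def predict_batch(self, pts):
        pts = np.atleast_2d(pts)
        return pts[:, self.dim].copy(), np.zeros(len(pts))


def box_history(half_width=0.5, d=2):
    """Wave history whose non-implausible set is the box |x_i| <= half_width."""
    sigma = half_width / 3.0
    emulators = {f"x{i}": _StubEmulator(i) for i in range(d)}
    observations = {
        f"x{i}": Observation(f"x{i}", 0.0, var_e=sigma**2) for i in range(d)
    }
    policy = CutoffPolicy(outputs=tuple(emulators), c_max=3.0)
    return [(emulators, policy)], observations
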