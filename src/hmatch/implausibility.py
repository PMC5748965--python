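"""Implausibility measures and chained non-implausibility membership.

The single-output implausibility standardises the distance between the
emulator expectation and the observed value by every relevant uncertainty:

    I_i(x)^2 = (E_D(f_i(x)) - z_i)^2 / (Var_D(f_i(x)) + Var(eps_i) + Var(e_i))

Several outputs are combined through order statistics: the maximum I_M, the
second maximum I_2M and the third maximum I_3M, the latter two being robust to
the failure of one or two emulators.  Inputs surviving every wave's cutoffs
form the current non-implausible space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .linkage import Observation


class ZeroVarianceError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class CutoffPolicy:
    """Cutoffs on the combined implausibility order statistics for a wave.

    ``outputs`` is the set Q_k of output names the cutoffs apply to.  At least
    one of the three cutoffs must be present; c=3 on the maximum is the
    conventional choice motivated by the 3-sigma rule for unimodal
    distributions.
    """

    outputs: tuple[str, ...]
    c_max: float | None = None
    c_2max: float | None = None
    c_3max: float | None = None

    def __post_init__(self):
        cuts = [self.c_max, self.c_2max, self.c_3max]
        if all(c is None for c in cuts):
            raise ValueError("at least one cutoff must be given")
        if any(c is not None and c <= 0 for c in cuts):
            raise ValueError("cutoffs must be positive")
        if not self.outputs:
            raise ValueError("the output set Q_k must be non-empty")

    def accept(self, I: np.ndarray) -> np.ndarray:
        """Vector of booleans for an (n_points, n_outputs) implausibility array."""
        I = np.atleast_2d(I)
        if I.shape[1] != len(self.outputs):
            raise ValueError("implausibility array does not match the output set")
        ok = np.ones(I.shape[0], dtype=bool)
        # sort once, reuse for all three order statistics
        s = np.sort(I, axis=1)[:, ::-1]
        for m, c in ((1, self.c_max), (2, self.c_2max), (3, self.c_3max)):
            if c is None:
                continue
            if s.shape[1] >= m:
                ok &= s[:, m - 1] <= c
        return ok


def implausibility(pred, obs: Observation) -> float:
    """Single-output implausibility of a prediction against an observation."""
    var_total = float(pred.variance) + obs.total_var
    if var_total <= 0:
        raise ZeroVarianceError(
            f"all variances are zero for output {obs.name!r}; "
            "implausibility is undefined"
        )
    if pred.variance < 0:
        raise ValueError("prediction variance must be >= 0")
    return abs(float(pred.mean) - obs.z) / np.sqrt(var_total)


def implausibility_array(
    means: np.ndarray, variances: np.ndarray, z: float, obs_var: float, name: str = ""
) -> np.ndarray:
    """Vectorised implausibility for one output over many points.

    ``variances`` is the emulator variance Var_D; pass zeros when the value
    comes from the simulator itself (the certification of final runs).
    """
    means = np.asarray(means, float)
    variances = np.asarray(variances, float)
    total = variances + obs_var
    if np.any(total <= 0):
        raise ZeroVarianceError(f"zero total variance for output {name!r}")
    return np.abs(means - z) / np.sqrt(total)


def combine(values: Sequence[float] | np.ndarray, m: int) -> float:
    """The m-th largest implausibility: m=1 is I_M, m=2 is I_2M, m=3 is I_3M."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("cannot combine an empty implausibility vector")
    if not 1 <= m <= v.size:
        raise ValueError(f"order statistic index m={m} out of range 1..{v.size}")
    return float(np.sort(v)[::-1][m - 1])


def wave_implausibilities(
    points: np.ndarray,
    emulators: Mapping[str, object],
    observations: Mapping[str, Observation],
    outputs: Sequence[str],
) -> np.ndarray:
    """(n_points, len(outputs)) implausibility array for one wave's emulators."""
    points = np.atleast_2d(points)
    cols = []
    for name in outputs:
        if name not in observations:
            raise KeyError(f"no observation configured for emulated output {name!r}")
        em = emulators[name]
        mean, var = em.predict_batch(points)
        obs = observations[name]
        cols.append(implausibility_array(mean, var, obs.z, obs.total_var, name))
    return np.column_stack(cols)


def _wave_accept(
    points: np.ndarray,
    emulators: Mapping[str, object],
    observations: Mapping[str, Observation],
    policy: CutoffPolicy,
) -> np.ndarray:
    """Policy acceptance with per-output short-circuiting.

    I_M <= c holds iff no output exceeds c; I_2M <= c iff at most one does;
    I_3M <= c iff at most two do.  Outputs are therefore evaluated one at a
    time, dropping a point as soon as its exceedance counts make failure
    certain — equivalent to :meth:`CutoffPolicy.accept` but far cheaper on
    bulk Monte-Carlo samples, where most points fail early.
    """
    n = points.shape[0]
    alive = np.ones(n, dtype=bool)
    cnt2 = np.zeros(n, dtype=np.int8)
    cnt3 = np.zeros(n, dtype=np.int8)
    for name in policy.outputs:
        idx = np.where(alive)[0]
        if idx.size == 0:
            break
        if name not in observations:
            raise KeyError(f"no observation configured for emulated output {name!r}")
        obs = observations[name]
        mean, var = emulators[name].predict_batch(points[idx])
        I = implausibility_array(mean, var, obs.z, obs.total_var, name)
        failed = np.zeros(idx.size, dtype=bool)
        if policy.c_max is not None:
            failed |= I > policy.c_max
        if policy.c_2max is not None:
            cnt2[idx] += I > policy.c_2max
            failed |= cnt2[idx] >= 2
        if policy.c_3max is not None:
            cnt3[idx] += I > policy.c_3max
            failed |= cnt3[idx] >= 3
        alive[idx[failed]] = False
    return alive


def chained_membership(
    points: np.ndarray,
    wave_history: Sequence[tuple[Mapping[str, object], CutoffPolicy]],
    observations: Mapping[str, Observation],
) -> np.ndarray:
    """Membership of each point in the space surviving every wave's cutoffs.

    An empty history accepts everything (the initial space is unconstrained).
    Later waves are only evaluated at points still alive, which keeps chained
    Monte-Carlo volume estimates cheap.
    """
    points = np.atleast_2d(points)
    alive = np.ones(points.shape[0], dtype=bool)
    for emulators, policy in wave_history:
        if not alive.any():
            break
        idx = np.where(alive)[0]
        alive[idx] = _wave_accept(points[idx], emulators, observations, policy)
    return alive


def nonimplausible(
    x: np.ndarray,
    wave_history: Sequence[tuple[Mapping[str, object], CutoffPolicy]],
    observations: Mapping[str, Observation],
) -> bool:
    """True iff the single point ``x`` survives every wave's cutoff policy."""
    return bool(chained_membership(np.atleast_2d(x), wave_history, observations)[0])
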