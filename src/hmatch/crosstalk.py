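"""Hormonal crosstalk ODE model of auxin/ethylene/cytokinin signalling in a
single Arabidopsis root cell.

The model tracks 15 quantities: the hormones auxin, cytokinin (CK) and
ethylene (ET); the POLARIS transcript (PLSm) and peptide (PLSp); an
auxin-receptor pair (Ra inactive, Ra* active), an ethylene-receptor pair
(Re unbound, Re* active) with the downstream kinase pair (CTR1, CTR1*) and the
ethylene-downstream signal X; and three exogenous feeding pools (IAA,
cytokinin, ACC) that are held constant at 0 (no feeding) or 1 (feeding).

Interactions encoded by the rate constants:

* Auxin is supplied from the shoot at maximal rate k1a, attenuated by the
  ethylene-downstream signal X (half-maximal at X = k1); produced by a
  background route k2 and by an ethylene-stimulated biosynthesis route k2a
  that is inhibited by cytokinin (scale k2b) and requires PLS peptide
  (saturation constant k2c); removed by turnover k3 and by X-stimulated
  transport k3a; fed auxin converts at rate k1vauxin.
* Auxin binds its receptor, Ra + Auxin -> Ra* (k4) with reversal k5; the
  active receptor drives PLS transcription at rate k6 (0.3 wildtype, 0 for
  the pls mutant), inhibited by ethylene with scale k6a; PLSm decays at k7
  and is translated at k8 into PLSp, which decays at k9.
* Ethylene is produced at a basal rate k12 plus an auxin-and-cytokinin
  stimulated rate k12a, decays at k13, and is boosted by fed ACC at k1veth.
  Ethylene converts the active receptor Re* to Re (k10); PLS peptide (k10a)
  and a basal route (k11) reactivate it.  Re* activates CTR1 -> CTR1* (k14,
  reversal k15), and CTR1* degrades the downstream signal X (k16a) which is
  produced at rate k16 and turns over at k17.
* Cytokinin is synthesised at rate k18a under auxin inhibition (scale k18),
  decays at k19, and is boosted by fed cytokinin at k1vCK.

The receptor pairs are conserved (Ra+Ra*, Re+Re*, CTR1+CTR1* are constant
along trajectories), so at equilibrium only ratios of the paired rate
constants are identifiable; eight denominators (k1a, k4, k8, k10, k12, k14,
k16, k18a) are fixed to 1 and the search operates on the 23 log-ratios below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .linkage import (
    MEASURED_TRENDS,
    Observation,
    TrendSpec,
    absolute_to_observation,
    trend_to_observation,
)

STATE_NAMES = (
    "Auxin", "X", "PLSp", "Ra", "Ra*", "CK", "ET", "PLSm",
    "Re", "Re*", "CTR1", "CTR1*", "IAA", "cytokinin", "ACC",
)

# initial conditions; IAA/cytokinin/ACC are overridden by the scenario
INITIAL_STATE = {
    "Auxin": 0.1, "X": 0.1, "PLSp": 0.1, "Ra": 0.0, "Ra*": 1.0,
    "CK": 0.1, "ET": 0.1, "PLSm": 0.1, "Re": 0.0, "Re*": 0.3,
    "CTR1": 0.0, "CTR1*": 0.3, "IAA": 0.0, "cytokinin": 0.0, "ACC": 0.0,
}

PARAM_NAMES = (
    "k1", "k1a", "k2", "k2a", "k2b", "k2c", "k3", "k3a", "k4", "k5",
    "k6", "k6a", "k7", "k8", "k9", "k10", "k10a", "k11", "k12", "k12a",
    "k13", "k14", "k15", "k16", "k16a", "k17", "k18", "k18a", "k19",
    "k1vauxin", "k1vCK", "k1veth",
)

# rate parameters whose scale is not identifiable at equilibrium; fixed to 1
ELIMINATED = ("k1a", "k4", "k8", "k10", "k12", "k14", "k16", "k18a")

# the 23 reduced inputs: name -> (numerator, denominator or None, lo, hi)
# ranges are on the natural (ratio) scale; the search space is their log
REDUCED_INPUTS: tuple[tuple[str, str, str | None, float, float], ...] = (
    ("k1",            "k1",       None,    0.1,     10.0),
    ("k2/k1a",        "k2",       "k1a",   0.02,    2.0),
    ("k2a/k1a",       "k2a",      "k1a",   0.28,    28.0),
    ("k2b",           "k2b",      None,    0.1,     10.0),
    ("k2c",           "k2c",      None,    1e-6,    1.0),
    ("k3/k1a",        "k3",       "k1a",   0.2,     20.0),
    ("k3a/k1a",       "k3a",      "k1a",   0.045,   4.5),
    ("k5/k4",         "k5",       "k4",    0.1,     10.0),
    ("k6a",           "k6a",      None,    0.002,   2000.0),
    ("k7",            "k7",       None,    0.1,     10.0),
    ("k9/k8",         "k9",       "k8",    0.1,     10.0),
    ("k10a/k10",      "k10a",     "k10",   166.0,   1.66e4),
    ("k11/k10",       "k11",      "k10",   166.0,   1.66e5),
    ("k12a/k12",      "k12a",     "k12",   0.1,     10.0),
    ("k13/k12",       "k13",      "k12",   1.0,     1000.0),
    ("k15/k14",       "k15",      "k14",   2.83e-4, 0.283),
    ("k16a/k16",      "k16a",     "k16",   0.333,   33.3),
    ("k17/k16",       "k17",      "k16",   0.033,   3.33),
    ("k18",           "k18",      None,    0.01,    10.0),
    ("k19/k18a",      "k19",      "k18a",  0.01,    10.0),
    ("k1vauxin/k1a",  "k1vauxin", "k1a",   0.1,     100.0),
    ("k1vCK/k18a",    "k1vCK",    "k18a",  0.1,     10.0),
    ("k1veth/k12",    "k1veth",   "k12",   1.0,     100.0),
)

INPUT_NAMES = tuple(r[0] for r in REDUCED_INPUTS)
INPUT_NAMES_K2C0 = tuple(n for n in INPUT_NAMES if n != "k2c")

# natural-log search ranges (design "native" units)
LOG_RANGES = np.array([[math.log(lo), math.log(hi)] for _, _, _, lo, hi in REDUCED_INPUTS])
LOG_RANGES_K2C0 = np.array(
    [[math.log(lo), math.log(hi)] for name, _, _, lo, hi in REDUCED_INPUTS if name != "k2c"]
)

K6_WILDTYPE = 0.3
K6_MUTANT = 0.0

Variant = Literal["full", "k2c_zero"]


@dataclass(frozen=True)
class Scenario:
    """Genotype plus feeding regime.

    ``genotype`` sets the PLS transcription control k6 (wildtype 0.3, pls
    mutant 0); feeding sets the constant exogenous pools IAA, cytokinin and
    ACC to 1.
    """

    genotype: Literal["wt", "mu"] = "wt"
    feed_auxin: bool = False
    feed_cytokinin: bool = False
    feed_ethylene: bool = False

    @property
    def k6(self) -> float:
        return K6_WILDTYPE if self.genotype == "wt" else K6_MUTANT

    @property
    def label(self) -> str:
        for lbl, sc in SCENARIO_TABLE.items():
            if sc == self:
                return lbl
        return "unmeasured"


SCENARIO_TABLE: dict[str, Scenario] = {
    "wt": Scenario("wt"),
    "mu": Scenario("mu"),
    "fa": Scenario("wt", feed_auxin=True),
    "fe": Scenario("wt", feed_ethylene=True),
    "fc": Scenario("wt", feed_cytokinin=True),
    "mu_fe": Scenario("mu", feed_ethylene=True),
}

# 18 outputs: two absolute wildtype concentrations first, then the 16 trends
def _trend_name(chem: str, a2: str) -> str:
    return f"{chem}_{a2.replace('_', '')}"


OUTPUT_NAMES: tuple[str, ...] = ("Auxin_wt", "CK_wt") + tuple(
    _trend_name(chem, a2) for chem, a1, a2 in MEASURED_TRENDS
)

TREND_DIRECTIONS: dict[tuple[str, str, str], str] = {
    ("Auxin", "wt", "mu"): "Down",
    ("Auxin", "wt", "fa"): "Up",
    ("Auxin", "wt", "fe"): "Up",
    ("Auxin", "wt", "fc"): "Down",
    ("Auxin", "mu", "mu_fe"): "Down",
    ("PLSm", "wt", "fa"): "Up",
    ("PLSm", "wt", "fe"): "Down",
    ("PLSm", "wt", "fc"): "Down",
    ("ET", "wt", "mu"): "NoChange",
    ("ET", "wt", "fa"): "Up",
    ("ET", "wt", "fe"): "Up",
    ("ET", "wt", "fc"): "Up",
    ("CK", "wt", "mu"): "Up",
    ("CK", "wt", "fa"): "Down",
    ("CK", "wt", "fe"): "Down",
    ("CK", "wt", "fc"): "Up",
}


def arabidopsis_observations() -> dict[str, Observation]:
    """The 18 observation targets: 2 absolute concentrations + 16 trends."""
    obs: dict[str, Observation] = {
        "Auxin_wt": absolute_to_observation(0.24, 1.0, name="Auxin_wt"),
        "CK_wt": absolute_to_observation(0.24, 1.0, name="CK_wt"),
    }
    for chem, a1, a2 in MEASURED_TRENDS:
        spec = TrendSpec(chem, (a1, a2), TREND_DIRECTIONS[(chem, a1, a2)])
        o = trend_to_observation(spec)
        obs[_trend_name(chem, a2)] = o
    return obs


# --------------------------------------------------------------------------
# parameter expansion
# --------------------------------------------------------------------------

class InputRangeError(ValueError):
    pass


def expand_inputs(
    x: Sequence[float], variant: Variant = "full", check_range: bool = True
) -> dict[str, float]:
    """Reduced log-input vector -> the 32 named rate constants.

    Each component of ``x`` is the natural log of a Table-style ratio; the
    eight eliminated denominators are fixed to 1, so numerators equal their
    ratios.  ``k6`` is left unset (it belongs to the scenario).  For the
    k2c_zero variant ``x`` is 22-dimensional (no k2c entry).
    """
    rows = [r for r in REDUCED_INPUTS if variant == "full" or r[0] != "k2c"]
    x = np.asarray(x, float).ravel()
    if x.size != len(rows):
        raise ValueError(f"expected {len(rows)} inputs, got {x.size}")
    params = {name: 1.0 for name in ELIMINATED}
    for xi, (name, num, den, lo, hi) in zip(x, rows):
        if check_range:
            tol = 1e-9
            if not (math.log(lo) - tol <= xi <= math.log(hi) + tol):
                raise InputRangeError(
                    f"input {name!r} = exp({xi:.4g}) outside its range [{lo}, {hi}]"
                )
        params[num] = math.exp(xi)  # denominator fixed at 1
    if variant == "k2c_zero":
        params["k2c"] = 0.0
    params.setdefault("k6", K6_WILDTYPE)
    return params


def _param_tuple(params: dict[str, float], k6: float) -> tuple[float, ...]:
    p = dict(params)
    p["k6"] = k6
    return tuple(p[name] for name in PARAM_NAMES)


# --------------------------------------------------------------------------
# the ODE right-hand side
# --------------------------------------------------------------------------

def _rhs_full(y, t, p):
    (k1, k1a, k2, k2a, k2b, k2c, k3, k3a, k4, k5,
     k6, k6a, k7, k8, k9, k10, k10a, k11, k12, k12a,
     k13, k14, k15, k16, k16a, k17, k18, k18a, k19,
     k1vauxin, k1vCK, k1veth) = p
    (auxin, X, PLSp, Ra, Ras, CK, ET, PLSm,
     Re, Res, CTR1, CTR1s, IAA, ck_fed, ACC) = y

    biosynth = (k2a * ET / (1.0 + CK / k2b)) * (PLSp / (k2c + PLSp))
    d_auxin = (k1a / (1.0 + X / k1) + k2 + biosynth
               - (k3 + k3a * X) * auxin + k1vauxin * IAA)
    d_X = k16 - k16a * CTR1s * X - k17 * X
    d_PLSp = k8 * PLSm - k9 * PLSp
    d_Ra = -k4 * auxin * Ra + k5 * Ras
    d_Ras = k4 * auxin * Ra - k5 * Ras
    d_CK = k18a / (1.0 + auxin / k18) - k19 * CK + k1vCK * ck_fed
    d_ET = k12 + k12a * auxin * CK - k13 * ET + k1veth * ACC
    d_PLSm = k6 * Ras / (1.0 + ET / k6a) - k7 * PLSm
    conv = k10 * ET * Res - (k10a * PLSp + k11) * Re
    d_Re = conv
    d_Res = -conv
    act = k14 * Res * CTR1 - k15 * CTR1s
    d_CTR1 = -act
    d_CTR1s = act
    return (d_auxin, d_X, d_PLSp, d_Ra, d_Ras, d_CK, d_ET, d_PLSm,
            d_Re, d_Res, d_CTR1, d_CTR1s, 0.0, 0.0, 0.0)


def _rhs_k2c_zero(y, t, p):
    # PLSp-saturation factor removed entirely (the limit k2c -> 0 taken with
    # PLSp > 0 held fixed), not evaluated at k2c = 0
    (k1, k1a, k2, k2a, k2b, k2c, k3, k3a, k4, k5,
     k6, k6a, k7, k8, k9, k10, k10a, k11, k12, k12a,
     k13, k14, k15, k16, k16a, k17, k18, k18a, k19,
     k1vauxin, k1vCK, k1veth) = p
    (auxin, X, PLSp, Ra, Ras, CK, ET, PLSm,
     Re, Res, CTR1, CTR1s, IAA, ck_fed, ACC) = y

    biosynth = k2a * ET / (1.0 + CK / k2b)
    d_auxin = (k1a / (1.0 + X / k1) + k2 + biosynth
               - (k3 + k3a * X) * auxin + k1vauxin * IAA)
    d_X = k16 - k16a * CTR1s * X - k17 * X
    d_PLSp = k8 * PLSm - k9 * PLSp
    d_Ra = -k4 * auxin * Ra + k5 * Ras
    d_Ras = k4 * auxin * Ra - k5 * Ras
    d_CK = k18a / (1.0 + auxin / k18) - k19 * CK + k1vCK * ck_fed
    d_ET = k12 + k12a * auxin * CK - k13 * ET + k1veth * ACC
    d_PLSm = k6 * Ras / (1.0 + ET / k6a) - k7 * PLSm
    conv = k10 * ET * Res - (k10a * PLSp + k11) * Re
    act = k14 * Res * CTR1 - k15 * CTR1s
    return (d_auxin, d_X, d_PLSp, d_Ra, d_Ras, d_CK, d_ET, d_PLSm,
            conv, -conv, -act, act, 0.0, 0.0, 0.0)


def _jac(y, t, p, variant: Variant = "full"):
    """Analytic 15x15 Jacobian of the right-hand side (LSODA's Dfun)."""
    (k1, k1a, k2, k2a, k2b, k2c, k3, k3a, k4, k5,
     k6, k6a, k7, k8, k9, k10, k10a, k11, k12, k12a,
     k13, k14, k15, k16, k16a, k17, k18, k18a, k19,
     k1vauxin, k1vCK, k1veth) = p
    (auxin, X, PLSp, Ra, Ras, CK, ET, PLSm,
     Re, Res, CTR1, CTR1s, IAA, ck_fed, ACC) = y
    J = np.zeros((15, 15))

    ck_inhib = 1.0 + CK / k2b
    B = k2a * ET / ck_inhib
    if variant == "full":
        P = PLSp / (k2c + PLSp)
        dP_dPLSp = k2c / (k2c + PLSp) ** 2
    else:
        P = 1.0
        dP_dPLSp = 0.0
    # Auxin row
    J[0, 0] = -(k3 + k3a * X)
    J[0, 1] = -k1a / (k1 * (1.0 + X / k1) ** 2) - k3a * auxin
    J[0, 2] = B * dP_dPLSp
    J[0, 5] = -P * k2a * ET / (k2b * ck_inhib**2)
    J[0, 6] = P * k2a / ck_inhib
    J[0, 12] = k1vauxin
    # X row
    J[1, 1] = -k16a * CTR1s - k17
    J[1, 11] = -k16a * X
    # PLSp row
    J[2, 2] = -k9
    J[2, 7] = k8
    # Ra / Ra* rows
    J[3, 0] = -k4 * Ra
    J[3, 3] = -k4 * auxin
    J[3, 4] = k5
    J[4] = -J[3]
    # CK row
    J[5, 0] = -k18a / (k18 * (1.0 + auxin / k18) ** 2)
    J[5, 5] = -k19
    J[5, 13] = k1vCK
    # ET row
    J[6, 0] = k12a * CK
    J[6, 5] = k12a * auxin
    J[6, 6] = -k13
    J[6, 14] = k1veth
    # PLSm row
    et_inhib = 1.0 + ET / k6a
    J[7, 4] = k6 / et_inhib
    J[7, 6] = -k6 * Ras / (k6a * et_inhib**2)
    J[7, 7] = -k7
    # Re / Re* rows (conv = k10 ET Re* - (k10a PLSp + k11) Re)
    J[8, 2] = -k10a * Re
    J[8, 6] = k10 * Res
    J[8, 8] = -(k10a * PLSp + k11)
    J[8, 9] = k10 * ET
    J[9] = -J[8]
    # CTR1 / CTR1* rows (act = k14 Re* CTR1 - k15 CTR1*)
    J[11, 9] = k14 * CTR1
    J[11, 10] = k14 * Res
    J[11, 11] = -k15
    J[10] = -J[11]
    return J


def _jac_full(y, t, p):
    return _jac(y, t, p, "full")


def _jac_k2c_zero(y, t, p):
    return _jac(y, t, p, "k2c_zero")


def rhs(
    state: Sequence[float],
    params: dict[str, float] | Sequence[float],
    t: float = 0.0,
    variant: Variant = "full",
) -> np.ndarray:
    """Time derivatives of the 15 state variables."""
    if isinstance(params, dict):
        p = tuple(params[name] for name in PARAM_NAMES)
    else:
        p = tuple(params)
    if p[PARAM_NAMES.index("k6a")] < 0 or p[PARAM_NAMES.index("k2c")] < 0:
        raise ValueError("k6a and k2c must be non-negative")
    fn = _rhs_full if variant == "full" else _rhs_k2c_zero
    return np.asarray(fn(tuple(state), t, p), float)


class EquilibriumError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-8
    atol: float = 1e-10
    t_end: float = 1e4
    t_extend: float = 1e5
    eq_tol: float = 1e-8  # residual threshold, relative to max(state, 1)


def initial_state(scenario: Scenario) -> np.ndarray:
    y0 = np.array([INITIAL_STATE[name] for name in STATE_NAMES], float)
    y0[STATE_NAMES.index("IAA")] = 1.0 if scenario.feed_auxin else 0.0
    y0[STATE_NAMES.index("cytokinin")] = 1.0 if scenario.feed_cytokinin else 0.0
    y0[STATE_NAMES.index("ACC")] = 1.0 if scenario.feed_ethylene else 0.0
    return y0


def solve_equilibrium(
    params: dict[str, float],
    scenario: Scenario,
    solver: SolverOptions = SolverOptions(),
    variant: Variant = "full",
) -> np.ndarray:
    """Integrate the stiff system to t = 1e4 and verify equilibrium.

    The residual check demands max |dy/dt| <= eq_tol * max(|y|, 1) per
    component; if unmet, integration continues once to t = 1e5 before an
    :class:`EquilibriumError` is raised.
    """
    p = _param_tuple(params, scenario.k6)
    fn = _rhs_full if variant == "full" else _rhs_k2c_zero
    jac = _jac_full if variant == "full" else _jac_k2c_zero
    y0 = initial_state(scenario)

    def _run(y_start, t0, t1):
        y = odeint(
            fn, y_start, [t0, t1], args=(p,), Dfun=jac,
            rtol=solver.rtol, atol=solver.atol, mxstep=100000,
        )
        return y[-1]

    y_end = _run(y0, 0.0, solver.t_end)
    res = np.abs(np.asarray(fn(tuple(y_end), solver.t_end, p)))
    scale = np.maximum(np.abs(y_end), 1.0)
    if np.all(res <= solver.eq_tol * scale):
        return y_end
    y_end = _run(y_end, solver.t_end, solver.t_extend)
    res = np.abs(np.asarray(fn(tuple(y_end), solver.t_extend, p)))
    scale = np.maximum(np.abs(y_end), 1.0)
    if np.all(res <= solver.eq_tol * scale):
        return y_end
    raise EquilibriumError(
        f"no equilibrium by t={solver.t_extend:g} for scenario {scenario.label!r} "
        f"(max residual {float(np.max(res / scale)):.3g})"
    )


def trend_outputs(
    x: Sequence[float],
    variant: Variant = "full",
    solver: SolverOptions = SolverOptions(),
    check_range: bool = True,
) -> pd.Series:
    """The 18 equilibrium outputs at a reduced input vector.

    First the two absolute wildtype log-concentrations ln(Auxin_wt) and
    ln(CK_wt), then the 16 trend log-ratios ln(h_{j,a2}/h_{j,a1}).
    """
    params = expand_inputs(x, variant=variant, check_range=check_range)
    eq: dict[str, np.ndarray] = {}
    for label, sc in SCENARIO_TABLE.items():
        eq[label] = solve_equilibrium(params, sc, solver=solver, variant=variant)

    def conc(label: str, chem: str) -> float:
        return float(eq[label][STATE_NAMES.index(chem)])

    vals = {
        "Auxin_wt": math.log(conc("wt", "Auxin")),
        "CK_wt": math.log(conc("wt", "CK")),
    }
    for chem, a1, a2 in MEASURED_TRENDS:
        vals[_trend_name(chem, a2)] = math.log(conc(a2, chem) / conc(a1, chem))
    return pd.Series(vals, index=list(OUTPUT_NAMES))


def make_simulator(
    variant: Variant = "full", solver: SolverOptions = SolverOptions()
) -> Callable[[np.ndarray], pd.DataFrame]:
    """Batch simulator: native (log) input matrix -> DataFrame of 18 outputs.

    Failed runs (equilibrium or integration failure) come back as NaN rows so
    the caller can exclude and count them.
    """

    def simulate(native_points: np.ndarray) -> pd.DataFrame:
        pts = np.atleast_2d(np.asarray(native_points, float))
        rows = []
        for x in pts:
            try:
                rows.append(trend_outputs(x, variant=variant, solver=solver,
                                          check_range=False))
            except (EquilibriumError, ValueError, FloatingPointError):
                rows.append(pd.Series(np.nan, index=list(OUTPUT_NAMES)))
        return pd.DataFrame(rows).reset_index(drop=True)

    return simulate


def input_ranges(variant: Variant = "full") -> tuple[np.ndarray, tuple[str, ...]]:
    """Log-scale search ranges and input names for a model variant."""
    if variant == "full":
        return LOG_RANGES.copy(), INPUT_NAMES
    return LOG_RANGES_K2C0.copy(), INPUT_NAMES_K2C0


def centre_input(variant: Variant = "full") -> np.ndarray:
    """The log-midpoint of the search ranges (the geometric centre)."""
    ranges, _ = input_ranges(variant)
    return ranges.mean(axis=1)
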