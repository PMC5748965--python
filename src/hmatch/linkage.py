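"""The statistical link between a simulator and reality.

An observation z of a real system quantity y is modelled as z = y + e with
observation error e, and the simulator at its best input x* as
y = f(x*) + eps with model discrepancy eps.  Both enter every comparison only
through their variances, combined as sigma^2 = Var(eps) + Var(e).

Trend observations (Up / Down / NoChange of an equilibrium concentration
relative to a reference scenario) are encoded on the natural-log scale: an
"Up" trend meaning an increase of between 20% and ten fold corresponds to the
log-symmetric interval z +/- 3 sigma with z = 1.24 and sigma = 0.35, "Down" is
its mirror image, and "No change" is z = 0 with sigma = 0.061.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

# log-scale targets for qualitative trends
TREND_VALUES: dict[str, tuple[float, float]] = {
    "Up": (1.24, 0.35),
    "Down": (-1.24, 0.35),
    "NoChange": (0.0, 0.061),
}

CHEMICALS = ("Auxin", "PLSm", "ET", "CK")
SCENARIOS = ("wt", "mu", "fa", "fe", "fc", "mu_fe")

# the 16 measured trend combinations: (chemical, reference scenario, scenario)
MEASURED_TRENDS: tuple[tuple[str, str, str], ...] = (
    ("Auxin", "wt", "mu"),
    ("Auxin", "wt", "fa"),
    ("Auxin", "wt", "fe"),
    ("Auxin", "wt", "fc"),
    ("Auxin", "mu", "mu_fe"),
    ("PLSm", "wt", "fa"),
    ("PLSm", "wt", "fe"),
    ("PLSm", "wt", "fc"),
    ("ET", "wt", "mu"),
    ("ET", "wt", "fa"),
    ("ET", "wt", "fe"),
    ("ET", "wt", "fc"),
    ("CK", "wt", "mu"),
    ("CK", "wt", "fa"),
    ("CK", "wt", "fe"),
    ("CK", "wt", "fc"),
)


@dataclass(frozen=True)
class Observation:
    """One output's target value and its uncertainty budget.

    ``z`` is on the natural-log scale for trend and concentration outputs.
    ``var_e`` is the observation-error variance, ``var_eps`` the
    model-discrepancy variance.  When only the combined sigma is elicited the
    whole variance is stored in ``var_e`` and ``combined`` is set.
    """

    name: str
    z: float
    var_e: float
    var_eps: float = 0.0
    combined: bool = False

    def __post_init__(self):
        if self.var_e < 0 or self.var_eps < 0:
            raise ValueError(f"negative variance for observation {self.name!r}")

    @property
    def total_var(self) -> float:
        return self.var_e + self.var_eps

    @property
    def sigma(self) -> float:
        return math.sqrt(self.total_var)


@dataclass(frozen=True)
class TrendSpec:
    """A qualitative trend of one measurable chemical between two scenarios."""

    chemical: str
    scenario_pair: tuple[str, str]  # (reference, perturbed)
    direction: Literal["Up", "Down", "NoChange"]

    def __post_init__(self):
        if self.chemical not in CHEMICALS:
            raise ValueError(f"unknown chemical {self.chemical!r}")
        if self.direction not in TREND_VALUES:
            raise ValueError(f"unknown trend direction {self.direction!r}")
        key = (self.chemical, *self.scenario_pair)
        if key not in MEASURED_TRENDS:
            raise ValueError(
                f"{self.chemical} trend for scenario pair {self.scenario_pair} "
                "is not one of the 16 measured combinations"
            )

    @property
    def name(self) -> str:
        a2 = self.scenario_pair[1].replace("_", "")
        return f"{self.chemical}_{a2}"


def trend_to_observation(spec: TrendSpec) -> Observation:
    """Target value and combined sigma for a qualitative trend.

    Pure function of the direction: Up -> (1.24, 0.35), Down -> (-1.24, 0.35),
    NoChange -> (0, 0.061).  The split between observation error and model
    discrepancy is not separately elicited, so the whole variance sits in a
    single combined slot.
    """
    z, sigma = TREND_VALUES[spec.direction]
    return Observation(name=spec.name, z=z, var_e=sigma**2, var_eps=0.0, combined=True)


def absolute_to_observation(
    target_concentration: float, span_orders: float = 1.0, name: str = ""
) -> Observation:
    """Target for an absolute concentration, on the natural-log scale.

    The interval "target plus or minus ``span_orders`` orders of magnitude" is
    read as log-symmetric: z = ln(target) and 3 sigma = span_orders * ln(10).
    """
    if not target_concentration > 0:
        raise ValueError("target concentration must be positive")
    z = math.log(target_concentration)
    sigma = span_orders * math.log(10.0) / 3.0
    return Observation(name=name, z=z, var_e=sigma**2, var_eps=0.0, combined=True)


def combined_sigma(var_eps: float, var_e: float) -> float:
    """sqrt(Var(eps) + Var(e))."""
    if var_eps < 0 or var_e < 0:
        raise ValueError("variances must be non-negative")
    return math.sqrt(var_eps + var_e)


# --- tabular round trip ---------------------------------------------------

def observations_to_csv(observations: Iterable[Observation], path: str | Path) -> None:
    rows = [
        {
            "name": o.name,
            "z": o.z,
            "sigma": o.sigma,
            "var_e": o.var_e,
            "var_eps": o.var_eps,
            "combined": o.combined,
        }
        for o in observations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def observations_from_csv(path: str | Path) -> dict[str, Observation]:
    df = pd.read_csv(path)
    out: dict[str, Observation] = {}
    for _, r in df.iterrows():
        out[r["name"]] = Observation(
            name=r["name"],
            z=float(r["z"]),
            var_e=float(r["var_e"]),
            var_eps=float(r["var_eps"]),
            combined=bool(r.get("combined", False)),
        )
    return out
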