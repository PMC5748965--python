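"""The iterative wave algorithm: design, emulate, cut, refocus.

Each wave designs runs over the current non-implausible region, fits fresh
emulators to that wave's runs only, admits outputs whose emulators pass
three-sigma diagnostics, imposes implausibility cutoffs, and records the
Monte-Carlo volume of the surviving space.  The match terminates when the
emulator variances are small against the observation/discrepancy budget
(converged) or the surviving volume hits zero (empty).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    BudgetExhaustedError,
    RunDesign,
    latin_hypercube,
    maximin_lhc,
    rejection_sample,
)
from .emulator import DiagnosticReport, FitConfig, FittedEmulator, diagnose, fit_emulator
from .implausibility import (
    CutoffPolicy,
    chained_membership,
    implausibility_array,
    wave_implausibilities,
)
from .linkage import Observation


class WaveAbortError(RuntimeError):
    pass


class EmptySpaceError(RuntimeError):
    pass


Simulator = Callable[[np.ndarray], pd.DataFrame]


@dataclass
class WaveConfig:
    """Per-wave settings for the history match."""

    n_runs: int = 200
    n_diagnostic: int = 50
    policy: dict | None = None           # {"c_max": .., "c_2max": .., "c_3max": ..}
    outputs: Sequence[str] | None = None  # candidate outputs; default: all observed
    fit: FitConfig = field(default_factory=FitConfig)
    admission_threshold: float = 0.95
    n_mc_volume: int = 20000
    convergence_fraction: float = 0.1
    max_draw_factor: int = 2000           # rejection budget = factor * n_runs
    max_failure_fraction: float = 0.2
    maximin_candidates: int = 100


@dataclass
class Wave:
    design: RunDesign
    outputs: pd.DataFrame
    emulators: dict[str, FittedEmulator]
    policy: CutoffPolicy
    diagnostics: dict[str, DiagnosticReport]
    seed: int
    n_failed: int = 0

    @property
    def q(self) -> tuple[str, ...]:
        return self.policy.outputs


@dataclass
class WaveState:
    """The accumulated history match: waves, volumes, provenance."""

    ranges: np.ndarray
    names: tuple[str, ...]
    observations: dict[str, Observation]
    waves: list[Wave] = field(default_factory=list)
    volume_history: list[tuple[float, float]] = field(default_factory=list)
    nonimplausible_cache: np.ndarray | None = None  # scaled points
    status: str = "continue"  # continue | converged | empty
    provenance: dict = field(default_factory=dict)

    @property
    def history(self) -> list[tuple[dict[str, FittedEmulator], CutoffPolicy]]:
        return [(w.emulators, w.policy) for w in self.waves]

    def membership(self, points: np.ndarray) -> np.ndarray:
        """Chained non-implausibility of scaled points through all waves."""
        return chained_membership(points, self.history, self.observations)

    def current_q(self) -> tuple[str, ...]:
        return self.waves[-1].q if self.waves else ()


def _policy_from_config(config: WaveConfig, outputs: Sequence[str]) -> CutoffPolicy:
    pol = config.policy or {"c_max": 3.0}
    return CutoffPolicy(outputs=tuple(outputs), **pol)


def _design_next_wave(
    state: WaveState, n: int, seed: int, config: WaveConfig
) -> tuple[RunDesign, float]:
    """Design runs over the current non-implausible region.

    Wave 1 uses a maximin Latin hypercube over the whole space; later waves
    draw Latin-hypercube batches over the bounding box of the cached
    non-implausible sample and reject through chained membership, falling back
    to full-space proposals if the box would clip more than 1% of accepted
    points.
    """
    d = len(state.names)
    if not state.waves:
        des = maximin_lhc(n, state.ranges, n_candidates=config.maximin_candidates,
                          seed=seed, names=state.names)
        return des, 1.0

    cache = state.nonimplausible_cache
    if cache is None or len(cache) < 2:
        lo = np.full(d, -1.0)
        hi = np.full(d, 1.0)
    else:
        span = cache.max(axis=0) - cache.min(axis=0)
        lo = np.maximum(cache.min(axis=0) - 0.05 * span, -1.0)
        hi = np.minimum(cache.max(axis=0) + 0.05 * span, 1.0)
        # fall back to the full space if the box clips too many members
        if len(cache) >= 50:
            inside = np.all((cache >= lo) & (cache <= hi), axis=1)
            if inside.mean() < 0.99:
                lo, hi = np.full(d, -1.0), np.full(d, 1.0)

    def source(m: int, rng: np.random.Generator) -> np.ndarray:
        u = (latin_hypercube(m, d, rng) + 1.0) * 0.5
        return lo + u * (hi - lo)

    try:
        res = rejection_sample(
            source,
            state.membership,
            n_target=n,
            max_draws=config.max_draw_factor * max(n, 1),
            seed=seed,
            ranges=state.ranges,
            names=state.names,
        )
    except BudgetExhaustedError as e:
        # a sparse region: accept a smaller design when it can still support
        # an emulator, otherwise give up on the wave
        if len(e.accepted) >= max(d + 2, n // 4):
            warnings.warn(
                f"rejection budget exhausted; continuing with {len(e.accepted)} "
                f"of {n} requested runs"
            )
            design = RunDesign(points=e.accepted, ranges=state.ranges,
                               names=state.names, seed=seed)
            return design, len(e.accepted) / e.n_drawn
        raise WaveAbortError(
            f"could not find enough non-implausible design points "
            f"({len(e.accepted)}/{n} in {e.n_drawn} draws)"
        ) from e
    return res.design, res.acceptance_fraction


def run_wave(
    state: WaveState, simulator: Simulator, config: WaveConfig, seed: int
) -> WaveState:
    """Execute one wave of the history match and append it to the state."""
    rng = np.random.default_rng(seed)
    train_seed = int(rng.integers(2**31 - 1))
    diag_seed = int(rng.integers(2**31 - 1))
    mc_seed = int(rng.integers(2**31 - 1))

    design, _ = _design_next_wave(state, config.n_runs, train_seed, config)
    diag_design, _ = _design_next_wave(state, config.n_diagnostic, diag_seed, config)

    out_train = simulator(design.native)
    out_diag = simulator(diag_design.native)

    candidates = tuple(config.outputs) if config.outputs else tuple(state.observations)
    for name in candidates:
        if name not in out_train.columns:
            raise WaveAbortError(f"simulator did not produce output {name!r}")

    ok_train = ~out_train[list(candidates)].isna().any(axis=1).to_numpy()
    ok_diag = ~out_diag[list(candidates)].isna().any(axis=1).to_numpy()
    fail_frac = 1.0 - ok_train.mean()
    if fail_frac > config.max_failure_fraction:
        raise WaveAbortError(
            f"{fail_frac:.0%} of wave runs failed (limit "
            f"{config.max_failure_fraction:.0%})"
        )
    design = RunDesign(points=design.points[ok_train], ranges=design.ranges,
                       names=design.names, seed=design.seed)
    out_train = out_train.loc[ok_train].reset_index(drop=True)
    diag_design = RunDesign(points=diag_design.points[ok_diag], ranges=diag_design.ranges,
                            names=diag_design.names, seed=diag_design.seed)
    out_diag = out_diag.loc[ok_diag].reset_index(drop=True)

    prev_q = set(state.current_q())
    emulators: dict[str, FittedEmulator] = {}
    diagnostics: dict[str, DiagnosticReport] = {}
    admitted: list[str] = []
    for name in candidates:
        try:
            em = fit_emulator(design, out_train[name].to_numpy(), config.fit, name=name)
        except Exception as e:  # unfittable output: leave for a later wave
            if name in prev_q:
                raise WaveAbortError(f"previously admitted output {name!r} failed: {e}")
            continue
        rep = diagnose(em, diag_design, out_diag[name].to_numpy(),
                       coverage_threshold=config.admission_threshold)
        diagnostics[name] = rep
        if rep.passed or name in prev_q:
            emulators[name] = em
            admitted.append(name)

    if not admitted:
        raise WaveAbortError("no output passed emulator diagnostics this wave")
    # outputs are added to Q_k, never removed
    q_k = tuple(n for n in candidates if n in set(admitted) | prev_q)
    policy = _policy_from_config(config, q_k)

    wave = Wave(design=design, outputs=out_train, emulators=emulators,
                policy=policy, diagnostics=diagnostics, seed=seed)
    new_waves = state.waves + [wave]
    new_state = WaveState(
        ranges=state.ranges, names=state.names, observations=state.observations,
        waves=new_waves, volume_history=list(state.volume_history),
        provenance=dict(state.provenance),
    )

    frac, se, sample = _volume_and_sample(
        new_state, config.n_mc_volume, mc_seed, prev_cache=state.nonimplausible_cache
    )
    new_state.volume_history.append((frac, se))
    new_state.nonimplausible_cache = sample
    new_state.provenance.setdefault("wave_seeds", []).append(seed)

    # termination checks
    if frac == 0.0 and (sample is None or len(sample) == 0):
        new_state.status = "empty"
    elif sample is not None and len(sample) >= 10 and _is_converged(new_state, sample, config):
        new_state.status = "converged"
    else:
        new_state.status = "continue"
    return new_state


def _is_converged(state: WaveState, sample: np.ndarray, config: WaveConfig) -> bool:
    wave = state.waves[-1]
    for name in wave.q:
        em = wave.emulators.get(name)
        if em is None:
            return False
        _, var = em.predict_batch(sample)
        budget = state.observations[name].total_var
        if float(np.mean(var)) > config.convergence_fraction * budget:
            return False
    return True


def _volume_and_sample(
    state: WaveState, n_mc: int, seed: int, prev_cache: np.ndarray | None = None
) -> tuple[float, float, np.ndarray | None]:
    """Monte-Carlo volume of the chained region, with a nested fallback.

    A uniform sample over the initial space is exact but cannot resolve
    volumes far below 1/n_mc; when it finds too few members and a cache of
    previously non-implausible points exists, the estimate is refined by
    sampling uniformly inside the (padded) bounding box of the surviving
    cache and rescaling by the box's exact volume fraction.
    """
    rng = np.random.default_rng(seed)
    d = len(state.names)
    pts = rng.uniform(-1.0, 1.0, size=(n_mc, d))
    keep = state.membership(pts)
    frac = float(keep.mean())
    se = float(np.sqrt(max(frac * (1 - frac), 1e-12) / n_mc))
    sample = pts[keep] if keep.any() else None

    survivors = None
    if prev_cache is not None and len(prev_cache):
        alive = state.membership(prev_cache)
        if alive.any():
            survivors = prev_cache[alive]

    if keep.sum() < 50 and prev_cache is not None and len(prev_cache):
        # refine inside the padded bounding box of the previous wave's cache
        # (the chained region is nested inside it up to the padding)
        base = survivors if survivors is not None else prev_cache
        span = base.max(axis=0) - base.min(axis=0)
        lo = np.maximum(base.min(axis=0) - 0.05 * span - 1e-9, -1.0)
        hi = np.minimum(base.max(axis=0) + 0.05 * span + 1e-9, 1.0)
        box_frac = float(np.prod((hi - lo) / 2.0))
        n_hit, n_tried = 0, 0
        boxed = []
        # escalate until the region is resolved or the budget is spent
        while n_tried < 10 * n_mc and n_hit < 50:
            box_pts = lo + rng.uniform(0.0, 1.0, size=(n_mc, d)) * (hi - lo)
            keep_b = state.membership(box_pts)
            n_tried += n_mc
            n_hit += int(keep_b.sum())
            if keep_b.any():
                boxed.append(box_pts[keep_b])
        frac_b = n_hit / n_tried
        frac = box_frac * frac_b
        se = box_frac * float(np.sqrt(max(frac_b * (1 - frac_b), 1e-12) / n_tried))
        if boxed:
            boxed = np.vstack(boxed)
            sample = boxed if sample is None else np.vstack([sample, boxed])

    if survivors is not None:
        sample = survivors if sample is None else np.vstack([sample, survivors])

    # make sure the cache is big enough to steer the next wave's design box
    if sample is not None and 0 < len(sample) < 200 and frac > 0:
        lo = np.maximum(sample.min(axis=0) - 1e-9, -1.0)
        hi = np.minimum(sample.max(axis=0) + 1e-9, 1.0)
        more = lo + rng.uniform(0.0, 1.0, size=(4 * n_mc, d)) * (hi - lo)
        keep2 = state.membership(more)
        if keep2.any():
            sample = np.vstack([sample, more[keep2]])
    return frac, se, sample


def estimate_volume(
    state: WaveState, n_mc: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo fraction of the initial space that is non-implausible."""
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if not state.waves:
        return 1.0, 0.0
    frac, se, _ = _volume_and_sample(state, n_mc, seed,
                                     prev_cache=state.nonimplausible_cache)
    return frac, se


# --------------------------------------------------------------------------
# 2-D projections
# --------------------------------------------------------------------------

def _grid_edges(grid: int) -> np.ndarray:
    return np.linspace(-1.0, 1.0, grid + 1)


def _projection_points(
    d: int, pair: tuple[int, int], grid: int, n_mc: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    i, j = pair
    edges = _grid_edges(grid)
    centres = 0.5 * (edges[:-1] + edges[1:])
    cells = [(a, b) for a in centres for b in centres]
    pts = rng.uniform(-1.0, 1.0, size=(len(cells) * n_mc, d))
    for c, (a, b) in enumerate(cells):
        sl = slice(c * n_mc, (c + 1) * n_mc)
        pts[sl, i] = a
        pts[sl, j] = b
    return pts, centres


def min_implausibility_projection(
    state: WaveState, pair: tuple[int, int], grid: int = 20, n_mc: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Minimised final-wave implausibility I_P over a 2-D input plane.

    Cell (a, b) holds min over n_mc random settings of the other inputs of
    the final wave's maximum implausibility I_M.
    """
    i, j = pair
    if i == j:
        raise ValueError("projection indices must be distinct")
    if not state.waves:
        raise ValueError("no waves to project")
    rng = np.random.default_rng(seed)
    d = len(state.names)
    pts, _ = _projection_points(d, pair, grid, n_mc, rng)
    wave = state.waves[-1]
    I = wave_implausibilities(pts, wave.emulators, state.observations, wave.q)
    IM = I.max(axis=1)
    return IM.reshape(grid, grid, n_mc).min(axis=2)


def optical_depth(
    state: WaveState, pair: tuple[int, int], grid: int = 20, n_mc: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Fraction of the complementary input space that is non-implausible.

    Cell (a, b) holds the proportion of n_mc uniform settings of the other
    inputs for which the full point survives every wave; values lie in [0,1].
    """
    i, j = pair
    if i == j:
        raise ValueError("projection indices must be distinct")
    rng = np.random.default_rng(seed)
    d = len(state.names)
    pts, _ = _projection_points(d, pair, grid, n_mc, rng)
    keep = state.membership(pts)
    return keep.reshape(grid, grid, n_mc).mean(axis=2)


# --------------------------------------------------------------------------
# acceptable runs
# --------------------------------------------------------------------------

def simulator_implausibilities(
    outputs: pd.DataFrame, observations: Mapping[str, Observation],
    names: Sequence[str],
) -> np.ndarray:
    cols = []
    for name in names:
        o = observations[name]
        cols.append(
            implausibility_array(outputs[name].to_numpy(), 0.0, o.z, o.total_var, name)
        )
    return np.column_stack(cols)


def generate_acceptable_runs(
    state: WaveState,
    simulator: Simulator,
    n: int,
    max_draws: int,
    seed: int,
    policy: CutoffPolicy | None = None,
    batch: int = 200,
) -> pd.DataFrame:
    """Sample the final non-implausible region and certify runs by simulation.

    Uniform draws from the final region are simulated and retained only when
    the simulator-based implausibility (emulator variance set to zero)
    satisfies the certification policy for *all* observed outputs.  On budget
    exhaustion the partial table is returned with a warning.
    """
    if n == 0:
        return pd.DataFrame()
    rng = np.random.default_rng(seed)
    d = len(state.names)
    all_outputs = tuple(state.observations)
    policy = policy or CutoffPolicy(outputs=all_outputs, c_max=3.0)

    # propose from the bounding box of the cached non-implausible sample when
    # available; proposals are still filtered through chained membership
    cache = state.nonimplausible_cache
    if cache is not None and len(cache) >= 20:
        span = cache.max(axis=0) - cache.min(axis=0)
        lo = np.maximum(cache.min(axis=0) - 0.05 * span, -1.0)
        hi = np.minimum(cache.max(axis=0) + 0.05 * span, 1.0)
    else:
        lo, hi = np.full(d, -1.0), np.full(d, 1.0)

    kept: list[pd.DataFrame] = []
    n_kept = 0
    n_drawn = 0
    while n_kept < n and n_drawn < max_draws:
        # draw a batch of non-implausible candidates
        cand = np.empty((0, d))
        while len(cand) < batch and n_drawn < max_draws:
            m = min(50 * batch, max_draws - n_drawn)
            pts = lo + rng.uniform(0.0, 1.0, size=(m, d)) * (hi - lo)
            n_drawn += m
            keep = state.membership(pts)
            cand = np.vstack([cand, pts[keep]])
        if not len(cand):
            continue
        cand_design = RunDesign(points=cand, ranges=state.ranges, names=state.names)
        out = simulator(cand_design.native)
        ok = ~out[list(policy.outputs)].isna().any(axis=1).to_numpy()
        if not ok.any():
            continue
        out = out.loc[ok].reset_index(drop=True)
        native = cand_design.native[ok]
        I = simulator_implausibilities(out, state.observations, policy.outputs)
        acc = policy.accept(I)
        if acc.any():
            block = pd.concat(
                [pd.DataFrame(native[acc], columns=list(state.names)),
                 out.loc[acc].reset_index(drop=True)],
                axis=1,
            )
            kept.append(block)
            n_kept += int(acc.sum())
    if n_kept < n:
        warnings.warn(
            f"acceptable-run budget exhausted: {n_kept}/{n} found in {n_drawn} draws"
        )
    result = pd.concat(kept, ignore_index=True) if kept else pd.DataFrame(
        columns=list(state.names) + list(all_outputs)
    )
    return result.iloc[:n] if n_kept > n else result
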