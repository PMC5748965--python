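"""Space-filling and rejection-constrained input designs.

All designs live in *scaled* coordinates, the hypercube ``[-1, 1]^d``, with an
affine map to the native (usually log-transformed) parameter ranges.  Distances
and Gaussian-process correlation lengths are always measured in scaled space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist


class RangeError(ValueError):
    """A parameter range is non-finite or inverted."""


class BudgetExhaustedError(RuntimeError):
    """Rejection sampling ran out of draws before reaching its target.

    Carries the points accepted so far in ``accepted`` and the draw count in
    ``n_drawn``.
    """

    def __init__(self, msg: str, accepted: np.ndarray, n_drawn: int):
        super().__init__(msg)
        self.accepted = accepted
        self.n_drawn = n_drawn


def _validate_ranges(ranges: np.ndarray) -> np.ndarray:
    ranges = np.asarray(ranges, dtype=float)
    if ranges.ndim != 2 or ranges.shape[1] != 2:
        raise RangeError("ranges must be a (d, 2) array of (lower, upper) pairs")
    if not np.all(np.isfinite(ranges)):
        raise RangeError("ranges must be finite")
    if not np.all(ranges[:, 0] < ranges[:, 1]):
        bad = np.where(ranges[:, 0] >= ranges[:, 1])[0]
        raise RangeError(f"lower >= upper for range index(es) {bad.tolist()}")
    return ranges


@dataclass(frozen=True)
class RunDesign:
    """A set of simulator input points with their native-range mapping.

    ``points`` are scaled coordinates in ``[-1, 1]^d``; ``ranges`` give the
    per-dimension (lower, upper) pair in native units.  The native<->scaled map
    is affine and invertible.
    """

    points: np.ndarray
    ranges: np.ndarray
    names: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        ranges = _validate_ranges(self.ranges)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "ranges", ranges)
        if pts.shape[1] != ranges.shape[0]:
            raise ValueError("points and ranges disagree on dimension")
        if len(self.names) != ranges.shape[0]:
            raise ValueError("names and ranges disagree on dimension")
        if pts.size and (pts.min() < -1 - 1e-12 or pts.max() > 1 + 1e-12):
            raise ValueError("scaled coordinates must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]

    def to_native(self, scaled: np.ndarray | None = None) -> np.ndarray:
        x = self.points if scaled is None else np.atleast_2d(np.asarray(scaled, float))
        lo, hi = self.ranges[:, 0], self.ranges[:, 1]
        return lo + (x + 1.0) * 0.5 * (hi - lo)

    def to_scaled(self, native: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(native, float))
        lo, hi = self.ranges[:, 0], self.ranges[:, 1]
        return 2.0 * (x - lo) / (hi - lo) - 1.0

    @property
    def native(self) -> np.ndarray:
        return self.to_native()

    @classmethod
    def from_native(
        cls,
        native: np.ndarray,
        ranges: np.ndarray,
        names: Sequence[str],
        seed: int | None = None,
    ) -> "RunDesign":
        ranges = _validate_ranges(ranges)
        lo, hi = ranges[:, 0], ranges[:, 1]
        scaled = 2.0 * (np.atleast_2d(np.asarray(native, float)) - lo) / (hi - lo) - 1.0
        return cls(points=scaled, ranges=ranges, names=tuple(names), seed=seed)

    # --- persistence -----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write native-unit coordinates as CSV plus a JSON sidecar."""
        path = Path(path)
        import pandas as pd

        pd.DataFrame(self.native, columns=list(self.names)).to_csv(path, index=False)
        sidecar = {
            "ranges": self.ranges.tolist(),
            "names": list(self.names),
            "seed": self.seed,
            "coordinates": "native",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RunDesign":
        path = Path(path)
        import pandas as pd

        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path)
        return cls.from_native(
            df[meta["names"]].to_numpy(),
            np.asarray(meta["ranges"], float),
            meta["names"],
            seed=meta["seed"],
        )


def latin_hypercube(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """One Latin hypercube in scaled space, points at bin centres.

    Each dimension is split into ``n`` equal bins and the bin order permuted,
    so every dimension has exactly one point per bin.  Bin-centre placement
    (rather than within-bin jitter) keeps designs reproducible.
    """
    cols = [rng.permutation(n) for _ in range(d)]
    bins = np.stack(cols, axis=1).astype(float)
    return (bins + 0.5) / n * 2.0 - 1.0


def maximin_lhc(
    n: int,
    ranges: np.ndarray,
    n_candidates: int = 1000,
    seed: int = 0,
    names: Sequence[str] | None = None,
    _return_candidate_scores: bool = False,
):
    """Best-of-``n_candidates`` maximin Latin hypercube design.

    Candidate hypercubes are generated independently and the one with the
    largest minimum pairwise Euclidean distance (in scaled coordinates) is
    kept.
    """
    ranges = _validate_ranges(ranges)
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    d = ranges.shape[0]
    if names is None:
        names = tuple(f"x{i+1}" for i in range(d))
    rng = np.random.default_rng(seed)

    best_pts, best_score, scores = None, -np.inf, []
    for _ in range(n_candidates):
        pts = latin_hypercube(n, d, rng)
        score = np.inf if n == 1 else pdist(pts).min()
        scores.append(score)
        if score > best_score:
            best_score, best_pts = score, pts
    design = RunDesign(points=best_pts, ranges=ranges, names=tuple(names), seed=seed)
    if _return_candidate_scores:
        return design, np.asarray(scores)
    return design


@dataclass
class RejectionResult:
    """A rejection-sampled design plus acceptance bookkeeping.

    The acceptance fraction doubles as a crude Monte-Carlo estimate of the
    membership set's volume relative to the candidate distribution.
    """

    design: RunDesign
    n_drawn: int
    n_accepted: int

    @property
    def acceptance_fraction(self) -> float:
        return self.n_accepted / self.n_drawn if self.n_drawn else float("nan")


def rejection_sample(
    candidate_source: Callable[[int, np.random.Generator], np.ndarray],
    membership: Callable[[np.ndarray], np.ndarray],
    n_target: int,
    max_draws: int,
    seed: int,
    ranges: np.ndarray,
    names: Sequence[str] | None = None,
    batch: int = 2048,
) -> RejectionResult:
    """Draw scaled candidate points until ``n_target`` satisfy ``membership``.

    ``candidate_source(m, rng)`` must return an ``(m, d)`` array of scaled
    points; ``membership`` maps an ``(m, d)`` array to a boolean vector.
    Raises :class:`BudgetExhaustedError` when ``max_draws`` is spent first.
    """
    ranges = _validate_ranges(ranges)
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    if max_draws < n_target:
        raise ValueError("max_draws must be >= n_target")
    d = ranges.shape[0]
    if names is None:
        names = tuple(f"x{i+1}" for i in range(d))
    rng = np.random.default_rng(seed)

    accepted: list[np.ndarray] = []
    n_acc = 0
    n_drawn = 0
    while n_acc < n_target:
        m = min(batch, max_draws - n_drawn)
        if m <= 0:
            raise BudgetExhaustedError(
                f"accepted only {n_acc}/{n_target} points in {n_drawn} draws",
                np.vstack(accepted) if accepted else np.empty((0, d)),
                n_drawn,
            )
        cand = candidate_source(m, rng)
        keep = np.asarray(membership(cand), dtype=bool)
        if n_acc + keep.sum() >= n_target:
            # stop at the draw that completes the target so the acceptance
            # fraction reflects only the draws actually consumed
            cutoff = int(np.where(np.cumsum(keep) == n_target - n_acc)[0][0]) + 1
            cand, keep, m = cand[:cutoff], keep[:cutoff], cutoff
        n_drawn += m
        if keep.any():
            accepted.append(cand[keep])
            n_acc += int(keep.sum())
    pts = np.vstack(accepted)[:n_target] if accepted else np.empty((0, d))
    design = RunDesign(points=pts, ranges=ranges, names=tuple(names), seed=seed)
    return RejectionResult(design=design, n_drawn=n_drawn, n_accepted=n_target)


def uniform_source(m: int, rng: np.random.Generator, d: int) -> np.ndarray:
    return rng.uniform(-1.0, 1.0, size=(m, d))


def lhc_source(d: int) -> Callable[[int, np.random.Generator], np.ndarray]:
    """Candidate stream of Latin hypercube batches over the full scaled cube."""

    def source(m: int, rng: np.random.Generator) -> np.ndarray:
        return latin_hypercube(m, d, rng)

    return source
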