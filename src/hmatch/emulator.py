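"""Per-output Bayes linear emulators.

Each simulator output f_i(x) is emulated as

    f_i(x) = sum_j beta_ij g_ij(x_A) + u_i(x_A) + w_i(x)

where x_A are the active inputs, g_ij a pruned polynomial basis, u_i a
weakly-stationary Gaussian process with squared-exponential covariance
sigma_u^2 exp(-||x - x'||^2 / theta^2) over the active coordinates, and w_i a
nugget (white noise of variance sigma_w^2) carrying the effect of the inactive
inputs.  Beliefs about f_i at a new point are adjusted against the vector of
training outputs D_i through the Bayes linear update

    E_D(f(x))   = E(f(x)) + Cov(f(x), D) Var(D)^-1 (D - E(D))
    Var_D(f(x)) = Var(f(x)) - Cov(f(x), D) Var(D)^-1 Cov(D, f(x))

Two prior treatments of the regression coefficients are supported: a fully
specified (known) beta with Var(beta) = 0, and the vague-prior limit
Var(beta) -> infinity, implemented in its numerically stable universal-kriging
form, under which the regression surface coincides with its generalised
least-squares fit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from .design import RunDesign

# A monomial is a sorted tuple of (input index, power) pairs; () is the constant.
Monomial = tuple[tuple[int, int], ...]


class RankError(np.linalg.LinAlgError):
    pass


class FactorizationError(np.linalg.LinAlgError):
    pass


class NotFittedError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# basis handling
# --------------------------------------------------------------------------

def build_basis(active: Sequence[int], order: int) -> list[Monomial]:
    """All monomials of total degree <= order in the active inputs.

    Terms are ordered by total degree then lexicographically, which fixes the
    tie-break order used by the pruning procedures.  The constant term () is
    always first.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    active = sorted(set(int(a) for a in active))

    terms: list[Monomial] = [()]
    for deg in range(1, order + 1):
        terms.extend(_monomials_of_degree(active, deg))
    return terms


def _monomials_of_degree(active: list[int], deg: int) -> list[Monomial]:
    out: list[Monomial] = []

    # enumerate in lexicographic order of the exponent vectors
    def rec2(idx: int, remaining: int, cur: list[tuple[int, int]]):
        if idx == len(active):
            if remaining == 0:
                out.append(tuple(cur))
            return
        for p in range(remaining, -1, -1):
            if p:
                cur.append((active[idx], p))
            rec2(idx + 1, remaining - p, cur)
            if p:
                cur.pop()

    rec2(0, deg, [])
    return out


def eval_basis(points: np.ndarray, basis: Sequence[Monomial]) -> np.ndarray:
    """Design matrix of the basis terms at the given (scaled) points."""
    pts = np.atleast_2d(np.asarray(points, float))
    n = pts.shape[0]
    G = np.empty((n, len(basis)))
    for j, term in enumerate(basis):
        col = np.ones(n)
        for idx, power in term:
            col = col * pts[:, idx] ** power
        G[:, j] = col
    return G


def basis_to_str(term: Monomial) -> str:
    if not term:
        return "1"
    return "*".join(f"x{i}^{p}" if p > 1 else f"x{i}" for i, p in term)


# --------------------------------------------------------------------------
# AIC-guided term selection
# --------------------------------------------------------------------------

def _aic(n: int, rss: float, k: int) -> float:
    # Small-sample corrected AIC (AICc) of a Gaussian fit, up to an additive
    # constant; K = k regression coefficients plus the error variance.  The
    # correction term guards against the heavy selection bias of stepwise
    # searches when the candidate pool is large relative to the run count.
    rss = max(rss, 1e-300)
    K = k + 1
    corr = 2.0 * K * (K + 1) / max(n - K - 1, 1)
    return n * math.log(rss / n) + 2.0 * K + corr


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise RankError("collinear design matrix in OLS fit")
    r = y - X @ coef
    return float(r @ r)


def forward_aic(
    C: np.ndarray, y: np.ndarray, always: Sequence[int] = (0,), max_terms: int | None = None
) -> list[int]:
    """Greedy forward selection by AIC over the candidate columns of ``C``.

    Exact single-term RSS reductions are scored against the orthonormal basis
    of the already-selected terms, so each step costs one matrix product.
    Returns the selected column indices (the ``always`` columns first).
    """
    n, m = C.shape
    sel = list(always)
    Q = np.linalg.qr(C[:, sel])[0]
    r = y - Q @ (Q.T @ y)
    rss = float(r @ r)
    aic = _aic(n, rss, len(sel))
    available = np.ones(m, dtype=bool)
    available[list(always)] = False
    if max_terms is None:
        # protect residual degrees of freedom: never spend more than a fifth
        # of the runs on regression terms
        max_terms = min(m, max(len(always) + 1, n // 5))

    while available.any() and len(sel) < max_terms:
        Cp = C - Q @ (Q.T @ C)
        norms2 = np.einsum("ij,ij->j", Cp, Cp)
        scores = np.full(m, -np.inf)
        ok = available & (norms2 > 1e-10 * n)
        proj = Cp.T @ r
        with np.errstate(divide="ignore", invalid="ignore"):
            scores[ok] = proj[ok] ** 2 / norms2[ok]
        best = int(np.argmax(scores))
        if not np.isfinite(scores[best]) or scores[best] <= 0:
            break
        rss_new = rss - float(scores[best])
        aic_new = _aic(n, rss_new, len(sel) + 1)
        if aic_new >= aic:
            break
        qnew = Cp[:, best] / math.sqrt(norms2[best])
        Q = np.column_stack([Q, qnew])
        r = r - qnew * (qnew @ r)
        rss, aic = rss_new, aic_new
        sel.append(best)
        available[best] = False
    return sel


def backward_aic(C: np.ndarray, y: np.ndarray, always: Sequence[int] = (0,)) -> list[int]:
    """Backward elimination by AIC, never dropping the ``always`` columns."""
    n, m = C.shape
    sel = list(range(m))
    rss = _ols_rss(C, y)
    aic = _aic(n, rss, len(sel))
    improved = True
    while improved and len(sel) > len(always):
        improved = False
        best_drop, best_aic, best_rss = None, aic, rss
        for j in sel:
            if j in always:
                continue
            trial = [k for k in sel if k != j]
            try:
                rss_t = _ols_rss(C[:, trial], y)
            except RankError:
                continue
            aic_t = _aic(n, rss_t, len(trial))
            if aic_t < best_aic:
                best_drop, best_aic, best_rss = j, aic_t, rss_t
        if best_drop is not None:
            sel.remove(best_drop)
            aic, rss = best_aic, best_rss
            improved = True
    return sel


def select_active_inputs(
    design: RunDesign, values: np.ndarray, criterion: str = "aic"
) -> list[int]:
    """Active inputs by forward-backward stepwise selection on linear terms.

    Fits first-order polynomials in the scaled inputs and keeps the inputs
    whose linear terms survive stepwise AIC.  Deterministic for a given
    design, values and criterion.
    """
    if criterion != "aic":
        raise ValueError("only the AIC criterion is implemented")
    y = np.asarray(values, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("output values must be finite")
    n, d = design.n, design.d
    if n < d + 2:
        raise ValueError(f"need at least d+2={d+2} runs for a first-order fit, got {n}")
    X = np.column_stack([np.ones(n), design.points])
    try:
        _ols_rss(X, y)
    except RankError as e:
        raise RankError("design has collinear columns") from e

    fsel = forward_aic(X, y, always=(0,))
    kept = backward_aic(X[:, fsel], y, always=(0,))
    return sorted(fsel[j] - 1 for j in kept if fsel[j] != 0)


def select_basis_terms(
    design: RunDesign,
    values: np.ndarray,
    active: Sequence[int],
    order: int = 3,
) -> list[Monomial]:
    """Prune the complete order-``order`` basis in the active inputs by AIC.

    Backward elimination from the full basis when it is small enough to fit
    (fewer than half the runs); otherwise greedy forward selection over the
    same candidate list.  The constant term is always retained.
    """
    y = np.asarray(values, float)
    full = build_basis(active, order)
    n = design.n
    C = eval_basis(design.points, full)
    # backward elimination refits O(q^2) models, so it is reserved for bases
    # small enough to make that cheap; larger candidate sets use the greedy
    # forward search under the same criterion
    if len(full) <= min(max(2, n // 2), 80):
        keep = backward_aic(C, y, always=(0,))
    else:
        keep = forward_aic(C, y, always=(0,))
    keep = sorted(keep)
    return [full[j] for j in keep]


# --------------------------------------------------------------------------
# covariance and the fitted emulator
# --------------------------------------------------------------------------

def gp_covariance(x: np.ndarray, x2: np.ndarray, sigma_u2: float, theta: float) -> float:
    """Squared-exponential covariance sigma_u^2 exp(-||x-x2||^2/theta^2)."""
    if theta <= 0:
        raise ValueError("correlation length theta must be positive")
    x = np.asarray(x, float).ravel()
    x2 = np.asarray(x2, float).ravel()
    if x.shape != x2.shape:
        raise ValueError("points must share a dimension")
    d2 = float(np.sum((x - x2) ** 2))
    return sigma_u2 * math.exp(-d2 / theta**2)


def _corr_matrix(A: np.ndarray, B: np.ndarray, theta: float) -> np.ndarray:
    if A.shape[1] == 0:  # no active inputs: the GP collapses to a constant
        return np.ones((A.shape[0], B.shape[0]))
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / theta**2)


@dataclass
class EmulatorSpec:
    """Hyperparameters and structure of one output's emulator."""

    active: tuple[int, ...]
    basis: tuple[Monomial, ...]
    theta: float
    sigma_u2: float
    sigma_w2: float
    nugget_proportion: float
    beta_mean: tuple[float, ...] | None = None  # None => vague prior limit

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.sigma_u2 < 0 or self.sigma_w2 < 0:
            raise ValueError("variances must be non-negative")
        if not 0 <= self.nugget_proportion <= 1:
            raise ValueError("nugget proportion must lie in [0, 1]")
        for term in self.basis:
            for idx, _ in term:
                if idx not in self.active:
                    raise ValueError(
                        f"basis term {basis_to_str(term)} references inactive input {idx}"
                    )

    @property
    def sigma_c2(self) -> float:
        return self.sigma_u2 + self.sigma_w2


@dataclass
class FitConfig:
    """Options controlling emulator fitting.

    theta is the scaled-space correlation length (0.35 suits third-order
    regression surfaces); nugget_proportion p sets sigma_w^2 = p sigma_c^2
    with sigma_c^2 the squared residual standard error of the regression fit.
    """

    order: int = 3
    theta: float = 0.35
    nugget_proportion: float = 0.05
    active: Sequence[int] | None = None
    basis: Sequence[Monomial] | None = None
    beta_mean: Sequence[float] | None = None  # known-coefficient prior
    sigma_u2: float | None = None
    sigma_w2: float | None = None
    select_basis: bool = True


@dataclass
class Prediction:
    mean: float
    variance: float


class FittedEmulator:
    """One output's emulator, trained and ready for adjusted predictions."""

    def __init__(self, spec: EmulatorSpec, design: RunDesign, values: np.ndarray,
                 name: str = ""):
        self.spec = spec
        self.design = design
        self.D = np.asarray(values, float).ravel()
        self.name = name
        if self.D.size != design.n:
            raise ValueError("values length must equal the design run count")
        self._build_cache()

    # --- adjustment cache -------------------------------------------------
    def _build_cache(self):
        s = self.spec
        Xa = self.design.points[:, list(s.active)]
        self._Xa = Xa
        R = _corr_matrix(Xa, Xa, s.theta)
        if s.sigma_w2 == 0.0:
            # without a nugget, coincident active coordinates make Var(D)
            # exactly singular
            dup = self._duplicate_rows()
            if dup:
                raise FactorizationError(
                    f"Var(D) is singular: duplicated design rows {dup}"
                )
        K = s.sigma_u2 * R + s.sigma_w2 * np.eye(self.design.n)
        scale = max(s.sigma_c2, 1e-12)
        K = K + 1e-10 * scale * np.eye(self.design.n)
        try:
            self._chol = cho_factor(K, lower=True)
        except np.linalg.LinAlgError:
            dup = self._duplicate_rows()
            raise FactorizationError(
                "Var(D) is singular"
                + (f"; duplicated design rows {dup}" if dup else "")
            )
        G = eval_basis(self.design.points, s.basis)
        self._G = G
        self._KiG = cho_solve(self._chol, G)
        if s.beta_mean is None:
            A = G.T @ self._KiG
            try:
                self._Achol = cho_factor(A, lower=True)
            except np.linalg.LinAlgError:
                raise FactorizationError("G' Var(D)^-1 G is singular (collinear basis)")
            self.beta = cho_solve(self._Achol, G.T @ cho_solve(self._chol, self.D))
        else:
            self._Achol = None
            self.beta = np.asarray(s.beta_mean, float)
            if self.beta.size != len(s.basis):
                raise ValueError("beta_mean length must equal the basis size")
        resid = self.D - G @ self.beta
        self._alpha = cho_solve(self._chol, resid)
        self._var_warned = False

    def _duplicate_rows(self) -> list[tuple[int, int]]:
        pts = self._Xa
        dups = []
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.allclose(pts[i], pts[j], atol=1e-12):
                    dups.append((i, j))
        return dups

    # --- prediction -------------------------------------------------------
    def predict_batch(self, points: np.ndarray, chunk: int = 4096):
        """Adjusted expectation and variance at many (scaled) points."""
        pts = np.atleast_2d(np.asarray(points, float))
        if pts.shape[1] != self.design.d:
            raise ValueError("points must have the design's input dimension")
        s = self.spec
        means = np.empty(pts.shape[0])
        varis = np.empty(pts.shape[0])
        for start in range(0, pts.shape[0], chunk):
            sl = slice(start, start + chunk)
            P = pts[sl]
            Pa = P[:, list(s.active)]
            r = s.sigma_u2 * _corr_matrix(Pa, self._Xa, s.theta)  # (m, n)
            Gx = eval_basis(P, s.basis)
            means[sl] = Gx @ self.beta + r @ self._alpha
            t = cho_solve(self._chol, r.T)  # K^-1 r'
            var = s.sigma_c2 - np.einsum("ij,ji->i", r, t)
            if self._Achol is not None:
                u = Gx.T - self._KiG.T @ r.T  # (q, m)
                w = cho_solve(self._Achol, u)
                var = var + np.einsum("ij,ij->j", u, w)
            varis[sl] = var
        neg_tol = 1e-10 * max(s.sigma_c2, 1.0)
        if np.any(varis < -neg_tol):
            worst = float(varis.min())
            raise FloatingPointError(
                f"emulator variance {worst} below round-off tolerance -{neg_tol}"
            )
        if np.any(varis < 0) and not self._var_warned:
            warnings.warn("clamping slightly negative emulator variances to zero")
            self._var_warned = True
        np.clip(varis, 0.0, None, out=varis)
        return means, varis

    def predict(self, x: np.ndarray) -> Prediction:
        m, v = self.predict_batch(np.atleast_2d(x))
        return Prediction(mean=float(m[0]), variance=float(v[0]))

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        s = self.spec
        return {
            "name": self.name,
            "spec": {
                "active": list(s.active),
                "basis": [list(map(list, t)) for t in s.basis],
                "theta": s.theta,
                "sigma_u2": s.sigma_u2,
                "sigma_w2": s.sigma_w2,
                "nugget_proportion": s.nugget_proportion,
                "beta_mean": None if s.beta_mean is None else list(s.beta_mean),
            },
            "design": {
                "points": self.design.points.tolist(),
                "ranges": self.design.ranges.tolist(),
                "names": list(self.design.names),
                "seed": self.design.seed,
            },
            "D": self.D.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedEmulator":
        sp = doc["spec"]
        spec = EmulatorSpec(
            active=tuple(sp["active"]),
            basis=tuple(tuple((int(i), int(p)) for i, p in t) for t in sp["basis"]),
            theta=sp["theta"],
            sigma_u2=sp["sigma_u2"],
            sigma_w2=sp["sigma_w2"],
            nugget_proportion=sp["nugget_proportion"],
            beta_mean=None if sp["beta_mean"] is None else tuple(sp["beta_mean"]),
        )
        dd = doc["design"]
        design = RunDesign(
            points=np.asarray(dd["points"], float),
            ranges=np.asarray(dd["ranges"], float),
            names=tuple(dd["names"]),
            seed=dd["seed"],
        )
        return cls(spec, design, np.asarray(doc["D"], float), name=doc.get("name", ""))

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "FittedEmulator":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_emulator(
    design: RunDesign, values: np.ndarray, config: FitConfig | None = None, name: str = ""
) -> FittedEmulator:
    """Fit one output's emulator to a set of training runs.

    With the default vague prior on the coefficients the regression surface
    equals its least-squares fit, sigma_c^2 is set to the squared residual
    standard error of that fit, sigma_w^2 = p sigma_c^2, and theta defaults to
    0.35 in scaled units.
    """
    config = config or FitConfig()
    y = np.asarray(values, float).ravel()
    if y.size != design.n:
        raise ValueError("values length must equal the design run count")

    if config.active is not None:
        active = sorted(int(a) for a in config.active)
    elif config.basis is not None:
        active = sorted({idx for term in config.basis for idx, _ in term})
    else:
        active = select_active_inputs(design, y)

    if config.basis is not None:
        basis = [tuple(t) for t in config.basis]
    elif config.select_basis and config.beta_mean is None:
        basis = select_basis_terms(design, y, active, config.order)
    else:
        basis = build_basis(active, config.order)

    n, q = design.n, len(basis)
    if config.beta_mean is None and n <= q:
        raise ValueError(f"need more runs ({n}) than basis terms ({q})")

    if config.beta_mean is not None:
        # fully specified coefficients: sigma_u2 must be supplied
        if config.sigma_u2 is None:
            raise ValueError("known-beta emulators need an explicit sigma_u2")
        sigma_u2 = float(config.sigma_u2)
        sigma_w2 = float(config.sigma_w2 or 0.0)
        p = sigma_w2 / (sigma_u2 + sigma_w2) if (sigma_u2 + sigma_w2) > 0 else 0.0
        spec = EmulatorSpec(
            active=tuple(active), basis=tuple(basis), theta=config.theta,
            sigma_u2=sigma_u2, sigma_w2=sigma_w2, nugget_proportion=p,
            beta_mean=tuple(float(b) for b in config.beta_mean),
        )
        return FittedEmulator(spec, design, y, name=name)

    G = eval_basis(design.points, basis)
    coef, _, rank, _ = np.linalg.lstsq(G, y, rcond=None)
    if rank < q:
        raise RankError("collinear basis columns in the regression fit")
    resid = y - G @ coef
    dof = max(n - q, 1)
    sigma_c2 = float(resid @ resid) / dof
    sigma_c2 = max(sigma_c2, 1e-14 * max(1.0, float(y @ y) / n))
    if config.sigma_u2 is not None or config.sigma_w2 is not None:
        sigma_u2 = float(config.sigma_u2 or 0.0)
        sigma_w2 = float(config.sigma_w2 or 0.0)
        tot = sigma_u2 + sigma_w2
        p = sigma_w2 / tot if tot > 0 else 0.0
    else:
        p = config.nugget_proportion
        sigma_w2 = p * sigma_c2
        sigma_u2 = (1.0 - p) * sigma_c2
    spec = EmulatorSpec(
        active=tuple(active), basis=tuple(basis), theta=config.theta,
        sigma_u2=sigma_u2, sigma_w2=sigma_w2, nugget_proportion=p, beta_mean=None,
    )
    return FittedEmulator(spec, design, y, name=name)


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

@dataclass
class DiagnosticReport:
    """Three-sigma coverage of emulator prediction intervals on held-out runs."""

    coverage: float
    std_errors: np.ndarray
    threshold: float
    passed: bool


def diagnose(
    em: FittedEmulator,
    validation_design: RunDesign,
    validation_values: np.ndarray,
    coverage_threshold: float = 0.95,
    interval_sigmas: float = 3.0,
) -> DiagnosticReport:
    """Check |truth - mean| <= 3 sqrt(variance) on a fresh validation design."""
    y = np.asarray(validation_values, float).ravel()
    if y.size == 0:
        raise ValueError("validation set is empty")
    if y.size != validation_design.n:
        raise ValueError("validation values and design lengths differ")
    mean, var = em.predict_batch(validation_design.points)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        std_err = np.where(sd > 0, (y - mean) / sd, np.where(y == mean, 0.0, np.inf))
    coverage = float(np.mean(np.abs(y - mean) <= interval_sigmas * sd))
    return DiagnosticReport(
        coverage=coverage,
        std_errors=std_err,
        threshold=coverage_threshold,
        passed=coverage >= coverage_threshold,
    )
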