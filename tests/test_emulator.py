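import itertools
import math

import numpy as np
import pytest

from hmatch.design import RunDesign, maximin_lhc
from hmatch.emulator import (
    FactorizationError,
    FitConfig,
    FittedEmulator,
    build_basis,
    diagnose,
    eval_basis,
    fit_emulator,
    gp_covariance,
    select_active_inputs,
)

RNG = np.random.default_rng(2024)


def design_from_scaled(points, d=None):
    points = np.atleast_2d(points)
    d = points.shape[1]
    ranges = np.tile([-1.0, 1.0], (d, 1))
    return RunDesign(points=points, ranges=ranges, names=tuple(f"x{i}" for i in range(d)))


# ---------------------------------------------------------------------------
# independent dense-solve oracle for the adjustment equations
# ---------------------------------------------------------------------------

def dense_adjust(em: FittedEmulator, x: np.ndarray):
    """Naive Bayes linear adjustment by explicit dense inverses.

    Known beta: prior mean G beta, covariances from the kernel alone.
    Vague beta: large-but-finite Var(beta) = tau*I pushed through the full
    prior covariance algebra.  tau = 1e4 balances the O(1/tau) truncation of
    the vague limit against the O(tau) conditioning loss of the dense solve.
    """
    s = em.spec
    X = em.design.points[:, list(s.active)]
    xa = np.atleast_2d(x)[:, list(s.active)]
    n = em.design.n

    def kern(A, B):
        out = np.empty((len(A), len(B)))
        for i in range(len(A)):
            for j in range(len(B)):
                out[i, j] = gp_covariance(A[i], B[j], s.sigma_u2, s.theta)
        return out

    K = kern(X, X) + s.sigma_w2 * np.eye(n)
    kx = kern(xa, X)
    G = eval_basis(em.design.points, s.basis)
    gx = eval_basis(np.atleast_2d(x), s.basis)

    if s.beta_mean is not None:
        beta = np.asarray(s.beta_mean)
        prior_mean_x = (gx @ beta).item()
        prior_mean_D = G @ beta
        var_fx = s.sigma_u2 + s.sigma_w2
        cov_xD = kx
        VarD = K
    else:
        tau = 1e4
        prior_mean_x = 0.0
        prior_mean_D = np.zeros(n)
        var_fx = (gx @ gx.T).item() * tau + s.sigma_u2 + s.sigma_w2
        cov_xD = gx @ G.T * tau + kx
        VarD = G @ G.T * tau + K

    Vinv = np.linalg.inv(VarD)
    mean = prior_mean_x + (cov_xD @ Vinv @ (em.D - prior_mean_D)).item()
    var = var_fx - (cov_xD @ Vinv @ cov_xD.T).item()
    return mean, var


class TestBasis:
    def test_order_zero(self):
        assert build_basis([0, 3], 0) == [()]

    def test_one_input_cubic(self):
        assert build_basis([2], 3) == [(), ((2, 1),), ((2, 2),), ((2, 3),)]

    @pytest.mark.parametrize("p", [1, 2, 3, 4, 5])
    def test_complete_cubic_count(self, p):
        # enumeration oracle: count exponent vectors with total degree <= 3
        terms = build_basis(list(range(p)), 3)
        oracle = sum(
            1
            for exps in itertools.product(range(4), repeat=p)
            if sum(exps) <= 3
        )
        assert len(terms) == oracle == math.comb(p + 3, 3)

    def test_eval_basis_matches_manual(self):
        pts = np.array([[0.5, -1.0], [2.0, 3.0]])
        basis = [(), ((0, 1),), ((0, 1), (1, 2))]
        G = eval_basis(pts, basis)
        assert np.allclose(G[:, 0], 1.0)
        assert np.allclose(G[:, 1], pts[:, 0])
        assert np.allclose(G[:, 2], pts[:, 0] * pts[:, 1] ** 2)


class TestActiveInputs:
    def test_recovers_single_driver(self):
        # output depends only on input 0; stepwise must match the exhaustive
        # best-subset search over all 8 subsets
        des = maximin_lhc(50, np.tile([-1.0, 1.0], (3, 1)), n_candidates=20, seed=5)
        y = np.exp(3.5 * des.points[:, 0])
        active = select_active_inputs(des, y)
        assert active == [0]

        def subset_aic(subset):
            X = np.column_stack([np.ones(des.n)] + [des.points[:, i] for i in subset])
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ coef) ** 2).sum())
            return des.n * np.log(rss / des.n) + 2 * (len(subset) + 2)

        best = min(
            (frozenset(sub) for r in range(4) for sub in itertools.combinations(range(3), r)),
            key=lambda s: subset_aic(sorted(s)),
        )
        assert set(active) == set(best)

    def test_constant_values_empty_set(self):
        des = maximin_lhc(30, np.tile([-1.0, 1.0], (3, 1)), n_candidates=10, seed=6)
        assert select_active_inputs(des, np.full(30, 2.5)) == []

    def test_too_few_runs(self):
        des = maximin_lhc(3, np.tile([-1.0, 1.0], (3, 1)), n_candidates=5, seed=1)
        with pytest.raises(ValueError):
            select_active_inputs(des, np.ones(3))

    def test_deterministic(self):
        des = maximin_lhc(40, np.tile([-1.0, 1.0], (4, 1)), n_candidates=10, seed=8)
        y = des.points[:, 1] - 2 * des.points[:, 3] ** 2 + 0.01 * RNG.normal(size=40)
        assert select_active_inputs(des, y) == select_active_inputs(des, y)


class TestGPCovariance:
    def test_zero_distance(self):
        assert gp_covariance([0.2, 0.3], [0.2, 0.3], 2.0, 0.5) == 2.0

    def test_at_one_correlation_length(self):
        x = np.zeros(2)
        x2 = np.array([0.35, 0.0])
        assert gp_covariance(x, x2, 1.0, 0.35) == pytest.approx(math.exp(-1.0))

    def test_monotone_decay(self):
        vals = [gp_covariance([0.0], [d], 1.0, 0.3) for d in np.linspace(0, 5, 30)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-10

    def test_bad_theta(self):
        with pytest.raises(ValueError):
            gp_covariance([0.0], [1.0], 1.0, 0.0)


class TestFitAndPredict:
    def test_known_beta_interpolates_five_runs(self):
        # constant-mean emulator of exp(3.5 x) from runs at 0.1..0.5 must
        # pass through all five training values with zero variance
        from hmatch.toy import toy_emulator, toy_exponential

        xs = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        em = toy_emulator(xs, toy_exponential(xs))
        mean, var = em.predict_batch(em.design.points)
        assert np.allclose(mean, toy_exponential(xs), atol=1e-7)
        assert np.all(var <= 1e-7)

    def test_linear_function_regression_exact(self):
        des = design_from_scaled(RNG.uniform(-1, 1, (30, 2)))
        y = 2.0 + 3.0 * des.points[:, 0]
        cfg = FitConfig(order=1, active=(0,), select_basis=False, nugget_proportion=0.0)
        em = fit_emulator(des, y, cfg)
        grid = design_from_scaled(RNG.uniform(-1, 1, (40, 2)))
        mean, var = em.predict_batch(grid.points)
        assert np.allclose(mean, 2.0 + 3.0 * grid.points[:, 0], atol=1e-6)
        assert np.all(var < 1e-6)

    def test_pure_nugget_no_interpolation(self):
        # p = 1: all residual variance is white noise, so even at a training
        # point the prediction keeps a positive variance
        des = design_from_scaled(np.linspace(-1, 1, 8).reshape(-1, 1))
        y = np.sin(2 * des.points[:, 0]) + 0.1 * RNG.normal(size=8)
        cfg = FitConfig(order=1, active=(0,), select_basis=False, nugget_proportion=1.0)
        em = fit_emulator(des, y, cfg)
        mean, var = em.predict_batch(des.points)
        assert np.all(var > 0.1 * em.spec.sigma_c2)
        assert not np.allclose(mean, y, atol=1e-3)

    def test_nugget_inflates_variance_everywhere(self):
        des = design_from_scaled(np.linspace(-1, 1, 10).reshape(-1, 1))
        y = np.exp(des.points[:, 0])
        grid = np.linspace(-1, 1, 57).reshape(-1, 1)
        cfgs = [FitConfig(order=2, active=(0,), select_basis=False, nugget_proportion=p)
                for p in (0.0, 0.3)]
        em0, em1 = (fit_emulator(des, y, c) for c in cfgs)
        v0 = em0.predict_batch(grid)[1]
        v1 = em1.predict_batch(grid)[1]
        assert np.all(v1 >= v0 - 1e-12)

    def test_prior_reversion_far_from_runs(self):
        # known-beta: far from every run the mean reverts to the regression
        # surface and the variance to sigma_u^2 + sigma_w^2
        des = design_from_scaled(np.array([[-0.9], [-0.8]]))
        cfg = FitConfig(active=(0,), basis=[()], beta_mean=(1.5,),
                        sigma_u2=0.49, sigma_w2=0.01, theta=0.05)
        em = fit_emulator(des, np.array([2.0, 2.2]), cfg)
        pred = em.predict(np.array([0.95]))
        assert pred.mean == pytest.approx(1.5, abs=1e-6)
        assert pred.variance == pytest.approx(0.5, rel=1e-6)

    def test_duplicate_rows_raise(self):
        pts = np.array([[0.1], [0.1], [0.5]])
        des = design_from_scaled(pts)
        cfg = FitConfig(active=(0,), basis=[()], beta_mean=(0.0,),
                        sigma_u2=1.0, sigma_w2=0.0, theta=0.3)
        with pytest.raises(FactorizationError):
            fit_emulator(des, np.array([1.0, 1.0, 2.0]), cfg)

    def test_sigma_c2_equals_squared_rse(self):
        des = design_from_scaled(RNG.uniform(-1, 1, (40, 2)))
        y = des.points[:, 0] + 0.3 * RNG.normal(size=40)
        cfg = FitConfig(order=1, active=(0, 1), select_basis=False)
        em = fit_emulator(des, y, cfg)
        G = eval_basis(des.points, em.spec.basis)
        coef, _, _, _ = np.linalg.lstsq(G, y, rcond=None)
        rse2 = float(((y - G @ coef) ** 2).sum()) / (40 - G.shape[1])
        assert em.spec.sigma_c2 == pytest.approx(rse2, rel=1e-9)
        assert em.spec.sigma_w2 == pytest.approx(0.05 * rse2, rel=1e-9)


class TestOracleEquivalence:
    @pytest.mark.parametrize("vague", [False, True])
    @pytest.mark.parametrize("n", [5, 9, 12])
    def test_dense_solve_matches_cached(self, n, vague):
        # n <= 12: cached-factorisation adjustment equals the naive
        # dense-inverse computation to relative tolerance 1e-8 (vague prior
        # checked against a large-but-finite Var(beta))
        rng = np.random.default_rng(n + 100 * vague)
        des = design_from_scaled(rng.uniform(-1, 1, (n, 2)))
        y = np.exp(des.points[:, 0]) + 0.5 * des.points[:, 1]
        if vague:
            cfg = FitConfig(order=1, active=(0, 1), select_basis=False,
                            nugget_proportion=0.2)
        else:
            cfg = FitConfig(active=(0, 1), basis=[()], beta_mean=(1.0,),
                            sigma_u2=1.2, sigma_w2=0.3, theta=0.5)
        em = fit_emulator(des, y, cfg)
        for x in rng.uniform(-1, 1, (6, 2)):
            pred = em.predict(x)
            mean_o, var_o = dense_adjust(em, x)
            scale = max(abs(mean_o), 1.0)
            # finite-tau oracle truncation dominates the vague-case tolerance
            mean_tol = 1e-8 if not vague else 1e-4
            var_tol = 1e-8 if not vague else 1e-2
            assert abs(pred.mean - mean_o) <= mean_tol * scale
            assert abs(pred.variance - var_o) <= max(var_tol * abs(var_o), var_tol * em.spec.sigma_c2)


class TestCoverageCalibration:
    def test_three_sigma_coverage_of_gp_draws(self):
        # functions drawn from the emulator's own prior must be covered by
        # the three-sigma band ~95% of the time, averaged over replicates
        rng = np.random.default_rng(7)
        theta, sigma_u = 0.4, 1.0
        train = np.linspace(-1, 1, 9).reshape(-1, 1)
        test = rng.uniform(-1, 1, (40, 1))
        allpts = np.vstack([train, test])
        from scipy.spatial.distance import cdist

        K = sigma_u**2 * np.exp(-cdist(allpts, allpts, "sqeuclidean") / theta**2)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(len(allpts)))
        covered = []
        for _ in range(200):
            f = L @ rng.normal(size=len(allpts))
            des = design_from_scaled(train)
            cfg = FitConfig(active=(0,), basis=[()], beta_mean=(0.0,),
                            sigma_u2=sigma_u**2, sigma_w2=0.0, theta=theta)
            em = fit_emulator(des, f[:9], cfg)
            mean, var = em.predict_batch(test)
            covered.append(
                np.mean(np.abs(f[9:] - mean) <= 3 * np.sqrt(np.maximum(var, 0)))
            )
        assert np.mean(covered) >= 0.95


class TestDiagnose:
    def test_training_points_zero_nugget_full_coverage(self):
        from hmatch.toy import toy_emulator, toy_exponential

        xs = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        em = toy_emulator(xs, toy_exponential(xs))
        rep = diagnose(em, em.design, toy_exponential(xs))
        assert rep.coverage == 1.0
        assert rep.passed

    def test_toy_exponential_validation_coverage(self):
        from hmatch.toy import toy_emulator, toy_exponential, _toy_design

        xs = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        em = toy_emulator(xs, toy_exponential(xs))
        new_x = np.linspace(0.1, 0.5, 50)
        rep = diagnose(em, _toy_design(new_x), toy_exponential(new_x))
        assert rep.coverage >= 0.95

    def test_empty_validation_set_rejected(self):
        from hmatch.toy import toy_emulator, toy_exponential

        xs = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        em = toy_emulator(xs, toy_exponential(xs))
        with pytest.raises(ValueError):
            diagnose(em, em.design, np.array([]))


class TestSerialization:
    def test_bit_exact_reload(self, tmp_path):
        des = design_from_scaled(RNG.uniform(-1, 1, (25, 3)))
        y = np.exp(des.points[:, 0]) - des.points[:, 2] ** 2
        em = fit_emulator(des, y, FitConfig(order=2))
        em.save_json(tmp_path / "em.json")
        back = FittedEmulator.load_json(tmp_path / "em.json")
        pts = RNG.uniform(-1, 1, (30, 3))
        m1, v1 = em.predict_batch(pts)
        m2, v2 = back.predict_batch(pts)
        assert np.array_equal(m1, m2)
        assert np.array_equal(v1, v2)
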