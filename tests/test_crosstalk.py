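import math
import warnings

import numpy as np
import pandas as pd
import pytest

from hmatch import crosstalk as ct
from hmatch.crosstalk import (
    ELIMINATED,
    INPUT_NAMES,
    OUTPUT_NAMES,
    PARAM_NAMES,
    SCENARIO_TABLE,
    STATE_NAMES,
    InputRangeError,
    Scenario,
    SolverOptions,
    expand_inputs,
    initial_state,
    rhs,
    solve_equilibrium,
    trend_outputs,
)

RNG = np.random.default_rng(99)


def random_input(rng):
    lo, hi = ct.LOG_RANGES[:, 0], ct.LOG_RANGES[:, 1]
    return lo + rng.uniform(0, 1, len(lo)) * (hi - lo)


class TestExpandInputs:
    def test_dimension_counts(self):
        # 32 rate constants; the control k6 and 8 eliminated denominators
        # reduce the search space to 23 log-ratios
        assert len(PARAM_NAMES) == 32
        assert len(ELIMINATED) == 8
        assert len(INPUT_NAMES) == 23
        assert len(ct.INPUT_NAMES_K2C0) == 22

    def test_midpoint_positive_and_finite(self):
        params = expand_inputs(ct.centre_input())
        for name in PARAM_NAMES:
            if name == "k6":
                continue
            assert params[name] > 0
            assert math.isfinite(params[name])
        for name in ELIMINATED:
            assert params[name] == 1.0

    def test_out_of_range_rejected(self):
        x = ct.centre_input()
        x[4] = math.log(1.0) + math.log(1.01)  # k2c 1% above its upper bound
        with pytest.raises(InputRangeError, match="k2c"):
            expand_inputs(x)

    def test_k2c_zero_variant_has_no_k2c_input(self):
        x22 = np.delete(ct.centre_input(), INPUT_NAMES.index("k2c"))
        params = expand_inputs(x22, variant="k2c_zero")
        assert params["k2c"] == 0.0


class TestRHS:
    def test_auxin_receptor_stationarity(self):
        # whenever -[Auxin][Ra] + (k5/k4)[Ra*] = 0 the Ra derivative vanishes,
        # for any overall receptor rate scale k4
        params = expand_inputs(ct.centre_input())
        params["k6"] = 0.3
        for k4 in (1.0, 7.3):
            p = dict(params)
            ratio = p["k5"]  # k5/k4 with k4 = 1
            p["k4"] = k4
            p["k5"] = ratio * k4
            y = dict(zip(STATE_NAMES, [0.5] * 15))
            y["Auxin"], y["Ra*"] = 2.0, 1.0
            y["Ra"] = ratio * y["Ra*"] / y["Auxin"]
            dy = rhs([y[n] for n in STATE_NAMES], p)
            assert dy[STATE_NAMES.index("Ra")] == pytest.approx(0.0, abs=1e-12)

    def test_plsm_production_limits(self):
        params = expand_inputs(ct.centre_input())
        params["k6"] = 0.3
        base = dict(zip(STATE_NAMES, [0.1] * 15))
        base["Ra*"] = 0.7
        # ET -> infinity kills PLSm production (k7 decay term remains)
        y = dict(base)
        y["ET"] = 1e12
        dy = rhs([y[n] for n in STATE_NAMES], params)
        assert dy[STATE_NAMES.index("PLSm")] == pytest.approx(
            -params["k7"] * y["PLSm"], rel=1e-6
        )
        # k6a -> infinity removes the ethylene inhibition entirely
        p2 = dict(params)
        p2["k6a"] = 1e15
        y = dict(base)
        dy = rhs([y[n] for n in STATE_NAMES], p2)
        assert dy[STATE_NAMES.index("PLSm")] == pytest.approx(
            params["k6"] * y["Ra*"] - params["k7"] * y["PLSm"], rel=1e-9
        )

    @pytest.mark.parametrize("variant", ["full", "k2c_zero"])
    def test_receptor_pools_conserved_pointwise(self, variant):
        # paired production/consumption terms cancel: the three receptor-pool
        # sums have identically zero time derivative at random states
        rng = np.random.default_rng(3)
        params = expand_inputs(ct.centre_input())
        params["k6"] = 0.3
        for _ in range(10):
            y = rng.uniform(0.01, 2.0, 15)
            dy = rhs(y, params, variant=variant)
            for a, b in (("Ra", "Ra*"), ("Re", "Re*"), ("CTR1", "CTR1*")):
                s = dy[STATE_NAMES.index(a)] + dy[STATE_NAMES.index(b)]
                assert s == pytest.approx(0.0, abs=1e-12)

    def test_feeding_states_constant(self):
        params = expand_inputs(ct.centre_input())
        params["k6"] = 0.3
        dy = rhs(np.full(15, 0.5), params)
        for name in ("IAA", "cytokinin", "ACC"):
            assert dy[STATE_NAMES.index(name)] == 0.0

    def test_k2c_zero_differs_at_plsp_boundary(self):
        # with PLSp = 0 the full model's auxin biosynthesis term vanishes but
        # the reduced model keeps it: the models differ at the boundary
        params = expand_inputs(ct.centre_input())
        params["k6"] = 0.3
        y = dict(zip(STATE_NAMES, [0.2] * 15))
        y["PLSp"] = 0.0
        yv = [y[n] for n in STATE_NAMES]
        d_full = rhs(yv, params)[STATE_NAMES.index("Auxin")]
        d_var = rhs(yv, params, variant="k2c_zero")[STATE_NAMES.index("Auxin")]
        assert d_var > d_full

    def test_k2c_to_zero_limit_with_positive_plsp(self):
        # with PLSp > 0 held fixed the full-model term converges to the
        # variant term as k2c -> 0
        params = expand_inputs(ct.centre_input())
        params["k6"] = 0.3
        y = np.full(15, 0.3)
        d_var = rhs(y, params, variant="k2c_zero")[0]
        for k2c in (1e-3, 1e-6, 1e-9):
            p = dict(params)
            p["k2c"] = k2c
            d_full = rhs(y, p)[0]
            assert abs(d_full - d_var) < 5 * k2c
        assert abs(rhs(y, dict(params, k2c=1e-9))[0] - d_var) < 1e-8


class TestEquilibrium:
    def test_equilibrium_residual_and_conservation(self):
        params = expand_inputs(ct.centre_input())
        eq = solve_equilibrium(params, Scenario("wt"))
        dy = rhs(eq, dict(params, k6=0.3))
        assert np.max(np.abs(dy) / np.maximum(np.abs(eq), 1.0)) <= 1e-8
        # conserved sums keep their initial values 1, 0.3, 0.3
        idx = {n: STATE_NAMES.index(n) for n in STATE_NAMES}
        assert eq[idx["Ra"]] + eq[idx["Ra*"]] == pytest.approx(1.0, rel=1e-6)
        assert eq[idx["Re"]] + eq[idx["Re*"]] == pytest.approx(0.3, rel=1e-6)
        assert eq[idx["CTR1"]] + eq[idx["CTR1*"]] == pytest.approx(0.3, rel=1e-6)
        assert np.all(eq >= -1e-9)

    def test_mutant_loses_auxin(self):
        # Table-style trend: auxin is lower in the pls mutant than wildtype
        params = expand_inputs(ct.centre_input())
        wt = solve_equilibrium(params, Scenario("wt"))
        mu = solve_equilibrium(params, Scenario("mu"))
        i = STATE_NAMES.index("Auxin")
        assert mu[i] < wt[i]
        # and the mutant makes no PLS transcript at all
        assert mu[STATE_NAMES.index("PLSm")] == pytest.approx(0.0, abs=1e-8)

    def test_feeding_initial_conditions(self):
        y0 = initial_state(SCENARIO_TABLE["fe"])
        assert y0[STATE_NAMES.index("ACC")] == 1.0
        assert y0[STATE_NAMES.index("IAA")] == 0.0
        y0 = initial_state(SCENARIO_TABLE["wt"])
        assert y0[STATE_NAMES.index("ACC")] == 0.0

    def test_determinism(self):
        params = expand_inputs(random_input(np.random.default_rng(5)))
        a = solve_equilibrium(params, Scenario("wt"))
        b = solve_equilibrium(params, Scenario("wt"))
        assert np.array_equal(a, b)


class TestTrendOutputs:
    def test_output_vector_layout(self):
        assert len(OUTPUT_NAMES) == 18
        assert OUTPUT_NAMES[:2] == ("Auxin_wt", "CK_wt")
        assert OUTPUT_NAMES[6] == "Auxin_mufe"  # 7th output, after 2 absolutes

    def test_self_ratio_is_zero(self):
        # identical scenarios give identical equilibria, so a log-ratio of a
        # scenario against itself vanishes
        params = expand_inputs(ct.centre_input())
        a = solve_equilibrium(params, Scenario("wt"))
        b = solve_equilibrium(params, Scenario("wt"))
        i = STATE_NAMES.index("Auxin")
        assert math.log(a[i] / b[i]) == 0.0

    def test_finite_outputs_at_random_inputs(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = trend_outputs(random_input(np.random.default_rng(11)))
        assert list(s.index) == list(OUTPUT_NAMES)
        assert np.all(np.isfinite(s.to_numpy()))

    def test_simulator_returns_nan_rows_on_failure(self):
        sim = ct.make_simulator("full", SolverOptions(t_end=1e-3, t_extend=2e-3))
        out = sim(ct.centre_input()[None, :])
        assert out.shape == (1, 18)
        assert out.isna().all(axis=None)

    def test_observation_table_is_complete(self):
        obs = ct.arabidopsis_observations()
        assert set(obs) == set(OUTPUT_NAMES)
        assert obs["Auxin_mu"].z == -1.24
        assert obs["ET_mu"].sigma == pytest.approx(0.061)
        assert obs["Auxin_wt"].z == pytest.approx(math.log(0.24))


class TestScalingSymmetry:
    def test_equilibrium_invariant_under_denominator_rescaling(self):
        # multiplying an eliminated denominator and its numerators by a
        # common factor leaves every equilibrium output unchanged: the formal
        # justification of the 31 -> 23 reduction
        rng = np.random.default_rng(21)
        x = random_input(rng)
        params = expand_inputs(x)
        scaled = dict(params)
        for den, nums in {
            "k4": ["k5"],
            "k12": ["k12a", "k13", "k1veth"],
        }.items():
            c = rng.uniform(2.0, 5.0)
            scaled[den] = scaled[den] * c
            for num in nums:
                scaled[num] = scaled[num] * c
        for label in ("wt", "fe"):
            a = solve_equilibrium(params, SCENARIO_TABLE[label])
            b = solve_equilibrium(scaled, SCENARIO_TABLE[label])
            assert np.allclose(a, b, rtol=1e-5, atol=1e-9)
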