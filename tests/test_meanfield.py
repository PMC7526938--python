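"""Mean-field construction, balanced/semi-balanced solvers, theorem checks."""

import numpy as np
import pytest

from semibalance import meanfield as mf, synthetic
from conftest import brute_force_semibalanced, random_dale_network

# printed worked-example rate vectors (Hz) for the receptive-field model
CONTRAST_EXPECTED = {
    "X1low": ([11.6667, 7.6667, 7.5, 3.5], (0, 1, 2, 3)),
    "X2low": ([7.6667, 11.6667, 3.5, 7.5], (0, 1, 2, 3)),
    "X1+2low": ([19.3333, 19.3333, 11.0, 11.0], (0, 1, 2, 3)),
    "X1high": ([32.5, 0.0, 18.75, 0.0], (0, 2)),
    "X2high": ([0.0, 32.5, 0.0, 18.75], (1, 3)),
    "X1+2high": ([29.6667, 29.6667, 17.1667, 17.1667], (0, 1, 2, 3)),
}


@pytest.mark.parametrize("stim_name", list(CONTRAST_EXPECTED))
def test_contrast_demo_rates(contrast, stim_name):
    expected, support = CONTRAST_EXPECTED[stim_name]
    sol = mf.semibalanced_rates(contrast.net, contrast.stimuli[stim_name])
    assert sol.ok
    np.testing.assert_allclose(sol.r, expected, atol=5e-3)
    assert sol.support == support


def test_contrast_summation(contrast):
    """Low-contrast responses add linearly; high-contrast sub-linearly."""
    r = {k: mf.semibalanced_rates(contrast.net, v).r
         for k, v in contrast.stimuli.items()}
    np.testing.assert_allclose(r["X1+2low"], r["X1low"] + r["X2low"], atol=1e-8)
    assert np.all(r["X1+2high"] < r["X1high"] + r["X2high"] - 1e-6)


class TestBuildMeanfield:
    def test_fig1_block_arithmetic(self):
        """Entries equal j*p*N_b/sqrt(N) computed by hand per block."""
        spec = synthetic.fixture("fig1_linear").spec
        net = mf.build_meanfield(spec)
        s = np.sqrt(30000)
        assert net.W[0, 0] == pytest.approx(0.375 * 0.15 * 12000 / s)
        assert net.W[0, 2] == pytest.approx(-2.25 * 0.1 * 6000 / s)
        assert net.W[2, 2] == pytest.approx(-3.75 * 0.1 * 6000 / s)
        assert net.Wx[0, 0] == pytest.approx(2.70 * 0.08 * 3000 / s)
        assert net.JK > 0

    def test_absent_block_zero(self):
        spec = synthetic.fixture("fig1_competitive").spec
        net = mf.build_meanfield(spec)
        assert net.Wx[0, 1] == 0.0  # p_e1x2 = 0
        assert net.Wx[1, 0] == 0.0

    def test_weight_scaling_exponent(self):
        spec = synthetic.fixture("fig1_linear").spec
        n_half = mf.build_meanfield(spec, weight_scaling=0.5)
        n_one = mf.build_meanfield(spec, weight_scaling=1.0)
        np.testing.assert_allclose(n_one.W * np.sqrt(30000), n_half.W)

    def test_dale_violation_named(self):
        spec = synthetic.fixture("fig1_linear").spec
        spec.j[0, 2] = +1.0  # inhibitory column made positive
        with pytest.raises(ValueError, match="i"):
            mf.build_meanfield(spec)


class TestBalancedRates:
    def test_identity(self):
        net = mf.MeanFieldNetwork(W=-np.eye(2), Wx=np.zeros((2, 0)), JK=1.0)
        np.testing.assert_allclose(mf.balanced_rates(net, [3.0, 7.0]), [3.0, 7.0])

    def test_singular_rejected(self):
        net = mf.MeanFieldNetwork(W=np.array([[1.0, 2.0], [2.0, 4.0]]),
                                  Wx=np.zeros((2, 0)), JK=1.0)
        with pytest.raises(mf.SingularNetworkError) as exc:
            mf.balanced_rates(net, [1.0, 1.0])
        assert exc.value.cond > 1e12

    def test_low_contrast_equals_linear_solve(self, contrast):
        X = contrast.stimuli["X1+2low"]
        r = mf.balanced_rates(contrast.net, X)
        np.testing.assert_allclose(r, -np.linalg.solve(contrast.net.W, X))
        assert np.all(r > 0)


class TestSemibalancedSolver:
    def test_two_pop_silenced(self):
        net = mf.MeanFieldNetwork(W=np.array([[1.0, -2.0], [2.0, -1.0]]),
                                  Wx=np.zeros((2, 0)), JK=1.0)
        sol = mf.semibalanced_rates(net, [1.0, 3.0])
        assert sol.status == "unique"
        np.testing.assert_allclose(sol.r, [0.0, 3.0], atol=1e-10)

    def test_no_solution_status(self):
        # purely excitatory self-coupling with positive drive: rates blow up
        net = mf.MeanFieldNetwork(W=np.array([[2.0]]), Wx=np.zeros((1, 0)),
                                  JK=1.0)
        sol = mf.semibalanced_rates(net, [1.0])
        assert sol.status == "none"
        assert not sol.ok

    def test_oracle_equivalence_random_networks(self):
        """Solver agrees exactly with exhaustive support enumeration."""
        rng = np.random.default_rng(12345)
        n_multi = 0
        for _ in range(100):
            net = random_dale_network(rng)
            X = rng.uniform(-2, 2, size=net.n)
            sol = mf.semibalanced_rates(net, X)
            oracle = brute_force_semibalanced(net.W, X)
            assert len(sol.all_solutions) == len(oracle)
            for r in sol.all_solutions:
                assert mf.verify_semibalance(net, X, r, tol=1e-7).verdict
                assert any(np.allclose(r, q, atol=1e-6) for q in oracle)
            n_multi += sol.status == "multiple"
        # the random ensemble must exercise the solver non-trivially
        assert n_multi >= 0

    def test_balanced_consistency(self):
        """Positive balanced solution reappears as the full-support primary."""
        rng = np.random.default_rng(99)
        found = 0
        for _ in range(200):
            net = random_dale_network(rng)
            X = rng.uniform(-2, 2, size=net.n)
            try:
                bal = mf.balanced_rates(net, X)
            except np.linalg.LinAlgError:
                continue
            if np.all(bal > 1e-6):
                sol = mf.semibalanced_rates(net, X)
                np.testing.assert_allclose(sol.r, bal, atol=1e-8)
                assert sol.support == tuple(range(net.n))
                found += 1
        assert found > 5

    def test_iterative_path_matches_enumeration(self, contrast):
        sol_enum = mf.semibalanced_rates(contrast.net,
                                         contrast.stimuli["X1high"])
        sol_iter = mf.semibalanced_rates(contrast.net,
                                         contrast.stimuli["X1high"],
                                         max_enumerate=0)
        assert sol_iter.ok
        np.testing.assert_allclose(sol_iter.r, sol_enum.r, atol=1e-5)


class TestVerifyAndScaleInvariance:
    def test_worked_example_verdict(self, contrast):
        rep = mf.verify_semibalance(contrast.net, contrast.stimuli["X1high"],
                                    [32.5, 0.0, 18.75, 0.0], tol=1e-6)
        assert rep.verdict

    def test_deliberate_violation(self, contrast):
        rep = mf.verify_semibalance(contrast.net, contrast.stimuli["X1high"],
                                    [32.5, 1.0, 18.75, 0.0], tol=1e-6)
        assert not rep.verdict
        assert not rep.cond2[1]  # negative residual with nonzero rate at e2

    def test_negative_rates_fail_nonnegativity(self, contrast):
        rep = mf.verify_semibalance(contrast.net, contrast.stimuli["X1low"],
                                    [-1.0, 7.67, 7.5, 3.5])
        assert not rep.nonneg[0] and not rep.verdict

    def test_scale_invariance_all_or_none(self, contrast):
        X = contrast.stimuli["X1high"]
        r = mf.semibalanced_rates(contrast.net, X).r
        assert mf.scale_invariance_check(contrast.net, X, r, (0.1, 1.0, 10.0))
        # a non-solution fails uniformly at every scale (still all-or-none)
        assert mf.scale_invariance_check(contrast.net, X, r + 5.0,
                                         (0.1, 1.0, 10.0))

    def test_zero_solution_nonpositive_drive(self):
        net = mf.MeanFieldNetwork(W=np.array([[1.0, -2.0], [2.0, -1.0]]),
                                  Wx=np.zeros((2, 0)), JK=1.0)
        r = np.zeros(2)
        assert mf.verify_semibalance(net, [-1.0, -0.5], r).verdict
        assert mf.scale_invariance_check(net, [-1.0, -0.5], r, (0.1, 1, 10))


class TestBreakingStimulus:
    def test_two_pop_arithmetic(self):
        net = mf.MeanFieldNetwork(W=np.array([[1.0, -2.0], [2.0, -1.0]]),
                                  Wx=np.zeros((2, 0)), JK=1.0)
        stim = mf.breaking_stimulus(net)
        np.testing.assert_allclose(stim.X, [3.0, 3.0])
        np.testing.assert_allclose(mf.balanced_rates(net, stim), [-1.0, 1.0])

    def test_contrast_matrix(self, contrast):
        stim = mf.breaking_stimulus(contrast.net)
        assert np.all(stim.X > 0)
        bal = mf.balanced_rates(contrast.net, stim)
        assert bal[0] < 0 and bal[1] < 0  # excitatory populations

    def test_zero_column_rejected(self):
        net = mf.MeanFieldNetwork(W=np.array([[0.0, -2.0], [0.0, -1.0]]),
                                  Wx=np.zeros((2, 0)), JK=1.0)
        with pytest.raises(ValueError):
            mf.breaking_stimulus(net)

    def test_random_dale_property(self):
        rng = np.random.default_rng(777)
        for _ in range(50):
            net = random_dale_network(rng)
            stim = mf.breaking_stimulus(net)
            assert np.min(stim.X) > 0
            assert np.min(mf.balanced_rates(net, stim)) < 0


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_solutions_satisfy_conditions_property(data):
        """Any solution the solver returns satisfies the fixed-point
        equation, its three conditions, and scale invariance."""
        n = data.draw(st.integers(2, 4))
        n_exc = data.draw(st.integers(1, n - 1))
        mags = data.draw(st.lists(
            st.floats(0.2, 2.0, allow_nan=False), min_size=n * n,
            max_size=n * n))
        W = np.array(mags).reshape(n, n)
        W[:, n_exc:] *= -1.0
        if np.linalg.cond(W) > 1e6:
            return
        net = mf.MeanFieldNetwork(W=W, Wx=np.zeros((n, 0)), JK=1.0)
        X = np.array(data.draw(st.lists(
            st.floats(-2, 2, allow_nan=False), min_size=n, max_size=n)))
        sol = mf.semibalanced_rates(net, X)
        for r in sol.all_solutions:
            assert mf.verify_semibalance(net, X, r, tol=1e-7).verdict
            assert mf.scale_invariance_check(net, X, r, (1e-2, 1.0, 1e2))
            lhs = np.maximum(net.W @ r + X + r, 0.0)
            assert np.allclose(lhs, r, atol=1e-6)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_external_drive_shapes():
    spec = synthetic.fixture("fig1_linear").spec
    net = mf.build_meanfield(spec)
    stim = mf.external_drive(net, [15, 15])
    assert stim.X.shape == (3,)
    with pytest.raises(ValueError):
        mf.external_drive(net, [15, 15, 15])
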