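"""Operator algebra, realization, reduction and prediction primitives."""

import numpy as np
import pytest

from warfadapt import model_core as mc


def brute_convolution(h, u):
    N = len(u)
    return np.array([sum(h[k] * u[t - k] for k in range(min(t + 1, len(h))))
                     for t in range(N)])


class TestToeplitz:
    def test_definition(self):
        T = mc.toeplitz_of([1, 2, 3], 3)
        assert np.array_equal(T, [[1, 0, 0], [2, 1, 0], [3, 2, 1]])

    def test_first_column_is_impulse_response(self):
        h = np.array([0.4, -0.2, 0.1, 0.05])
        e1 = np.eye(4)[0]
        assert np.allclose(mc.toeplitz_of(h, 4) @ e1, h)

    def test_matches_convolution(self):
        assert np.allclose(mc.toeplitz_of([0.09, 0.085], 2) @ [1, 1],
                           [0.09, 0.175])

    @pytest.mark.parametrize("seed", range(5))
    def test_random_convolution_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        h = rng.normal(size=n)
        u = rng.normal(size=n)
        assert np.allclose(mc.toeplitz_of(h, n) @ u, brute_convolution(h, u))

    def test_convolution_commutes(self):
        rng = np.random.default_rng(7)
        g, u = rng.normal(size=6), rng.normal(size=6)
        assert np.allclose(mc.toeplitz_of(g, 6) @ u, mc.toeplitz_of(u, 6) @ g)

    def test_rejects_bad_length(self):
        with pytest.raises(ValueError):
            mc.toeplitz_of([1.0], 0)


class TestHankel:
    def test_single_past_impulse(self):
        G = mc.hankel_of([1, 0.5, 0.25], 3, 1)
        assert np.allclose(G @ [1.0], [0.5, 0.25, 0.0])

    def test_zero_coefficients_zero_operator(self):
        assert not mc.hankel_of(np.zeros(5), 4, 2).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_double_sum_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        h = rng.normal(size=9)
        u_past = rng.normal(size=4)
        G = mc.hankel_of(h, 4, 4)
        expected = np.array([
            sum(h[i + j + 1] * u_past[j] if i + j + 1 < len(h) else 0.0
                for j in range(4))
            for i in range(4)
        ])
        assert np.allclose(G @ u_past, expected)


class TestImpulseResponse:
    def test_patient7_head_by_long_division(self, patient7_model):
        # polynomial long division of the printed coefficients:
        # h0 = 0.09, h1 = 0.13 - 0.50*0.09 = 0.085
        h = mc.impulse_response(patient7_model, 2)
        assert np.allclose(h, [0.09, 0.085])

    def test_pure_delay(self):
        tf = mc.TransferFunctionModel(num=[1.0], den=[1.0, 0.0])
        assert np.allclose(mc.impulse_response(tf, 4), [0, 1, 0, 0])

    def test_state_space_agrees_with_tf(self, patient7_adaptive_first):
        from scipy.signal import tf2ss

        A, B, C, D = tf2ss(patient7_adaptive_first.num,
                           patient7_adaptive_first.den)
        ss = mc.StateSpaceModel(A=A, B=B, C=C, D=D)
        assert np.allclose(mc.impulse_response(ss, 10),
                           mc.impulse_response(patient7_adaptive_first, 10))


class TestSimulate:
    def test_zero_input_zero_output(self, patient7_model):
        assert not mc.simulate(patient7_model, np.zeros(6)).any()

    def test_superposition(self, patient7_model):
        rng = np.random.default_rng(0)
        u1, u2 = rng.normal(size=8), rng.normal(size=8)
        y = mc.simulate(patient7_model, u1 + u2)
        assert np.allclose(y, mc.simulate(patient7_model, u1)
                           + mc.simulate(patient7_model, u2))

    def test_patient7_unit_step_head(self, patient7_model):
        assert np.allclose(mc.simulate(patient7_model, np.ones(2)),
                           [0.09, 0.175])

    def test_free_response_added(self, patient7_model):
        u = np.ones(5)
        w = np.arange(5.0)
        assert np.allclose(mc.simulate(patient7_model, u, w),
                           mc.simulate(patient7_model, u) + w)

    def test_length_mismatch(self, patient7_model):
        with pytest.raises(ValueError):
            mc.simulate(patient7_model, np.ones(4), np.ones(3))


class TestRealize:
    def test_geometric_tail_is_order_one(self):
        ss = mc.realize_ss([0, 1, 0.5, 0.25, 0.125])
        assert ss.order == 1
        assert np.allclose(ss.A, [[0.5]])
        assert np.isclose((ss.C @ ss.B).item(), 1.0)
        assert np.isclose(ss.D.item(), 0.0)

    def test_pure_gain(self):
        ss = mc.realize_ss([3.0, 0.0, 0.0, 0.0])
        assert ss.order == 0
        assert np.isclose(ss.D.item(), 3.0)

    @pytest.mark.parametrize("order", [1, 2, 3, 4, 5])
    def test_round_trip_identity(self, order):
        rng = np.random.default_rng(order)
        poles = rng.uniform(-0.85, 0.85, order)
        tf = mc.TransferFunctionModel(num=rng.normal(size=order + 1),
                                      den=np.poly(poles))
        g = mc.impulse_response(tf, 2 * order + 3)
        ss = mc.realize_ss(g)
        assert ss.order <= order
        assert np.allclose(mc.impulse_response(ss, len(g)), g, atol=1e-7)

    def test_fir_realization_exact_and_nilpotent(self):
        g = np.array([0.2, -0.4, 0.3, 0.1])
        ss = mc.fir_realization(g)
        assert ss.order == 3
        assert np.allclose(mc.impulse_response(ss, 6),
                           np.concatenate([g, [0, 0]]))
        assert np.max(np.abs(ss.poles())) < 1e-12


class TestReduceOrder:
    def test_noop_keeps_transfer_function(self):
        rng = np.random.default_rng(1)
        tf = mc.TransferFunctionModel(num=rng.normal(size=4),
                                      den=np.poly(rng.uniform(-0.7, 0.7, 3)))
        ss = mc.realize_ss(mc.impulse_response(tf, 11))
        red = mc.reduce_order(ss, ss.order)
        assert np.allclose(mc.impulse_response(red, 11),
                           mc.impulse_response(ss, 11))

    def test_dominant_mode_kept(self):
        big = mc.StateSpaceModel(A=[[0.9]], B=[[1.0]], C=[[5.0]], D=[[0.0]])
        small = mc.StateSpaceModel(A=[[0.3]], B=[[1.0]], C=[[0.01]], D=[[0.0]])
        red = mc.reduce_order(mc.parallel(big, small), 1)
        assert red.order == 1
        assert np.isclose(np.abs(red.poles())[0], 0.9, atol=0.01)

    def test_integrator_retained_over_fast_mode(self):
        integ = mc.StateSpaceModel(A=[[1.0]], B=[[1.0]], C=[[1.0]], D=[[0.0]])
        fast = mc.StateSpaceModel(A=[[0.2]], B=[[1.0]], C=[[0.5]], D=[[0.0]])
        red = mc.reduce_order(mc.parallel(integ, fast), 1)
        assert np.isclose(np.abs(red.poles())[0], 1.0)

    def test_error_when_marginal_modes_exceed_budget(self):
        twoint = mc.parallel(
            mc.StateSpaceModel(A=[[1.0]], B=[[1.0]], C=[[1.0]], D=[[0.0]]),
            mc.StateSpaceModel(A=[[-1.0]], B=[[1.0]], C=[[1.0]], D=[[0.0]]))
        with pytest.raises(ValueError, match="marginal"):
            mc.reduce_order(twoint, 1)

    def test_never_increases_marginal_count(self):
        rng = np.random.default_rng(3)
        tf = mc.TransferFunctionModel(num=rng.normal(size=5),
                                      den=np.poly(rng.uniform(-0.8, 0.8, 4)))
        ss = mc.realize_ss(mc.impulse_response(tf, 13))
        for O in (1, 2, 3):
            red = mc.reduce_order(ss, O)
            n_marg = np.sum(np.abs(red.poles()) >= 1 - mc.POLE_TOL)
            assert n_marg == 0
            assert red.order <= O


class TestStabilityMargin:
    def test_patient7_denominator_root_at_minus_one(self, patient7_model):
        # 1 - 0.50 - 0.09 + 0.45 - 0.86 = 0 exactly: marginal root z = -1
        assert np.isclose(np.polyval(patient7_model.den, -1.0), 0.0)
        sm = mc.stability_margin(patient7_model)
        assert sm.margin >= 1.0 - 1e-9
        assert sm.marginal

    def test_scalar_mode(self):
        ss = mc.StateSpaceModel(A=[[0.5]], B=[[1.0]], C=[[1.0]], D=[[0.0]])
        sm = mc.stability_margin(ss)
        assert np.isclose(sm.margin, 0.5) and not sm.marginal

    def test_adaptive_branch_root_oracle(self, patient7_adaptive_first):
        roots = np.roots([1.0, -1.48, 0.5, -0.008])
        sm = mc.stability_margin(patient7_adaptive_first)
        assert np.isclose(sm.margin, np.max(np.abs(roots)))


class TestOneStepPredict:
    def test_pure_gain(self):
        tf = mc.TransferFunctionModel(num=[2.0], den=[1.0])
        pred = mc.one_step_predict(tf, [1.5, 1.8], [3.0, 4.0, 5.0],
                                   inr_baseline=1.0)
        assert np.isclose(pred, 2.0 * 5.0 + 1.0)

    def test_exact_data_zero_error(self, patient7_adaptive_first):
        rng = np.random.default_rng(2)
        u = rng.uniform(0, 10, 12)
        y = mc.simulate(patient7_adaptive_first, u) + 1.0
        pred = mc.one_step_predict(patient7_adaptive_first, y[:11], u[:12])
        assert np.isclose(pred, y[11], atol=1e-10)

    def test_matches_difference_equation_recursion(self, patient7_model):
        rng = np.random.default_rng(4)
        u = rng.uniform(0, 10, 10)
        y = mc.simulate(patient7_model, u) + 1.0
        num, den = patient7_model.num, patient7_model.den
        na = len(den) - 1
        b = np.zeros(na + 1)
        b[na + 1 - len(num):] = num
        for t1 in range(na, 10):
            expect = sum(-den[i] * (y[t1 - i] - 1.0) for i in range(1, na + 1))
            expect += sum(b[j] * u[t1 - j] for j in range(na + 1) if t1 >= j)
            got = mc.one_step_predict(patient7_model, y[:t1], u[: t1 + 1])
            assert np.isclose(got, expect + 1.0)

    def test_insufficient_history(self, patient7_model):
        with pytest.raises(ValueError):
            mc.one_step_predict(patient7_model, [1.0], [5.0, 5.0])


class TestSeriesValidation:
    def test_rejects_gap_in_days(self):
        with pytest.raises(ValueError):
            mc.DoseResponseSeries("x", [0, 1, 3], [1, 1, 1], [2, 2, 2])

    def test_rejects_negative_dose(self):
        with pytest.raises(ValueError):
            mc.DoseResponseSeries("x", [0, 1], [1, -1], [2, 2])

    def test_deviation_removes_baseline(self):
        s = mc.DoseResponseSeries("x", [0, 1], [5, 5], [2.5, 3.0],
                                  inr_baseline=1.0)
        assert np.allclose(s.deviation, [1.5, 2.0])


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=12),
           st.lists(st.floats(-5, 5), min_size=2, max_size=12))
    def test_toeplitz_convolution_property(h, u):
        """Applying the lower-triangular Toeplitz operator of h to u equals
        causal convolution, for arbitrary finite coefficient lists."""
        n = min(len(h), len(u))
        h, u = np.asarray(h[:n]), np.asarray(u[:n])
        direct = [sum(h[k] * u[t - k] for k in range(t + 1)) for t in range(n)]
        assert np.allclose(mc.toeplitz_of(h, n) @ u, direct, atol=1e-9)
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass
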