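"""Semi-blind robust identification: program assembly and recovery."""

import numpy as np
import pytest

from warfadapt import model_core as mc
from warfadapt import semiblind as sb
from tests.conftest import make_series


def spectral_norm(g, r):
    N = len(g)
    S = mc.toeplitz_of(g, N) * (r ** -np.subtract.outer(np.arange(N),
                                                        np.arange(N)))
    return np.linalg.svd(S, compute_uv=False)[0]


def lmi_matrix(g, r, K):
    """The positive-semidefinite block matrix of the gain/stability prior."""
    N = len(g)
    R = np.diag(r ** np.arange(N))
    T = mc.toeplitz_of(g, N)
    return np.block([[K * np.linalg.matrix_power(R, -2), T.T],
                     [T, K * R @ R]])


class TestAssemble:
    def test_scaling_matrix(self, default_priors, series_factory):
        pri = mc.PrioriSet(K=10, r=0.9, epsilon=0.1, gamma=0.5, K_u=1.0)
        ser = series_factory(np.ones(3), np.zeros(3))
        prog = sb.assemble(ser, pri)
        assert np.allclose(np.diag(prog.R), [1.0, 0.9, 0.81])

    def test_lmi_trivially_feasible_at_zero_g(self, default_priors):
        M = lmi_matrix(np.zeros(5), default_priors.r, default_priors.K)
        assert np.min(np.linalg.eigvalsh(M)) >= 0

    def test_window_too_short(self, default_priors, series_factory):
        ser = series_factory(np.ones(2), np.zeros(2))
        with pytest.raises(ValueError):
            sb.assemble(ser, default_priors)

    def test_residual_of_solution_equals_achieved_noise(self, default_priors):
        rng = np.random.default_rng(11)
        u = rng.uniform(0, 10, 7)
        tf = mc.TransferFunctionModel(num=[0.0, 0.3], den=[1.0, -0.6])
        y = mc.simulate(tf, u) + rng.uniform(-0.1, 0.1, 7)
        ser = make_series(u, y)
        res = sb.identify(ser, default_priors)
        prog = sb.assemble(ser, default_priors)
        recomputed = np.max(np.abs(prog.residual(res.model.g, res.model.p,
                                                 res.model.w_hat)))
        assert np.isclose(recomputed, res.achieved_noise, atol=1e-9)


class TestIdentify:
    def test_noiseless_recovery_of_delayed_gain(self, tight_priors):
        rng = np.random.default_rng(3)
        u = rng.uniform(0, 10, 7)
        tf = mc.TransferFunctionModel(num=[0.5], den=[1.0, 0.0])
        ser = make_series(u, mc.simulate(tf, u))
        res = sb.identify(ser, tight_priors)
        assert res.achieved_noise <= 1e-6
        expected = np.zeros(7)
        expected[1] = 0.5
        assert np.allclose(res.model.g, expected, atol=1e-6)
        assert abs(res.model.p) < 1e-6

    def test_all_zero_data_gives_zero_model(self, default_priors):
        ser = make_series(np.zeros(7), np.zeros(7))
        res = sb.identify(ser, default_priors)
        assert res.achieved_noise == 0.0
        assert not res.model.g.any()
        assert res.model.p == 0.0

    def test_gain_prior_binds_and_raises_residual(self, tight_priors):
        rng = np.random.default_rng(3)
        u = rng.uniform(0, 10, 7)
        tf = mc.TransferFunctionModel(num=[0.0, 2.0], den=[1.0, -0.5])
        ser = make_series(u, mc.simulate(tf, u))
        loose = sb.identify(ser, tight_priors)
        tightK = mc.PrioriSet(K=2.0, r=0.95, epsilon=1e-8, gamma=1e-6, K_u=1.0)
        constrained = sb.identify(ser, tightK)
        assert loose.achieved_noise < 1e-6
        assert constrained.achieved_noise > loose.achieved_noise + 1e-3
        # the solution satisfies its own LMI: spectral norm within K
        assert spectral_norm(constrained.model.g, 0.95) <= 2.0 + 1e-6
        M = lmi_matrix(constrained.model.g, 0.95, 2.0)
        assert np.min(np.linalg.eigvalsh(M)) >= -1e-6

    def test_achieved_noise_monotone_in_priors(self):
        rng = np.random.default_rng(9)
        u = rng.uniform(0, 10, 7)
        tf = mc.TransferFunctionModel(num=[0.0, 0.8], den=[1.0, -0.7])
        y = mc.simulate(tf, u) + np.linspace(0.5, 0.1, 7)  # offset to absorb
        ser = make_series(u, y)
        noises_K = [sb.identify(ser, mc.PrioriSet(K=k, r=0.95, epsilon=1e-8,
                                                  gamma=1e-6, K_u=1.0)
                                ).achieved_noise
                    for k in (0.2, 0.5, 1.0, 2.0)]
        assert all(a >= b - 1e-7 for a, b in zip(noises_K, noises_K[1:]))
        noises_g = [sb.identify(ser, mc.PrioriSet(K=10, r=0.95, epsilon=1e-8,
                                                  gamma=g, K_u=1.0)
                                ).achieved_noise
                    for g in (1e-6, 0.1, 0.3, 1.0)]
        assert all(a >= b - 1e-7 for a, b in zip(noises_g, noises_g[1:]))

    def test_feasibility_flag_follows_epsilon(self):
        rng = np.random.default_rng(13)
        u = rng.uniform(0, 10, 7)
        tf = mc.TransferFunctionModel(num=[0.0, 0.4], den=[1.0, -0.6])
        y = mc.simulate(tf, u) + rng.uniform(-0.05, 0.05, 7)
        ser = make_series(u, y)
        ok = sb.identify(ser, mc.PrioriSet(K=10, r=0.95, epsilon=0.05,
                                           gamma=1e-6, K_u=1.0))
        assert ok.feasible
        # a gain prior far below the true gain cannot fit within epsilon
        bad = sb.identify(ser, mc.PrioriSet(K=0.05, r=0.95, epsilon=0.05,
                                            gamma=1e-6, K_u=1.0))
        assert not bad.feasible
        assert bad.achieved_noise > 0.05

    def test_deterministic(self, default_priors):
        rng = np.random.default_rng(21)
        u = rng.uniform(0, 10, 7)
        y = rng.uniform(0, 2, 7)
        ser = make_series(u, y)
        r1 = sb.identify(ser, default_priors)
        r2 = sb.identify(ser, default_priors)
        assert np.array_equal(r1.model.g, r2.model.g)
        assert r1.model.p == r2.model.p


class TestBindFullModel:
    def test_impulse_is_p_plus_g_noiseless(self, tight_priors):
        rng = np.random.default_rng(5)
        u = rng.uniform(0, 10, 7)
        tf = mc.TransferFunctionModel(num=[0.0, 0.3], den=[1.0, -0.5])
        ser = make_series(u, mc.simulate(tf, u))
        res = sb.identify(ser, tight_priors)
        full = sb.bind_full_model(res)
        h = mc.impulse_response(full, 7)
        assert np.allclose(h, res.model.p + res.model.g, atol=1e-6)

    def test_impulse_matches_g_at_noise_scale(self, default_priors):
        # the realization smooths g at the certified noise scale by design
        rng = np.random.default_rng(5)
        u = rng.uniform(0, 10, 7)
        tf = mc.TransferFunctionModel(num=[0.0, 0.3], den=[1.0, -0.5])
        y = mc.simulate(tf, u) + rng.uniform(-0.05, 0.05, 7)
        ser = make_series(u, y)
        res = sb.identify(ser, default_priors)
        h = mc.impulse_response(sb.bind_full_model(res), 7)
        assert np.max(np.abs(h - (res.model.p + res.model.g))) \
            <= 2 * res.achieved_noise + 1e-6

    def test_pure_integrator_when_g_zero(self):
        integ = mc.StateSpaceModel(A=[[1.0]], B=[[1.0]], C=[[1.0]], D=[[1.0]])
        step = mc.simulate(integ, np.ones(4))
        assert np.allclose(step, [1, 2, 3, 4])

    def test_statistical_recovery_noiseless_with_initial_conditions(self):
        """Noiseless patients with genuine pre-study dosing: the program must
        absorb the decaying free response into w and keep the residual at the
        noise floor."""
        from dataclasses import replace

        from warfadapt import cohort

        cfg = cohort.CohortConfig(noise_eps=1e-12)
        pri = mc.PrioriSet(K=10, r=0.95, epsilon=1e-8, gamma=4.0, K_u=1.0)
        for seed in range(5):
            pat = replace(cohort.sample_patient(40 + seed, cfg),
                          regime_schedule=())
            ser, _ = cohort.simulate_patient(pat, 20, 140 + seed, cfg)
            res = sb.identify(ser, pri, slice(0, 7))
            assert res.achieved_noise <= 1e-6
            assert np.abs(res.model.w_hat[0]) > 0.1  # ICs really used
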