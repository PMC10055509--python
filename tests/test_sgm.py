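import numpy as np
import pytest
import scipy.integrate
import scipy.signal

import neurosgm as ns
from neurosgm.sgm import INITIAL_GUESSES, local_characteristic_roots

from conftest import random_stable_params


class TestGammaResponse:
    def test_unit_dc_gain(self):
        for tau in (0.005, 0.02, 0.2):
            assert ns.gamma_response(0.0, tau) == pytest.approx(1.0 + 0.0j)

    def test_lowpass_magnitude_is_nonincreasing(self):
        f = np.linspace(0, 35, 200)
        for tau in (0.006, 0.03, 0.1):
            mag = np.abs(ns.gamma_response(f, tau))
            assert np.all(np.diff(mag) <= 1e-15)

    def test_matches_time_domain_kernel_fft(self):
        # independent oracle: numerically Fourier-transform the sampled
        # gamma kernel h(t) = t/tau^2 * exp(-t/tau)
        tau, f = 0.01, 10.0
        dt = 1e-5
        t = np.arange(0, 1.0, dt)
        h = t / tau ** 2 * np.exp(-t / tau)
        oracle = np.sum(h * np.exp(-2j * np.pi * f * t)) * dt
        val = ns.gamma_response(f, tau)
        assert abs(val - oracle) / abs(oracle) < 1e-3

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            ns.gamma_response(1.0, 0.0)


def _local_state_space(p: ns.SGMParameters) -> scipy.signal.StateSpace:
    """Independent time-domain realization of the local E-I circuit.

    Each gamma kernel is a critically damped second-order filter; the
    states are (x_e, x_i, u_e, u_e', u_i, u_i') and the output is the total
    activity x_e + x_i driven by a common input.
    """
    te, ti = p.tau_e, p.tau_i
    A = np.array([
        [0, 0, -1 / te, 0, 0, 0],
        [0, 0, 0, 0, -1 / ti, 0],
        [0, 0, 0, 1, 0, 0],
        [p.g_ee / te ** 2, p.g_ei / te ** 2, -1 / te ** 2, -2 / te, 0, 0],
        [0, 0, 0, 0, 0, 1],
        [-p.g_ei / ti ** 2, p.g_ii / ti ** 2, 0, 0, -1 / ti ** 2, -2 / ti],
    ])
    B = np.array([[1.0], [1.0], [0], [0], [0], [0]])
    C = np.array([[1.0, 1.0, 0, 0, 0, 0]])
    return scipy.signal.StateSpace(A, B, C, [[0.0]])


class TestLocalTransfer:
    def test_finite_nonzero_at_stable_params(self, params):
        vals = ns.local_transfer(np.arange(1.0, 36.0), params)
        assert np.all(np.isfinite(vals))
        assert np.all(np.abs(vals) > 0)

    @pytest.mark.parametrize("p", [
        ns.SGMParameters(),
        ns.SGMParameters(g_ei=0.001, g_ii=0.001),
        INITIAL_GUESSES[1],
        INITIAL_GUESSES[2],
    ], ids=["default", "gain-floor", "guess2", "guess3"])
    def test_matches_state_space_frequency_response(self, p):
        # the state-space realization is an independent derivation path
        f = np.array([1.0, 4.0, 10.0, 25.0, 35.0])
        _, H = scipy.signal.freqresp(_local_state_space(p), 2 * np.pi * f)
        mine = ns.local_transfer(f, p)
        assert np.allclose(mine, H, rtol=1e-6)


class TestComplexLaplacian:
    def test_no_connections_gives_identity(self):
        g = ns.ConnectomeGraph(C=np.zeros((3, 3)), D=np.zeros((3, 3)))
        for f in (0.5, 10.0, 35.0):
            assert np.allclose(ns.complex_laplacian(f, g, 0.8, 10.0),
                               np.eye(3))

    def test_zero_frequency_limit_is_real(self, graph6):
        L = ns.complex_laplacian(0.0, graph6, 0.7, 8.0)
        expected = np.eye(6) - 0.7 * ns.degree_normalize(graph6.C)
        assert np.allclose(L, expected)
        assert np.allclose(L.imag, 0.0)

    def test_eigenvalues_match_directly_assembled_matrix(self, graph6):
        # oracle: assemble the delayed matrix element by element
        f, alpha, v = 12.0, 0.9, 7.5
        w = 2 * np.pi * f
        rowdeg = graph6.C.sum(axis=1)
        M = np.zeros((6, 6), dtype=complex)
        for i in range(6):
            for j in range(6):
                if rowdeg[i] > 0:
                    M[i, j] = (graph6.C[i, j] / rowdeg[i]
                               * np.exp(-1j * w * graph6.D[i, j] / (v * 1e3)))
        expected = np.linalg.eigvals(np.eye(6) - alpha * M)
        got = np.linalg.eigvals(ns.complex_laplacian(f, graph6, alpha, v))
        assert np.allclose(np.sort_complex(got), np.sort_complex(expected))

    def test_invalid_speed_rejected(self, graph6):
        with pytest.raises(ValueError):
            ns.complex_laplacian(1.0, graph6, 0.5, 0.0)


class TestForwardSpectrum:
    def test_eigenmode_sum_matches_resolvent_oracle(self, graph8, grid, params):
        # oracle: explicit (jwI + FG/tauG L)^{-1} H_local * P solve
        spec = ns.forward_spectrum(params, graph8, grid, method="eig")
        FG = ns.gamma_response(grid.frequencies, params.tau_G)
        Hloc = ns.local_transfer(grid.frequencies, params)
        for i, f in enumerate(grid.frequencies):
            L = ns.complex_laplacian(float(f), graph8, params.alpha,
                                     params.speed)
            A = 2j * np.pi * f * np.eye(8) + FG[i] / params.tau_G * L
            oracle = np.linalg.solve(A, Hloc[i] * np.ones(8))
            err = np.max(np.abs(spec.response[:, i] - oracle)
                         / np.abs(oracle))
            assert err < 1e-8

    def test_single_region_scalar_closed_form(self, grid, params):
        g = ns.ConnectomeGraph(C=np.zeros((1, 1)), D=np.zeros((1, 1)))
        spec = ns.forward_spectrum(params, g, grid)
        f = grid.frequencies
        lam = 1.0  # L = I for an isolated region
        X = (ns.local_transfer(f, params)
             / (2j * np.pi * f
                + lam * ns.gamma_response(f, params.tau_G) / params.tau_G))
        assert np.allclose(spec.response[0], X, rtol=1e-12)

    def test_doubling_drive_adds_six_db(self, graph6, grid, params):
        base = ns.forward_spectrum(params, graph6, grid)
        doubled = ns.forward_spectrum(params, graph6, grid,
                                      drive=2.0 * np.ones(6))
        assert np.allclose(doubled.values - base.values,
                           20 * np.log10(2.0), atol=1e-9)

    def test_hlocal_hook_reduces_to_network_response(self, graph6, grid,
                                                     params):
        spec = ns.forward_spectrum(params, graph6, grid,
                                   hlocal=lambda f, p: np.ones_like(f))
        FG = ns.gamma_response(grid.frequencies, params.tau_G)
        i = 40
        f = grid.frequencies[i]
        L = ns.complex_laplacian(float(f), graph6, params.alpha, params.speed)
        A = 2j * np.pi * f * np.eye(6) + FG[i] / params.tau_G * L
        oracle = np.linalg.solve(A, np.ones(6))
        assert np.allclose(spec.response[:, i], oracle, rtol=1e-10)

    def test_permutation_invariance(self, graph8, grid, params):
        order = np.array([5, 2, 7, 0, 3, 6, 1, 4])
        direct = ns.forward_spectrum(params, graph8.permuted(order), grid)
        permuted = ns.forward_spectrum(params, graph8, grid).values[order]
        assert np.allclose(direct.values, permuted, atol=1e-9)

    def test_truncation_refines_statistically(self, grid):
        # mean Frobenius error at K=N-1 must not exceed that at K=1
        errs = {1: [], 7: []}
        for seed in range(6):
            g = ns.synth_connectome(8, seed=seed)
            p = random_stable_params(np.random.default_rng(seed))
            full = ns.forward_spectrum(p, g, grid).response
            for K in errs:
                trunc = ns.forward_spectrum(p, g, grid, K=K,
                                            method="eig").response
                errs[K].append(np.linalg.norm(trunc - full))
        assert np.mean(errs[7]) <= np.mean(errs[1])

    def test_parameter_sensitivity_is_finite(self, graph6, grid):
        p = ns.SGMParameters(tau_G=0.015, alpha=0.6, speed=10.0)
        base = ns.forward_spectrum(p, graph6, grid).values
        for name in ns.PARAM_NAMES:
            bumped = p.replace(**{name: getattr(p, name) * 1.001})
            delta = ns.forward_spectrum(bumped, graph6, grid).values - base
            assert np.all(np.isfinite(delta))

    def test_invalid_truncation_rejected(self, graph6, grid, params):
        with pytest.raises(ValueError):
            ns.forward_spectrum(params, graph6, grid, K=0)
        with pytest.raises(ValueError):
            ns.forward_spectrum(params, graph6, grid, K=7)


class TestPsdDb:
    def test_reference_magnitudes(self):
        assert ns.psd_db(np.array([1.0]))[0] == 0.0
        assert ns.psd_db(np.array([10.0]))[0] == pytest.approx(20.0)

    def test_zero_floored_with_warning(self):
        with pytest.warns(RuntimeWarning, match="floored"):
            out = ns.psd_db(np.array([0.0, 1.0]))
        assert out[0] == -300.0


class TestStability:
    def test_mid_bound_parameters_stable_at_stage_one(self, params):
        ok, diag = ns.stability_check(params, stage=1)
        assert ok
        assert diag["max_pole_real"] < 0

    def test_gains_outside_stage_three_bounds_fail_bound_criterion(self):
        p = ns.SGMParameters(g_ei=0.6, g_ii=0.3)  # legal at stage 1 only
        ok, diag = ns.stability_check(p, stage=3)
        assert not ok
        assert "gains_in_bounds" in diag["failed"]

    @pytest.mark.parametrize("p", [
        ns.SGMParameters(),
        ns.SGMParameters(tau_i=0.005, g_ii=2.0),
        ns.SGMParameters(tau_e=0.005, tau_i=0.005, g_ei=0.7, g_ii=0.6),
        ns.SGMParameters(tau_e=0.03, tau_i=0.05, g_ei=0.7, g_ii=2.0),
    ], ids=["default", "gii-max-fast-i", "fast-high-gei", "slow-high-gains"])
    def test_verdict_matches_time_domain_boundedness(self, p):
        # oracle: integrate the state-space circuit and watch for growth
        ss = _local_state_space(p)
        x0 = np.full(6, 1e-3)
        sol = scipy.integrate.solve_ivp(
            lambda t, x: ss.A @ x, (0.0, 2.0), x0, rtol=1e-8, atol=1e-12,
        )
        growth = np.abs(sol.y[:, -1]).max() / np.abs(x0).max()
        bounded = growth < 1e3
        verdict, _ = ns.stability_check(p, stage=1)
        assert verdict == bounded

    def test_all_initial_guesses_are_stable(self):
        for guess in INITIAL_GUESSES:
            assert ns.stability_check(guess, stage=1)[0]

    def test_characteristic_roots_match_state_space_eigenvalues(self, params):
        roots = np.sort_complex(local_characteristic_roots(params))
        eigs = np.sort_complex(np.linalg.eigvals(
            _local_state_space(params).A))
        assert np.allclose(roots, eigs, rtol=1e-6)


class TestParameterContainer:
    def test_vector_round_trip(self, params):
        assert ns.SGMParameters.from_vector(params.to_vector()) == params

    def test_nonpositive_time_constant_rejected(self):
        with pytest.raises(ValueError):
            ns.SGMParameters(tau_G=0.0)

    def test_report_dict_uses_milliseconds(self):
        d = ns.SGMParameters(tau_G=0.0139).as_report_dict()
        assert d["tau_G_ms"] == pytest.approx(13.9)

    def test_stage_bounds_are_nested(self):
        for name in ("g_ei", "g_ii"):
            widths = [ns.stage_bounds(s)[name][1] for s in (1, 2, 3)]
            assert widths[0] >= widths[1] >= widths[2]
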