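"""Mild-form integrator: closed forms, Picard reference, equivalence."""

import numpy as np
import pytest

import neurofield as nf
from neurofield.config import RunConfig, GridConfig, KernelConfig, GainConfig, \
    DiffusionConfig, PhiConfig, InitialConfig


class TestNonlocalDrift:
    def test_unit_gain_gives_l1_norm(self, gauss_kernel, grid64, rng):
        Y = rng.normal(size=grid64.field_shape)
        F = nf.nonlocal_drift(Y, gauss_kernel, nf.constant_gain(1.0), grid64)
        W1 = float(np.sum(gauss_kernel.profile_on_grid(grid64)) * grid64.cell_volume)
        np.testing.assert_allclose(F, W1, rtol=1e-12)

    def test_constant_field_homogeneous(self, gauss_kernel, grid64):
        c = 1.3
        G = nf.sigmoid_gain()
        Y = np.full(grid64.field_shape, c)
        F = nf.nonlocal_drift(Y, gauss_kernel, G, grid64)
        W1 = float(np.sum(gauss_kernel.profile_on_grid(grid64)) * grid64.cell_volume)
        np.testing.assert_allclose(F, float(G(c)) * W1, rtol=1e-12)

    def test_zero_kernel(self, grid64, rng):
        Y = rng.normal(size=grid64.field_shape)
        assert np.all(nf.nonlocal_drift(Y, nf.zero_kernel(), nf.sigmoid_gain(),
                                        grid64) == 0)

    def test_fft_path_matches_dense_matrix(self, gauss_kernel, grid64, rng):
        Y = rng.normal(size=grid64.field_shape)
        G = nf.sigmoid_gain()
        fft_path = nf.nonlocal_drift(Y, gauss_kernel, G, grid64)
        W = gauss_kernel.matrix(grid64)
        dense = (W @ G(Y).ravel()) * grid64.cell_volume
        np.testing.assert_allclose(fft_path, dense, atol=1e-10)


class TestNoiseOperator:
    def test_additive_case_is_convolution(self, grid64, phi_gauss, rng):
        Y = rng.normal(size=grid64.field_shape)
        u = rng.normal(size=grid64.field_shape)
        out = nf.noise_operator_apply(Y, u, phi_gauss, nf.constant_diffusion(1.0))
        np.testing.assert_allclose(out, nf.circular_convolve(phi_gauss.values, u),
                                   atol=1e-12)

    def test_zero_input(self, grid64, phi_gauss, rng):
        Y = rng.normal(size=grid64.field_shape)
        out = nf.noise_operator_apply(Y, np.zeros_like(Y), phi_gauss,
                                      nf.linear_diffusion(0.5))
        assert np.allclose(out, 0.0)

    def test_multiplicative_case(self, grid64, phi_gauss, rng):
        lam = 0.8
        Y = rng.normal(size=grid64.field_shape)
        u = rng.normal(size=grid64.field_shape)
        out = nf.noise_operator_apply(Y, u, phi_gauss, nf.linear_diffusion(lam))
        np.testing.assert_allclose(
            out, lam * Y * nf.circular_convolve(phi_gauss.values, u), atol=1e-12)


class TestClosedForms:
    def test_pure_decay_exact(self, gauss_kernel, grid64, phi_gauss):
        Y0 = np.full(grid64.field_shape, 2.0)
        sol = nf.integrate(grid64, Y0, 60, 0.05, gauss_kernel,
                           nf.constant_gain(0.0), nf.constant_diffusion(0.0),
                           phi_gauss, seed=0)
        exact = 2.0 * np.exp(-sol.times)[:, None]
        assert np.max(np.abs(sol.values - exact)) < 1e-12

    def test_constant_drift_closed_form(self, gauss_kernel, grid64, phi_gauss):
        c, y0 = 0.7, 2.0
        W1 = float(np.sum(gauss_kernel.profile_on_grid(grid64)) * grid64.cell_volume)
        Y0 = np.full(grid64.field_shape, y0)
        sol = nf.integrate(grid64, Y0, 60, 0.05, gauss_kernel,
                           nf.constant_gain(c), nf.constant_diffusion(0.0),
                           phi_gauss, seed=0)
        exact = (np.exp(-sol.times) * y0
                 + (1 - np.exp(-sol.times)) * c * W1)[:, None]
        assert np.max(np.abs(sol.values - exact)) < 1e-12

    def test_ou_stationary_variance(self, grid64, phi_gauss, rng):
        # w = 0, sigma = 1: each node is Ornstein-Uhlenbeck with stationary
        # variance ||phi||^2 / 2 (continuum); 2000 replicate end states
        dt, n_steps, reps = 0.05, 120, 2000
        target = phi_gauss.l2_norm ** 2 / 2
        finals = np.empty((reps,) + grid64.field_shape)
        Y = np.zeros((reps,) + grid64.field_shape)
        decay = np.exp(-dt)
        for k in range(n_steps):
            dW = nf.white_noise_increments(grid64, dt, rng, n=reps)
            dWphi = nf.smoothed_increment(dW, phi_gauss)
            Y = decay * Y + decay * dWphi
        var = Y[:, ::8].var()   # subsample nodes to reduce correlation
        se = target * np.sqrt(2 / reps)
        assert abs(var - target) < 3 * se + 0.1 * target  # O(dt) scheme bias


class TestSimulate:
    def _config(self, **kw):
        base = dict(
            grid=GridConfig(half_width=10.0, points_per_axis=64),
            kernel=KernelConfig(type="exponential", beta=1.0),
            gain=GainConfig(type="sigmoid"),
            diffusion=DiffusionConfig(type="linear", value=0.5),
            phi=PhiConfig(type="gaussian", beta=1.0),
            initial=InitialConfig(type="bump", amplitude=1.0),
            time_horizon=0.5, dt=0.01, seed=3)
        base.update(kw)
        return RunConfig(**base)

    def test_zero_horizon_returns_initial(self):
        sol = nf.simulate(self._config(time_horizon=0.0))
        assert sol.values.shape[0] == 1

    def test_seed_reproducibility(self):
        s1 = nf.simulate(self._config())
        s2 = nf.simulate(self._config())
        np.testing.assert_array_equal(s1.values, s2.values)
        s3 = nf.simulate(self._config(seed=4))
        assert not np.array_equal(s1.values, s3.values)

    def test_multiplicative_noise_run_is_finite_and_bounded(self):
        # exponential kernel, sigma(a) = lambda a, sigmoid gain
        sol = nf.simulate(self._config(time_horizon=2.0))
        assert np.all(np.isfinite(sol.values))
        assert np.max(np.abs(sol.values)) < 50

    def test_inadmissible_kernel_refused(self):
        with pytest.raises(RuntimeError):
            nf.solver.ensure_admissible(nf.counterexample_kernel())


class TestPicard:
    def test_deterministic_decay_immediate_fixed_point(self, grid64, phi_gauss):
        Y0 = np.full(grid64.field_shape, 2.0)
        replay = nf.NoiseReplay(grid64, 0.05, 20, seed=1)
        sol, trace = nf.picard_solve(grid64, Y0, 20, 0.05, nf.zero_kernel(),
                                     nf.constant_gain(0.0),
                                     nf.constant_diffusion(0.0), phi_gauss,
                                     replay=replay)
        exact = 2.0 * np.exp(-sol.times)[:, None]
        assert np.max(np.abs(sol.values - exact)) == 0.0
        assert trace.iterations <= 2

    def test_supergeometric_contraction(self, gauss_kernel, grid64, phi_gauss):
        Y0 = np.ones(grid64.field_shape)
        replay = nf.NoiseReplay(grid64, 1.0 / 64, 64, seed=5)
        _, trace = nf.picard_solve(grid64, Y0, 64, 1.0 / 64, gauss_kernel,
                                   nf.sigmoid_gain(), nf.linear_diffusion(0.3),
                                   phi_gauss, replay=replay, tol=1e-14)
        H = np.asarray(trace.differences)
        # factorial-type tail: far below the geometric envelope implied by
        # the first contraction factor, and strongly contracting throughout
        envelope = H[1] * (H[1] / H[0]) ** (len(H) - 2)
        assert H[-1] < envelope / 10
        assert np.all(H[2:] / H[1:-1] < 0.2)

    def test_euler_agreement_improves_under_refinement(self, gauss_kernel,
                                                       grid64, phi_gauss):
        Y0 = np.ones(grid64.field_shape)
        fine_steps, T = 64, 1.0
        replay = nf.NoiseReplay(grid64, T / fine_steps, fine_steps, seed=5)
        fine = replay.increments_array()
        gain, diff = nf.sigmoid_gain(), nf.linear_diffusion(0.3)
        sups = []
        for factor in (8, 4, 2, 1):
            n = fine_steps // factor
            dt = T / n
            inc = nf.coarsen_increments(fine, factor)
            se = nf.integrate(grid64, Y0, n, dt, gauss_kernel, gain, diff,
                              phi_gauss, increments=inc)
            sp, _ = nf.picard_solve(grid64, Y0, n, dt, gauss_kernel, gain,
                                    diff, phi_gauss, increments=inc)
            sups.append(np.max(np.abs(se.values - sp.values)))
        assert np.all(np.diff(sups) < 0)

    def test_needs_frozen_noise(self, gauss_kernel, grid64, phi_gauss):
        with pytest.raises(ValueError):
            nf.picard_solve(grid64, np.zeros(grid64.field_shape), 10, 0.1,
                            gauss_kernel, nf.sigmoid_gain(),
                            nf.constant_diffusion(1.0), phi_gauss)


class TestWeightedNorm:
    def test_zero_field(self, grid64):
        assert nf.weighted_norm(np.zeros(grid64.field_shape), None, grid64) == 0.0

    def test_unit_weight_is_plain_l2(self, grid64, rng):
        Y = rng.normal(size=grid64.field_shape)
        rho = nf.constant_weight(grid64, 1.0)
        assert nf.weighted_norm(Y, rho, grid64) == pytest.approx(
            nf.weighted_norm(Y, None, grid64))

    def test_brute_force_oracle(self, grid64, rng):
        Y = rng.normal(size=grid64.field_shape)
        rho = nf.rho_fourier(nf.gaussian_kernel(1.0, 1.0), grid64)
        oracle = np.sqrt(sum(float(Y[i]) ** 2 * float(rho.values[i])
                             * grid64.cell_volume
                             for i in rng.permutation(grid64.n_nodes)))
        assert nf.weighted_norm(Y, rho, grid64) == pytest.approx(oracle, rel=1e-12)


class TestMomentDiagnostics:
    def _ensemble(self, grid, phi, gain, diffusion, kernel, n_steps, dt, reps,
                  y0=1.0):
        Y0 = np.full(grid.field_shape, y0)
        return [nf.integrate(grid, Y0, n_steps, dt, kernel, gain, diffusion,
                             phi, seed=1000 + i) for i in range(reps)]

    def test_pure_decay_second_moment(self, grid64, phi_gauss):
        paths = self._ensemble(grid64, phi_gauss, nf.constant_gain(0.0),
                               nf.constant_diffusion(0.0), nf.zero_kernel(),
                               40, 0.05, 100, y0=2.0)
        rep = nf.moment_diagnostics(paths)
        t = rep["times"]
        np.testing.assert_allclose(rep["p"][2]["sup_moment"],
                                   4.0 * np.exp(-2 * t), rtol=1e-10)

    def test_bounded_coefficients_plateau(self, grid64, phi_gauss):
        paths = self._ensemble(grid64, phi_gauss, nf.sigmoid_gain(),
                               nf.bounded_diffusion(0.5), nf.gaussian_kernel(1, 1),
                               200, 0.05, 100)
        rep = nf.moment_diagnostics(paths)
        assert rep["verdict"] == "bounded"
        assert abs(rep["growth_exponent"]) < 0.25

    def test_single_replicate_rejected(self, grid64, phi_gauss):
        paths = self._ensemble(grid64, phi_gauss, nf.sigmoid_gain(),
                               nf.constant_diffusion(0.0), nf.zero_kernel(),
                               5, 0.05, 1)
        with pytest.raises(ValueError):
            nf.moment_diagnostics(paths)


class TestEquivalence:
    def test_shared_noise_discrepancy_tiny(self, gauss_kernel, grid64, phi_gauss):
        rho = nf.rho_fourier(gauss_kernel, grid64)
        Y0 = np.ones(grid64.field_shape)
        d = nf.equivalence_check(grid64, Y0, 30, 0.05, gauss_kernel,
                                 nf.sigmoid_gain(), nf.linear_diffusion(0.4),
                                 phi_gauss, rho, seed=11)
        assert d < 1e-10

    def test_deterministic_case_exact_zero(self, gauss_kernel, grid64, phi_gauss):
        rho = nf.rho_fourier(gauss_kernel, grid64)
        Y0 = np.ones(grid64.field_shape)
        d = nf.equivalence_check(grid64, Y0, 20, 0.05, gauss_kernel,
                                 nf.sigmoid_gain(), nf.constant_diffusion(0.0),
                                 phi_gauss, rho, seed=11)
        assert d == 0.0

    def test_mismatched_seeds_detected(self, gauss_kernel, grid64, phi_gauss):
        rho = nf.rho_fourier(gauss_kernel, grid64)
        Y0 = np.ones(grid64.field_shape)
        d = nf.equivalence_check(grid64, Y0, 30, 0.05, gauss_kernel,
                                 nf.sigmoid_gain(), nf.linear_diffusion(0.4),
                                 phi_gauss, rho, seed=11, seed_hs=12)
        assert d > 1e-3

    def test_missing_weight_rejected(self, gauss_kernel, grid64, phi_gauss):
        with pytest.raises(ValueError):
            nf.equivalence_check(grid64, np.ones(grid64.field_shape), 5, 0.05,
                                 gauss_kernel, nf.sigmoid_gain(),
                                 nf.constant_diffusion(1.0), phi_gauss,
                                 None, seed=0)
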