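import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from gridbind.constants import rt
from gridbind.io_cv import BiasSpec, WindowConfig
from gridbind.reweight import (
    ReweightError,
    bias_energy_matrix,
    solve_weights,
)

from conftest import gaussian_umbrella_samples, make_sample_set

RT300 = rt(300.0)


def brute_force_fixed_point(u, n_i, temperature, tol=1e-12, max_iter=200_000):
    """Independent direct iteration of the weight/free-energy equations,
    written naively (no log-sum-exp, no minimizer)."""
    beta = 1.0 / rt(temperature)
    f = np.zeros(u.shape[1])
    for _ in range(max_iter):
        denom = (n_i[None, :] * np.exp(-beta * (u - f[None, :]))).sum(axis=1)
        w = 1.0 / denom
        w /= w.sum()
        f_new = -np.log((w[:, None] * np.exp(-beta * u)).sum(axis=0)) / beta
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            return f_new, w
        f = f_new
    return f, w


class TestBiasEnergyMatrix:
    def test_zero_at_center(self):
        s = make_sample_set({"w0": [[10.0]]}, ["d"])
        cfg = WindowConfig(
            windows=[("w0", [BiasSpec(cv="d", center=10.0, force_constant=2.0)])],
            temperature=300.0,
        )
        assert bias_energy_matrix(s, cfg)[0, 0] == pytest.approx(0.0)

    def test_one_angstrom_displacement(self):
        s = make_sample_set({"w0": [[11.0]]}, ["d"])
        cfg = WindowConfig(
            windows=[("w0", [BiasSpec(cv="d", center=10.0, force_constant=2.0)])],
            temperature=300.0,
        )
        assert bias_energy_matrix(s, cfg)[0, 0] == pytest.approx(1.0)

    def test_two_biases_add(self):
        s = make_sample_set({"w0": [[11.0, 0.2]]}, ["d", "omega"])
        cfg = WindowConfig(
            windows=[
                ("w0", [
                    BiasSpec(cv="d", center=10.0, force_constant=2.0),
                    BiasSpec(cv="omega", center=0.0, force_constant=5.0),
                ])
            ],
            temperature=300.0,
        )
        expected = 0.5 * 2.0 * 1.0**2 + 0.5 * 5.0 * 0.2**2
        assert bias_energy_matrix(s, cfg)[0, 0] == pytest.approx(expected)

    def test_missing_cv_is_an_error(self):
        s = make_sample_set({"w0": [[11.0]]}, ["d"])
        cfg = WindowConfig(
            windows=[("w0", [BiasSpec(cv="omega", center=0.0, force_constant=1.0)])],
            temperature=300.0,
        )
        with pytest.raises(ReweightError, match="omega"):
            bias_energy_matrix(s, cfg)


class TestSolveWeights:
    def test_zero_bias_gives_uniform_weights(self, rng):
        vals = {f"w{i}": rng.normal(0, 1, (40, 1)) for i in range(3)}
        s = make_sample_set(vals, ["x"])
        cfg = WindowConfig(
            windows=[(f"w{i}", [BiasSpec(cv="x", center=0.0, force_constant=0.0)])
                     for i in range(3)],
            temperature=300.0,
        )
        res = solve_weights(s, cfg)
        assert res.converged
        np.testing.assert_allclose(res.weights, 1.0 / s.n_frames, rtol=1e-10)
        np.testing.assert_allclose(res.perturbed_free_energies, 0.0, atol=1e-10)

    def test_single_window_closed_form(self, rng):
        x = rng.normal(0.5, 0.4, (200, 1))
        s = make_sample_set({"w0": x}, ["x"])
        cfg = WindowConfig(
            windows=[("w0", [BiasSpec(cv="x", center=0.0, force_constant=3.0)])],
            temperature=300.0,
        )
        res = solve_weights(s, cfg)
        u = 0.5 * 3.0 * x[:, 0] ** 2
        expected = np.exp(u / RT300)
        expected /= expected.sum()
        np.testing.assert_allclose(res.weights, expected, rtol=1e-8)
        assert res.perturbed_free_energies[0] == 0.0

    def test_weights_normalized_and_free_energies_anchored(self, rng):
        samples, config = gaussian_umbrella_samples(
            kappa=1.0, centers=[0.0, 1.0, 2.0], k_bias=2.0, n=150, seed=5
        )
        res = solve_weights(samples, config)
        assert res.converged
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.perturbed_free_energies[0] == 0.0

    def test_agrees_with_brute_force_oracle(self):
        samples, config = gaussian_umbrella_samples(
            kappa=1.0, centers=[0.0, 1.0, 2.0], k_bias=2.0, n=100, seed=11
        )
        res = solve_weights(samples, config, tol=1e-12)
        u = bias_energy_matrix(samples, config)
        f_ref, w_ref = brute_force_fixed_point(
            u, samples.n_per_window.astype(float), 300.0
        )
        np.testing.assert_allclose(res.perturbed_free_energies, f_ref, atol=1e-8)
        np.testing.assert_allclose(res.weights, w_ref, atol=1e-12)

    def test_pure_iteration_matches_warm_started_solution(self):
        samples, config = gaussian_umbrella_samples(
            kappa=1.0, centers=[0.0, 1.5], k_bias=2.0, n=120, seed=3
        )
        a = solve_weights(samples, config, tol=1e-11, warm_start=True)
        b = solve_weights(samples, config, tol=1e-11, warm_start=False)
        assert a.converged and b.converged
        np.testing.assert_allclose(
            a.perturbed_free_energies, b.perturbed_free_energies, atol=1e-9
        )

    def test_two_umbrella_free_energy_matches_quadrature(self):
        """F2 - F1 on the 1-D Gaussian system equals the quadrature value
        -RT ln[int e^{-beta(U0+U2)} / int e^{-beta(U0+U1)}]."""
        kappa, k, c = 1.0, 2.0, 2.0
        samples, config = gaussian_umbrella_samples(
            kappa=kappa, centers=[0.0, c], k_bias=k, n=5000, seed=42
        )
        res = solve_weights(samples, config)
        beta = 1.0 / RT300

        def z(center):
            return quad(
                lambda x: np.exp(-beta * (0.5 * kappa * x**2
                                          + 0.5 * k * (x - center) ** 2)),
                -20, 20,
            )[0]

        truth = -RT300 * np.log(z(c) / z(0.0))
        est = res.perturbed_free_energies[1]
        # closed form for the Gaussian integrals as a second, exact oracle
        closed = kappa * k * c**2 / (2 * (kappa + k))
        assert truth == pytest.approx(closed, abs=1e-10)
        # statistical agreement: ~3 sd of the estimator at n=5000/window
        assert est == pytest.approx(truth, abs=0.05)

    def test_nonconvergence_is_flagged_not_raised(self):
        samples, config = gaussian_umbrella_samples(
            kappa=1.0, centers=[0.0, 2.0], k_bias=2.0, n=50, seed=1
        )
        res = solve_weights(samples, config, tol=1e-15, max_iter=2, warm_start=False)
        assert not res.converged
        assert res.max_residual > 1e-15

    def test_unequal_sample_counts_reduce_to_equal_count_form(self, rng):
        """With equal n_i the generalized denominator is the equal-count
        estimator; cross-check by duplicating a window's samples."""
        samples, config = gaussian_umbrella_samples(
            kappa=1.0, centers=[0.0, 1.0], k_bias=2.0, n=80, seed=9
        )
        res = solve_weights(samples, config, tol=1e-12)
        u = bias_energy_matrix(samples, config)
        # equal-count closed form of the denominator: n * sum_i e^{-beta(U_i-F_i)}
        beta = 1.0 / RT300
        f = res.perturbed_free_energies
        denom = (80 * np.exp(-beta * (u - f[None, :]))).sum(axis=1)
        w = (1 / denom) / (1 / denom).sum()
        np.testing.assert_allclose(res.weights, w, rtol=1e-10)


class TestInvariants:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(shift=st.floats(-5, 5, allow_nan=False))
    def test_gauge_invariance_under_constant_bias_shift(self, shift):
        """Adding a constant to every window's bias shifts all F_i by that
        constant and leaves the weights unchanged."""
        samples, config = gaussian_umbrella_samples(
            kappa=1.0, centers=[0.0, 1.0], k_bias=2.0, n=60, seed=7
        )
        u = bias_energy_matrix(samples, config)
        n_i = samples.n_per_window.astype(float)
        f0, w0 = brute_force_fixed_point(u, n_i, 300.0, tol=1e-13)
        f1, w1 = brute_force_fixed_point(u + shift, n_i, 300.0, tol=1e-13)
        # anchored at F_1 = 0 the shift cancels; weights are identical
        np.testing.assert_allclose(f1, f0, atol=1e-7)
        np.testing.assert_allclose(w1, w0, atol=1e-12)

    def test_reweighted_mean_converges_to_quadrature_truth(self):
        """<x^2> under the unbiased ensemble recovered from biased samples."""
        kappa = 1.0
        samples, config = gaussian_umbrella_samples(
            kappa=kappa, centers=[-2.0, -1.0, 0.0, 1.0, 2.0], k_bias=2.0,
            n=4000, seed=13,
        )
        res = solve_weights(samples, config)
        x = samples.cv("x")
        est = float(np.sum(res.weights * x**2))
        truth = RT300 / kappa  # equipartition
        assert est == pytest.approx(truth, rel=0.05)
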