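"""Membrane response, Poisson firing, and the passive-cable series solution."""

import numpy as np
import pytest
from scipy import stats

from mcchain.neuron import (
    AxonParams,
    FiringParams,
    SpikeTrain,
    axonal_delay,
    cable_solution,
    firing_rate,
    generate_spikes,
    membrane_potential,
    propagate_spike_train,
)
from mcchain.signals import RngHandle, TimeGrid, Trace


@pytest.fixture
def fp():
    # linear regime: no drive saturation
    return FiringParams(drive_cap=None)


def small_grid():
    return TimeGrid(0.0, 4.0, 0.002)


class TestMembranePotential:
    def test_zero_flux_rests(self, fp):
        g = small_grid()
        z = Trace(g, np.zeros(g.n_points))
        v = membrane_potential([z, z], [0.0, 0.0], fp, g)
        assert np.all(v.values == fp.V_r)

    def test_linearity_without_saturation(self, fp):
        g = small_grid()
        t = g.times
        f1 = Trace(g, 0.1 * np.exp(-((t - 1.0) ** 2)))
        f2 = Trace(g, 0.2 * np.exp(-((t - 2.5) ** 2) * 4))
        v1 = membrane_potential([f1], [0.0], fp, g)
        v2 = membrane_potential([f2], [0.0], fp, g)
        v12 = membrane_potential([f1, f2], [0.0, 0.0], fp, g)
        np.testing.assert_allclose(
            v12.values - fp.V_r,
            (v1.values - fp.V_r) + (v2.values - fp.V_r),
            atol=1e-9,
        )

    def test_convolution_matches_direct_sum_oracle(self, fp):
        g = TimeGrid(0.0, 2.0, 0.01)
        t = g.times
        flux = Trace(g, 0.05 * np.sin(2 * np.pi * t / 2.0) ** 2)
        v = membrane_potential([flux], [0.0], fp, g)
        kernel = fp.kernel_gain * np.exp(-t / fp.kernel_tau) / fp.kernel_tau
        direct = np.zeros(g.n_points)
        for i in range(g.n_points):
            acc = 0.0
            for j in range(i + 1):
                acc += flux.values[i - j] * kernel[j]
            direct[i] = fp.V_r + acc * g.dt
        np.testing.assert_allclose(v.values, direct, rtol=1e-9, atol=1e-9)

    def test_drive_cap_bounds_plateau(self):
        fp = FiringParams(drive_cap=10.0)
        g = small_grid()
        big = Trace(g, np.full(g.n_points, 5.0))
        v = membrane_potential([big], [0.0], fp, g)
        assert v.values.max() <= fp.V_r + 10.0 + 1e-9


class TestFiringRate:
    def test_far_below_threshold_silent(self, fp):
        g = small_grid()
        v = Trace(g, np.full(g.n_points, fp.theta1 - 30.0))
        lam = firing_rate(v, fp)
        assert np.all(lam.values < 1e-3)

    def test_logistic_midpoint_at_threshold(self, fp):
        g = small_grid()
        v = Trace(g, np.full(g.n_points, fp.theta1))
        lam = firing_rate(v, fp)
        assert lam.values[0] == pytest.approx(fp.lambda_max / 2)

    def test_monotone_in_potential(self, fp):
        g = small_grid()
        v = Trace(g, np.linspace(-90, -20, g.n_points))
        lam = firing_rate(v, fp)
        assert np.all(np.diff(lam.values) >= 0)


class TestGenerateSpikes:
    def test_zero_rate_empty_train(self, rng):
        g = small_grid()
        lam = Trace(g, np.zeros(g.n_points))
        assert len(generate_spikes(lam, rng)) == 0

    def test_constant_rate_poisson_moments(self):
        lam0, T, reps = 20.0, 10.0, 500
        g = TimeGrid(0.0, T, 0.01)
        lam = Trace(g, np.full(g.n_points, lam0))
        counts = [
            len(generate_spikes(lam, RngHandle(1000 + r, "spk"))) for r in range(reps)
        ]
        counts = np.asarray(counts)
        mean_expected = lam0 * T
        assert abs(counts.mean() - mean_expected) < 3 * np.sqrt(mean_expected / reps)
        dispersion = counts.var(ddof=1) / counts.mean()
        # index of dispersion ~ 1 for Poisson; its sd is ~ sqrt(2/reps)
        assert abs(dispersion - 1.0) < 4 * np.sqrt(2 / reps)

    def test_thinning_matches_time_rescaling_oracle(self):
        # rescaled waiting times of an inhomogeneous Poisson process are
        # unit-rate exponential; aggregate KS p-value must not be tiny
        g = TimeGrid(0.0, 20.0, 0.001)
        lam = Trace(g, 10.0 + 8.0 * np.sin(2 * np.pi * g.times / 5.0))
        pvals = []
        for r in range(20):
            spikes = generate_spikes(lam, RngHandle(500 + r, "tr"))
            t = np.asarray(spikes.times)
            cum = np.interp(t, g.times, np.cumsum(lam.values) * g.dt)
            z = np.diff(cum)
            pvals.append(stats.kstest(z, "expon").pvalue)
        # Fisher combination against uniformity of p-values
        fisher = -2 * np.sum(np.log(np.asarray(pvals)))
        assert stats.chi2.sf(fisher, 2 * len(pvals)) > 0.01


class TestCableSolution:
    def test_single_cosine_mode_closed_form(self):
        p = AxonParams(n_modes=8)
        L = p.L_N
        profile = lambda x: np.cos(np.pi * x / L)  # noqa: E731
        x = np.linspace(0, L, 7)
        for t in (0.0, 0.05, 0.2):
            got = cable_solution(profile, p, x, t)
            expected = (
                np.exp(-t / p.tau_m)
                * np.exp(-np.pi**2 * t / (L**2 * p.tau_l))
                * np.cos(np.pi * x / L)
            )
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_matches_finite_difference_oracle(self):
        # explicit FD solver of the cable PDE with sealed (Neumann) ends
        p = AxonParams(n_modes=120)
        L, tau_m = p.L_N, p.tau_m
        D = 1.0 / p.tau_l  # um^2/s
        nx = 201
        x = np.linspace(0, L, nx)
        dx = x[1] - x[0]
        dt = 0.2 * dx**2 / D
        w = p.L_N / 10.0
        v = np.exp(-((x / w) ** 2))
        t_targets = [0.05, 0.1, 0.2]
        t_now, k = 0.0, 0
        results = {}
        while k < len(t_targets):
            step = min(dt, t_targets[k] - t_now)
            lap = np.empty_like(v)
            lap[1:-1] = (v[2:] - 2 * v[1:-1] + v[:-2]) / dx**2
            lap[0] = 2 * (v[1] - v[0]) / dx**2
            lap[-1] = 2 * (v[-2] - v[-1]) / dx**2
            v = v + step * (D * lap - v / tau_m)
            t_now += step
            if abs(t_now - t_targets[k]) < 1e-12:
                results[t_targets[k]] = v.copy()
                k += 1
        profile = lambda xx: np.exp(-((xx / w) ** 2))  # noqa: E731
        for t, fd in results.items():
            series = cable_solution(profile, p, x, t)
            scale = np.max(np.abs(fd))
            assert np.max(np.abs(series - fd)) / scale < 0.01

    def test_decays_to_zero(self):
        p = AxonParams(n_modes=10)
        w = p.L_N / 10.0
        profile = lambda x: np.exp(-((x / w) ** 2))  # noqa: E731
        assert abs(cable_solution(profile, p, p.L_N / 2, 50.0)) < 1e-12

    def test_sine_basis_vanishes_at_grounded_end(self):
        p = AxonParams(n_modes=40)
        L = p.L_N
        profile = lambda x: np.sin(np.pi * x / L)  # noqa: E731
        # single sine mode: closed form, and V(0,t) = 0 exactly
        for t in (0.0, 0.05):
            got = cable_solution(profile, p, np.array([0.0, L / 3]), t, basis="sine")
            expected = (
                np.exp(-t / p.tau_m)
                * np.exp(-np.pi**2 * t / (L**2 * p.tau_l))
                * np.sin(np.pi * np.array([0.0, L / 3]) / L)
            )
            np.testing.assert_allclose(got, expected, atol=1e-10)
            assert got[0] == pytest.approx(0.0, abs=1e-12)

    def test_series_self_convergence(self):
        # doubling the truncation changes nothing measurable after 1 ms
        w = AxonParams().L_N / 10.0
        profile = lambda x: np.exp(-((x / w) ** 2))  # noqa: E731
        xs = np.linspace(0, AxonParams().L_N, 11)
        a = cable_solution(profile, AxonParams(n_modes=60), xs, 0.001)
        b = cable_solution(profile, AxonParams(n_modes=120), xs, 0.001)
        assert np.max(np.abs(a - b)) < 1e-6


class TestAxonalDelay:
    def test_pure_decay_profile_flagged_zero(self):
        p = AxonParams(n_modes=8)
        profile = lambda x: np.cos(np.pi * x / p.L_N)  # noqa: E731
        delay, peaked = axonal_delay(p, profile)
        assert delay == 0.0 and not peaked

    def test_bump_delay_positive_and_grows_with_length(self):
        delays = []
        for L in (20.0, 43.2, 80.0):
            delay, peaked = axonal_delay(AxonParams(L_N=L))
            assert peaked and delay > 0
            delays.append(delay)
        assert delays[0] < delays[1] < delays[2]

    def test_refinement_agrees_with_dense_scan(self):
        p = AxonParams()
        delay, _ = axonal_delay(p)
        ts = np.linspace(1e-6, 1.0, 20001)
        w = p.L_N / 10.0
        vals = cable_solution(lambda x: np.exp(-((x / w) ** 2)), p, p.L_N, ts)
        assert delay == pytest.approx(ts[np.argmax(vals)], abs=1e-3)


class TestPropagate:
    def test_empty_train(self):
        out = propagate_spike_train(SpikeTrain(()), AxonParams(), delay=0.1)
        assert len(out) == 0

    def test_uniform_shift_preserves_isis(self):
        train = SpikeTrain((0.1, 0.25, 0.9, 1.7))
        out = propagate_spike_train(train, AxonParams(), delay=0.05)
        np.testing.assert_allclose(
            np.diff(out.times), np.diff(train.times), rtol=1e-12
        )
        assert out.times[0] == pytest.approx(0.15)

    def test_default_shift_equals_axonal_delay(self):
        p = AxonParams()
        delay, _ = axonal_delay(p)
        out = propagate_spike_train(SpikeTrain((1.0,)), p)
        assert out.times[0] == pytest.approx(1.0 + delay)
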