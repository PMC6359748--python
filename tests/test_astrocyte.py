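"""Li-Rinzel calcium dynamics, IP3 coupling, boundary flux and relay delay."""

import numpy as np
import pytest

from mcchain.astrocyte import (
    AstrocyteParams,
    AstrocyteState,
    Ip3Coupling,
    calcium_delay,
    calcium_flux_to_neuron,
    calcium_fluxes,
    count_sustained_peaks,
    hormone_to_ip3,
    resting_calcium,
    scan_oscillation_regime,
    simulate_astrocyte,
)
from mcchain.signals import TimeGrid, Trace


@pytest.fixture
def params():
    return AstrocyteParams()


def constant_ip3_trace(grid, value):
    return Trace(grid, np.full(grid.n_points, value), units="uM")


class TestCalciumFluxes:
    def test_no_gradient_no_channel_or_leak_flux(self, params):
        st = AstrocyteState(C_CY=0.5, C_ER=0.5, h=0.8)
        u_chan, u_leak, _ = calcium_fluxes(st, 0.4, params)
        assert u_chan == 0.0 and u_leak == 0.0

    def test_pump_half_saturation(self, params):
        st = AstrocyteState(C_CY=params.b3, C_ER=5.0, h=0.5)
        _, _, u_pump = calcium_fluxes(st, 0.0, params)
        assert u_pump == pytest.approx(params.v_pump / 2) == pytest.approx(0.45)

    def test_gate_fully_open_at_zero_calcium(self, params):
        from mcchain.astrocyte import gate_coefficients

        _, a3 = gate_coefficients(0.0, 0.0, params)
        assert a3 == pytest.approx(1.0)


class TestSimulateAstrocyte:
    def test_as_printed_conserves_weighted_difference(self, params):
        # subtracting the printed equations termwise gives
        # d/dt (C_CY - a1*C_ER) = 0 identically
        grid = TimeGrid(0.0, 100.0, 0.01)
        init = AstrocyteState.resting(params)
        ip3 = constant_ip3_trace(grid, 0.4)
        _, hist = simulate_astrocyte(ip3, init, params, grid, "as_printed")
        inv = hist[:, 0] - params.a1 * hist[:, 1]
        assert np.max(np.abs(inv - inv[0])) < 1e-6

    def test_li_rinzel_conserves_total_calcium(self, params):
        grid = TimeGrid(0.0, 100.0, 0.01)
        init = AstrocyteState.resting(params)
        ip3 = constant_ip3_trace(grid, 0.4)
        _, hist = simulate_astrocyte(ip3, init, params, grid, "li_rinzel")
        total = hist[:, 0] + params.a1 * hist[:, 1]
        assert np.max(np.abs(total - total[0])) < 1e-6

    def test_oscillates_inside_window_and_period_converges(self, params):
        grid = TimeGrid(0.0, 60.0, 0.01)
        fine = TimeGrid(0.0, 60.0, 0.005)
        init = AstrocyteState.resting(params)
        periods = []
        for g in (grid, fine):
            ca, _ = simulate_astrocyte(
                constant_ip3_trace(g, 0.45), init, params, g, "li_rinzel"
            )
            from scipy.signal import find_peaks

            peaks, _ = find_peaks(ca.values, prominence=0.05)
            t_peaks = g.times[peaks]
            assert len(t_peaks) >= 3
            periods.append(np.mean(np.diff(t_peaks)))
        assert periods[0] == pytest.approx(periods[1], rel=1e-3)

    def test_no_stimulus_monotone_decay_to_floor(self, params):
        grid = TimeGrid(0.0, 60.0, 0.01)
        init = AstrocyteState.resting(params, C_CY=0.1)
        ca, _ = simulate_astrocyte(
            constant_ip3_trace(grid, 0.0), init, params, grid, "li_rinzel"
        )
        assert count_sustained_peaks(ca, transient=0.0) == 0
        floor = resting_calcium(params)
        assert ca.values[-1] == pytest.approx(floor, abs=1e-3)
        # decay is monotone within integrator wiggle
        assert np.all(np.diff(ca.values) < 1e-6)

    def test_h_stays_in_unit_interval(self, params):
        grid = TimeGrid(0.0, 100.0, 0.01)
        init = AstrocyteState.resting(params)
        for ip3 in (0.0, 0.45, 1.0):
            _, hist = simulate_astrocyte(
                constant_ip3_trace(grid, ip3), init, params, grid, "li_rinzel"
            )
            assert np.all(hist[:, 2] >= -1e-9)
            assert np.all(hist[:, 2] <= 1.0 + 1e-9)


class TestOscillationRegime:
    def test_window_is_nonempty_and_bracketed(self, params):
        lo, hi = scan_oscillation_regime(
            params, "li_rinzel", np.arange(0.0, 1.2001, 0.05), duration=150.0
        )
        assert not np.isnan(lo)
        assert 0.2 < lo < 0.5 < hi < 0.9

    def test_steady_states_outside_window(self, params):
        # below: low steady calcium; above: high steady level, no waves
        grid = TimeGrid(0.0, 150.0, 0.05)
        init = AstrocyteState.resting(params)
        below, _ = simulate_astrocyte(
            constant_ip3_trace(grid, 0.1), init, params, grid, "li_rinzel"
        )
        above, _ = simulate_astrocyte(
            constant_ip3_trace(grid, 1.0), init, params, grid, "li_rinzel"
        )
        assert count_sustained_peaks(below) == 0
        assert count_sustained_peaks(above) == 0
        tail_lo = below.values[below.grid.index_of(100.0):]
        tail_hi = above.values[above.grid.index_of(100.0):]
        assert tail_hi.mean() > 4 * tail_lo.mean()

    def test_frequency_nondecreasing_in_ip3(self, params):
        # holds through the lower and middle of the oscillatory window;
        # near the upper boundary the period plateaus
        from scipy.signal import find_peaks

        grid = TimeGrid(0.0, 150.0, 0.01)
        init = AstrocyteState.resting(params)
        freqs = []
        for ip3 in (0.40, 0.45, 0.50):
            ca, _ = simulate_astrocyte(
                constant_ip3_trace(grid, ip3), init, params, grid, "li_rinzel"
            )
            i0 = grid.index_of(50.0)
            peaks, _ = find_peaks(ca.values[i0:], prominence=0.05)
            freqs.append(len(peaks))
        assert freqs[0] <= freqs[1] <= freqs[2]
        assert freqs[2] > freqs[0]


class TestIp3Coupling:
    coupling = Ip3Coupling(ip3_max=0.55, K_half=1e-5, hill_n=1.0, ip3_base=0.05)

    def test_zero_hormone_gives_base(self, coarse_grid):
        tr = Trace(coarse_grid, np.zeros(coarse_grid.n_points))
        out = hormone_to_ip3(tr, self.coupling)
        assert np.all(out.values == pytest.approx(0.05))

    def test_saturates_at_max(self, coarse_grid):
        tr = Trace(coarse_grid, np.full(coarse_grid.n_points, 1e3))
        out = hormone_to_ip3(tr, self.coupling)
        assert out.values[0] == pytest.approx(0.55, rel=1e-6)

    def test_hill_midpoint(self, coarse_grid):
        tr = Trace(coarse_grid, np.full(coarse_grid.n_points, 1e-5))
        out = hormone_to_ip3(tr, self.coupling)
        assert out.values[0] == pytest.approx(0.5 * (0.05 + 0.55))

    def test_monotone_in_hormone(self, coarse_grid):
        c = np.linspace(0, 1e-4, coarse_grid.n_points)
        out = hormone_to_ip3(Trace(coarse_grid, c), self.coupling)
        assert np.all(np.diff(out.values) >= 0)


class TestFluxToNeuron:
    def test_zero_trace_gives_zero_flux(self, params, coarse_grid):
        z = Trace(coarse_grid, np.zeros(coarse_grid.n_points))
        flux = calcium_flux_to_neuron(z, params)
        assert np.all(flux.values == 0.0)

    def test_linearity(self, params, coarse_grid):
        rest = resting_calcium(params)
        t = coarse_grid.times
        base = rest + 0.3 * np.exp(-((t - 10.0) ** 2))
        p = AstrocyteParams(flux_subtract_rest=False)
        one = calcium_flux_to_neuron(Trace(coarse_grid, base), p)
        two = calcium_flux_to_neuron(Trace(coarse_grid, 2 * base), p)
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-10)

    def test_peak_lag_shrinks_with_diffusivity(self, coarse_grid):
        rest = resting_calcium(AstrocyteParams())
        t = coarse_grid.times
        ca = Trace(coarse_grid, rest + 0.4 * np.exp(-((t - 10.0) ** 2)))
        lags = []
        for d_ca in (5.0, 20.0, 80.0):
            p = AstrocyteParams(D_Ca=d_ca, ca_clearance_tau=None)
            flux = calcium_flux_to_neuron(ca, p)
            lag = t[np.argmax(flux.values)] - 10.0
            assert lag > 0
            lags.append(lag)
        assert lags[0] > lags[1] > lags[2]


class TestCalciumDelay:
    def test_identical_traces_zero_delay(self, params, coarse_grid):
        t = coarse_grid.times
        wave = Trace(coarse_grid, 0.3 * np.exp(-((t - 5.0) ** 2)))
        omega, reached = calcium_delay([wave], wave, T=10.0)
        assert reached and omega == 0.0

    def test_bisection_matches_linear_scan(self, params, coarse_grid):
        t = coarse_grid.times
        astro = Trace(coarse_grid, 0.3 * np.exp(-((t - 5.0) ** 2)))
        # neuron absorbs a slightly larger variation, stretched and delayed
        neuron = Trace(coarse_grid, 0.35 * np.exp(-(((t - 14.0) / 2.0) ** 2)))
        omega, reached = calcium_delay([astro], neuron, T=10.0)
        assert reached
        # oracle: linear scan on the cumulative integral
        dt = coarse_grid.dt
        dem = np.trapezoid(
            np.abs(np.gradient(astro.values, dt))[: coarse_grid.index_of(10.0) + 1],
            dx=dt,
        )
        sup = np.abs(np.gradient(neuron.values, dt))
        cum = np.concatenate([[0], np.cumsum((sup[1:] + sup[:-1]) / 2 * dt)])
        k = np.argmax(cum >= dem)
        assert omega == pytest.approx(t[k] - 10.0, abs=2 * dt)

    def test_unreachable_flagged(self, params, coarse_grid):
        t = coarse_grid.times
        astro = Trace(coarse_grid, 0.3 * np.exp(-((t - 5.0) ** 2)))
        tiny = Trace(coarse_grid, 1e-4 * np.exp(-((t - 14.0) ** 2)))
        _, reached = calcium_delay([astro], tiny, T=10.0)
        assert not reached
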