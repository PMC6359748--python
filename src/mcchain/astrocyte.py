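"""IP3-gated astrocyte Ca2+ dynamics and the Ca2+ relay to the neuron.

The cytosolic/ER calcium exchange follows a Li-Rinzel-type reduction of
the IP3-receptor model: an IP3- and Ca2+-gated channel flux from the ER,
a passive leak, a Hill-2 SERCA pump, and a slow inactivation gate ``h``.
Hormone concentration is transduced into IP3 through a saturating Hill
coupling (G-protein receptor cascade), and cytosolic Ca2+ reaches the
neuron boundary by diffusion from the ER region treated as a point
source, i.e. convolution with a 3-D heat kernel.

Two sign conventions for the ER pool are provided.  ``as_printed``
integrates the equation set literally, which conserves
``C_CY - a1 * C_ER`` (cytosol and store rise together).  ``li_rinzel``
(the default for end-to-end runs) conserves total calcium
``C_CY + a1 * C_ER`` so that store depletion opposes cytosolic release
and sustained oscillations exist; this is the classical closed-cell
Li-Rinzel behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .hormone import green_function
from .signals import TimeGrid, Trace

__all__ = [
    "AstrocyteParams",
    "AstrocyteState",
    "Ip3Coupling",
    "calcium_fluxes",
    "simulate_astrocyte",
    "count_sustained_peaks",
    "scan_oscillation_regime",
    "hormone_to_ip3",
    "calibrate_ip3_coupling",
    "calcium_flux_to_neuron",
    "calcium_delay",
]

Convention = Literal["as_printed", "li_rinzel"]


@dataclass
class AstrocyteParams:
    """Li-Rinzel constants (defaults are the published astrocyte set)."""

    a1: float = 0.185          # ER/cytoplasm volume ratio
    v_chan: float = 6.0        # max channel flux rate, 1/s
    v_leak: float = 0.11       # max leak rate, 1/s
    v_pump: float = 0.9        # max pump flux, uM/s
    b1: float = 0.13           # IP3 dissociation constant, uM
    b2: float = 0.08234        # Ca2+ activation constant, uM
    b3: float = 0.1            # pump half-activation, uM
    b4: float = 0.9434         # IP3 constant of the gate, uM
    b5: float = 1.049          # Ca2+ inactivation constant, uM
    b6: float = 0.2            # gate binding rate, 1/(uM s)
    D_Ca: float = 20.0         # Ca2+ diffusion coefficient, um^2/s
    d_ER_B: float = 10.0       # ER-to-boundary distance, um
    total_ca: float = 2.0      # conserved C_CY + a1*C_ER (li_rinzel), uM
    flux_gain: float | None = None  # neuron-flux gain; None -> unit DC gain
    ca_capture_fraction: float = 0.125  # share of astrocytic Ca2+ the neuron absorbs
    flux_subtract_rest: bool = True  # drive the neuron with Ca2+ above resting level
    ca_clearance_tau: float | None = 1.0  # cytosolic buffering of Ca2+ in transit, s

    def __post_init__(self) -> None:
        for name in ("a1", "v_chan", "v_leak", "v_pump", "b1", "b2", "b3",
                     "b4", "b5", "b6", "D_Ca", "d_ER_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AstrocyteState:
    """Cytosolic Ca2+, ER Ca2+ (uM) and the inactivation gate h in [0, 1]."""

    C_CY: float
    C_ER: float
    h: float

    def __post_init__(self) -> None:
        if self.C_CY < 0 or self.C_ER < 0:
            raise ValueError("concentrations must be nonnegative")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")

    @classmethod
    def resting(cls, params: AstrocyteParams, C_CY: float = 0.1,
                C_IP3: float = 0.0) -> "AstrocyteState":
        """Rest state: C_ER from the conserved total, h at its nullcline."""
        C_ER = max((params.total_ca - C_CY) / params.a1, 0.0)
        bf = params.b5 * (C_IP3 + params.b1) / (C_IP3 + params.b4)
        h = bf / (bf + C_CY)
        return cls(C_CY, C_ER, h)


@dataclass
class Ip3Coupling:
    """Saturating Hill transduction hormone concentration -> IP3 (uM)."""

    ip3_max: float
    K_half: float               # hormone conc. at the Hill midpoint, molecules/um^3
    hill_n: float = 1.0
    ip3_base: float = 0.05

    def __post_init__(self) -> None:
        if not self.ip3_max > self.ip3_base >= 0:
            raise ValueError("need ip3_max > ip3_base >= 0")
        if self.K_half <= 0:
            raise ValueError("K_half must be positive")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")


def calcium_fluxes(
    state: AstrocyteState, C_IP3: float, params: AstrocyteParams
) -> tuple[float, float, float]:
    """Channel, leak and pump fluxes (uM/s) at the given state."""
    p = params
    m = C_IP3 / (C_IP3 + p.b1)
    n = state.C_CY / (state.C_CY + p.b2)
    U_chan = p.v_chan * m**3 * n**3 * state.h**3 * (state.C_ER - state.C_CY)
    U_leak = p.v_leak * (state.C_ER - state.C_CY)
    U_pump = p.v_pump * state.C_CY**2 / (state.C_CY**2 + p.b3**2)
    return U_chan, U_leak, U_pump


def gate_coefficients(
    C_CY: float, C_IP3: float, params: AstrocyteParams
) -> tuple[float, float]:
    """Gate time constant a2 (s) and steady value a3 for dh/dt = (a3-h)/a2."""
    bf = params.b5 * (C_IP3 + params.b1) / (C_IP3 + params.b4)
    a2 = 1.0 / (params.b6 * (bf + C_CY))
    a3 = bf / (bf + C_CY)
    return a2, a3


def _rhs(t, y, ip3_of_t, p: AstrocyteParams, convention: Convention):
    c_cy, c_er, h = y
    c_cy = max(c_cy, 0.0)
    c_er = max(c_er, 0.0)
    h = min(max(h, 0.0), 1.0)
    ip3 = float(ip3_of_t(t))
    state = AstrocyteState.__new__(AstrocyteState)
    state.C_CY, state.C_ER, state.h = c_cy, c_er, h
    U_chan, U_leak, U_pump = calcium_fluxes(state, ip3, p)
    dcy = p.a1 * (U_chan + U_leak) - U_pump
    if convention == "as_printed":
        der = (U_chan + U_leak) - U_pump / p.a1
    else:  # li_rinzel: total calcium C_CY + a1*C_ER conserved
        der = -dcy / p.a1
    a2, a3 = gate_coefficients(c_cy, ip3, p)
    dh = (a3 - h) / a2
    return (dcy, der, dh)


def simulate_astrocyte(
    ip3_trace: Trace,
    init: AstrocyteState,
    params: AstrocyteParams,
    grid: TimeGrid,
    convention: Convention = "li_rinzel",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[Trace, np.ndarray]:
    """Integrate the Ca2+ ODE system driven by an IP3 trace.

    Returns the cytosolic Ca2+ trace on the grid and the full state
    history (n_points x 3 array: C_CY, C_ER, h).
    """
    if ip3_trace.grid != grid:
        raise ValueError("ip3 trace must live on the run grid")
    t = grid.times
    ip3_vals = ip3_trace.values

    def ip3_of_t(tt):
        return np.interp(tt, t, ip3_vals)

    sol = solve_ivp(
        _rhs,
        (t[0], t[-1]),
        [init.C_CY, init.C_ER, init.h],
        t_eval=t,
        args=(ip3_of_t, params, convention),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"calcium integration failed: {sol.message}; last state {sol.y[:, -1]}"
        )
    history = sol.y.T
    ca = Trace(grid, np.clip(history[:, 0], 0.0, None), units="uM")
    return ca, history


def _constant_ip3_run(
    ip3: float,
    params: AstrocyteParams,
    convention: Convention,
    duration: float,
    dt: float,
) -> Trace:
    grid = TimeGrid(0.0, duration, dt)
    trace = Trace(grid, np.full(grid.n_points, ip3), units="uM")
    init = AstrocyteState.resting(params)
    ca, _ = simulate_astrocyte(trace, init, params, grid, convention)
    return ca


def count_sustained_peaks(
    ca: Trace, transient: float = 50.0, min_amplitude: float = 0.05
) -> int:
    """Number of Ca2+ peaks after an initial transient (prominence-filtered)."""
    i0 = ca.grid.index_of(transient)
    tail = ca.values[i0:]
    peaks, _ = find_peaks(tail, prominence=min_amplitude)
    return len(peaks)


def scan_oscillation_regime(
    params: AstrocyteParams,
    convention: Convention = "li_rinzel",
    ip3_grid: np.ndarray | None = None,
    duration: float = 150.0,
    dt: float = 0.05,
) -> tuple[float, float]:
    """Boundaries of the constant-IP3 interval with sustained oscillations.

    A grid point is oscillatory when the run shows at least two
    prominent Ca2+ peaks after a 50 s transient.  Returns (low, high);
    ``(nan, nan)`` when no grid point oscillates.
    """
    if ip3_grid is None:
        ip3_grid = np.arange(0.0, 1.2001, 0.02)
    ip3_grid = np.asarray(ip3_grid, dtype=float)
    if np.any(np.diff(ip3_grid) <= 0):
        raise ValueError("ip3_grid must be strictly increasing")
    osc = np.zeros(ip3_grid.size, dtype=bool)
    for i, ip3 in enumerate(ip3_grid):
        ca = _constant_ip3_run(float(ip3), params, convention, duration, dt)
        osc[i] = count_sustained_peaks(ca) >= 2
    if not osc.any():
        return (float("nan"), float("nan"))
    idx = np.nonzero(osc)[0]
    return (float(ip3_grid[idx[0]]), float(ip3_grid[idx[-1]]))


def hormone_to_ip3(hormone_trace: Trace, coupling: Ip3Coupling) -> Trace:
    """Monotone saturating Hill map from hormone concentration to IP3 (uM)."""
    c = np.clip(hormone_trace.values, 0.0, None)
    n = coupling.hill_n
    with np.errstate(divide="ignore", invalid="ignore"):
        hill = np.where(
            c > 0, c**n / (c**n + coupling.K_half**n), 0.0
        )
    ip3 = coupling.ip3_base + (coupling.ip3_max - coupling.ip3_base) * hill
    return Trace(hormone_trace.grid, ip3, units="uM")


def calibrate_ip3_coupling(
    mid_slot_concentration: float,
    ip3_max: float = 0.55,
    ip3_base: float = 0.05,
    hill_n: float = 1.0,
) -> Ip3Coupling:
    """Couple hormone to IP3 so a single "1"-pulse drives oscillations.

    ``K_half`` is pinned to the hormone concentration observed mid-slot
    at the reference astrocyte for one OOK pulse, which places the
    mid-slot IP3 at the Hill midpoint (ip3_base + ip3_max)/2 -- inside the
    oscillatory window of the default Li-Rinzel constants.
    """
    if mid_slot_concentration <= 0:
        raise ValueError("mid-slot concentration must be positive")
    return Ip3Coupling(
        ip3_max=ip3_max,
        K_half=mid_slot_concentration,
        hill_n=hill_n,
        ip3_base=ip3_base,
    )


def calcium_flux_to_neuron(ca_trace: Trace, params: AstrocyteParams) -> Trace:
    """Ca2+ flux density reaching the neuron boundary.

    Convolution of the cytosolic trace with the 3-D heat kernel at
    distance ``d_ER_B`` (ER treated as a point source).  The default gain
    normalises the kernel to unit DC gain, so the flux is a delayed,
    smoothed copy of the Ca2+ trace in the same units.  With
    ``flux_subtract_rest`` (default) the resting pump/leak equilibrium is
    removed first: the neuron is driven by calcium *signal*, not by the
    standing background exchange.
    """
    grid = ca_trace.grid
    t = grid.times - grid.t0
    kernel = np.zeros_like(t)
    kernel[1:] = green_function(params.d_ER_B, t[1:], params.D_Ca)
    if params.ca_clearance_tau is not None:
        # buffering/reuptake en route truncates the heavy diffusion tail
        kernel *= np.exp(-t / params.ca_clearance_tau)
    mass = np.trapezoid(kernel, dx=grid.dt)
    gain = params.flux_gain
    if gain is None:
        # unit DC gain over the grid horizon
        gain = 1.0 / mass if mass > 0 else 0.0
    values = ca_trace.values
    if params.flux_subtract_rest:
        values = np.clip(values - resting_calcium(params), 0.0, None)
    from scipy.signal import fftconvolve

    flux = fftconvolve(values, kernel)[: grid.n_points] * grid.dt * gain
    # FFT round-off can leave tiny negative values; flux is nonnegative
    return Trace(grid, np.clip(flux, 0.0, None), units=ca_trace.units)


def resting_calcium(params: AstrocyteParams, tol: float = 1e-10) -> float:
    """Pump-limited cytosolic Ca2+ floor: the root of leak = pump flux.

    At rest (no IP3) the channel flux is negligible and the leak from
    the ER balances the Hill-2 pump; solved by bisection.
    """
    from scipy.optimize import brentq

    def net(c_cy: float) -> float:
        c_er = max((params.total_ca - c_cy) / params.a1, 0.0)
        return (
            params.a1 * params.v_leak * (c_er - c_cy)
            - params.v_pump * c_cy**2 / (c_cy**2 + params.b3**2)
        )

    return float(brentq(net, 1e-9, params.total_ca, xtol=tol))


def _variation_density(values: np.ndarray, dt: float) -> np.ndarray:
    """|dC/dt| on the grid: the total-variation density of a trace."""
    d = np.gradient(values, dt)
    return np.abs(d)


def calcium_delay(
    astro_ca_traces: list[Trace],
    neuron_absorbed: Trace,
    T: float,
) -> tuple[float, bool]:
    """Relay delay Omega_Ca (s): extra time the neuron needs to absorb the
    per-astrocyte calcium signal variation of one slot.

    Demand is the mean per-astrocyte total variation over [0, T] (the
    relayed signal counted once); supply is the cumulative variation of
    the summed absorbed flux.  With more astrocytes the supply rate grows
    while the demand does not, so the delay shrinks.  Returns
    ``(omega_ca, reached)``; when the target is never reached within the
    grid, the grid end is returned with ``reached=False``.
    """
    if not astro_ca_traces:
        raise ValueError("need at least one astrocyte trace")
    grid = neuron_absorbed.grid
    for tr in astro_ca_traces:
        if tr.grid != grid:
            raise ValueError("all traces must share one grid")
    dt = grid.dt
    t = grid.times - grid.t0
    iT = grid.index_of(grid.t0 + T)
    demand = float(
        np.mean(
            [
                np.trapezoid(_variation_density(tr.values, dt)[: iT + 1], dx=dt)
                for tr in astro_ca_traces
            ]
        )
    )
    supply_rate = _variation_density(neuron_absorbed.values, dt)
    cum = np.concatenate(
        [[0.0], np.cumsum((supply_rate[1:] + supply_rate[:-1]) * 0.5 * dt)]
    )
    if cum[iT] >= demand:
        return 0.0, True
    if cum[-1] < demand:
        return float(t[-1] - T), False
    # bisection on the monotone cumulative integral
    lo, hi = iT, grid.n_points - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if cum[mid] >= demand:
            hi = mid
        else:
            lo = mid
    return float(t[hi] - T), True
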