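"""Amplify-and-forward neural firing and axonal cable propagation.

The neuron's membrane potential is the resting level plus the linear
response of the membrane to the calcium fluxes delivered by the
connected astrocytes (amplify-and-forward relaying: no decoding at the
relay).  Firing is an inhomogeneous Poisson process whose rate is a
logistic function of the distance of the potential from the firing
threshold; in the steep-slope limit this recovers a hard threshold.

Axonal propagation follows passive cable theory.  The initial potential
profile is expanded in a cosine series; each mode decays with its own
rate, and the membrane leak contributes a global exp(-t/tau_m) factor
with tau_m = gamma_m * gamma_c read as one effective time constant.
With the published values (64.1 MOhm, 1 mF/cm^2) the product is taken in
milliseconds (tau_m = 64.1 ms), the physiological range for membrane
time constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.signal import fftconvolve

from .signals import RngHandle, TimeGrid, Trace

__all__ = [
    "FiringParams",
    "SpikeTrain",
    "AxonParams",
    "membrane_potential",
    "firing_rate",
    "generate_spikes",
    "cable_solution",
    "axonal_delay",
    "propagate_spike_train",
]


@dataclass
class FiringParams:
    """Membrane response and rate-map constants."""

    V_r: float = -70.0         # resting potential, mV
    theta1: float = -55.0      # firing threshold, mV
    kernel_tau: float = 3.0    # membrane response time constant, s
    kernel_gain: float = 200.0  # mV per flux unit (uM), unit-mass kernel
    lambda_max: float = 18.0   # rate ceiling, Hz
    rate_slope: float = 5.0    # logistic steepness, 1/mV
    drive_cap: float | None = 60.0  # saturation of instantaneous drive, mV

    def __post_init__(self) -> None:
        if self.lambda_max <= 0:
            raise ValueError("lambda_max must be positive")
        if self.kernel_tau <= 0:
            raise ValueError("kernel_tau must be positive")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered action-potential event times (s) plus a waveform template tag."""

    times: tuple[float, ...]
    waveform: str = "biexp-1ms-2ms"

    def __post_init__(self) -> None:
        t = self.times
        if any(t2 <= t1 for t1, t2 in zip(t, t[1:])):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def count_in(self, start: float, end: float) -> int:
        a = np.asarray(self.times)
        return int(np.sum((a >= start) & (a < end)))


@dataclass
class AxonParams:
    """Passive-cable constants (published defaults; tau read in ms)."""

    gamma_m: float = 64.1      # membrane resistance, MOhm
    gamma_l: float = 8.0       # longitudinal resistance, MOhm
    gamma_c: float = 1.0       # capacitance, mF/cm^2
    L_N: float = 43.2          # axon length, um
    n_modes: int = 60          # series truncation
    N_N: int = 1               # neurons in the chain
    time_unit: float = 1e-3    # seconds per gamma-product time unit

    def __post_init__(self) -> None:
        for name in ("gamma_m", "gamma_l", "gamma_c", "L_N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_modes < 1 or self.N_N < 1:
            raise ValueError("n_modes and N_N must be >= 1")

    @property
    def tau_m(self) -> float:
        """Membrane leak time constant gamma_m*gamma_c, in seconds."""
        return self.gamma_m * self.gamma_c * self.time_unit

    @property
    def tau_l(self) -> float:
        """Longitudinal constant gamma_l*gamma_c, in s/um^2 when divided by L^2."""
        return self.gamma_l * self.gamma_c * self.time_unit


def membrane_potential(
    fluxes: list[Trace],
    t_on: list[float],
    params: FiringParams,
    grid: TimeGrid,
) -> Trace:
    """Resting potential plus summed linear responses to the Ca2+ fluxes.

    The response kernel is a unit-mass decaying exponential scaled by
    ``kernel_gain``; each astrocyte's flux is zeroed before its onset
    time ``t_on[i]``.  The summed instantaneous drive saturates at
    ``drive_cap`` (finite receptor conductance) before the temporal
    convolution, so a stronger-than-usual calcium wave widens the
    depolarisation plateau but does not deepen it -- the linearity of the
    response holds in the sub-saturation regime.
    """
    if len(fluxes) != len(t_on):
        raise ValueError("need one onset time per flux trace")
    t = grid.times - grid.t0
    kernel = np.exp(-t / params.kernel_tau) / params.kernel_tau
    drive = np.zeros(grid.n_points)
    for flux, ti in zip(fluxes, t_on):
        if flux.grid != grid:
            raise ValueError("flux trace grid does not match run grid")
        x = flux.values.copy()
        x[grid.times < ti] = 0.0
        drive += params.kernel_gain * x
    if params.drive_cap is not None:
        drive = np.minimum(drive, params.drive_cap)
    v = params.V_r + fftconvolve(drive, kernel)[: grid.n_points] * grid.dt
    return Trace(grid, v, units="mV")


def firing_rate(V: Trace, params: FiringParams) -> Trace:
    """Instantaneous firing rate: logistic map of V around the threshold."""
    z = params.rate_slope * (V.values - params.theta1)
    lam = params.lambda_max / (1.0 + np.exp(-np.clip(z, -500, 500)))
    return Trace(V.grid, lam, units="Hz")


def generate_spikes(rate: Trace, rng: RngHandle) -> SpikeTrain:
    """Inhomogeneous Poisson spike sample by thinning against the peak rate."""
    lam = rate.values
    if np.any(lam < 0):
        raise ValueError("rate must be nonnegative")
    lam_max = float(lam.max())
    if lam_max == 0.0:
        return SpikeTrain(())
    g = rng.generator
    grid = rate.grid
    t0, t1 = grid.times[0], grid.times[-1]
    n_cand = g.poisson(lam_max * (t1 - t0))
    cand = np.sort(g.uniform(t0, t1, size=n_cand))
    lam_at = np.interp(cand, grid.times, lam)
    keep = g.uniform(0.0, lam_max, size=n_cand) < lam_at
    times = np.unique(cand[keep])
    return SpikeTrain(tuple(float(x) for x in times))


def _fourier_coefficients(
    V0_profile, params: AxonParams, basis: str = "cosine"
) -> np.ndarray:
    L = params.L_N
    trig = np.cos if basis == "cosine" else np.sin
    zeta = np.empty(params.n_modes)
    for i in range(1, params.n_modes + 1):
        val, _ = quad(
            lambda x, i=i: V0_profile(x) * trig(np.pi * i * x / L), 0.0, L,
            limit=200,
        )
        zeta[i - 1] = 2.0 / L * val
    return zeta


def cable_solution(
    V0_profile,
    params: AxonParams,
    x,
    t,
    include_mean: bool = True,
    basis: str = "cosine",
):
    """Truncated eigenfunction-series solution of the passive cable equation.

    ``V(x,t) = e^(-t/tau_m) * sum_i zeta_i e^(-pi^2 i^2 t / (L^2 tau_l))
    phi_i(x)``; coefficients by quadrature against the initial profile.
    ``x`` in [0, L_N] um, ``t`` in seconds (scalars or arrays, broadcast
    against each other).

    ``basis`` selects the eigenfunctions: the default ``"cosine"``
    (sealed/Neumann ends) or ``"sine"`` (grounded ends, V = 0 at x = 0),
    for initial profiles vanishing at the boundaries.

    For the cosine basis, ``include_mean`` adds the i = 0 (spatially
    constant) mode, ``(1/L) int V0 dx``, which decays only through the
    membrane leak.  A sealed-end cable conserves the mean depolarisation
    apart from the leak, and the finite-difference solution contains this
    mode; without it the series integrates to zero along the cable and
    the terminal response of a one-signed initial bump turns
    nonphysically negative.
    """
    if basis not in ("cosine", "sine"):
        raise ValueError("basis must be 'cosine' or 'sine'")
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(x < 0) or np.any(x > params.L_N):
        raise ValueError("x must lie within [0, L_N]")
    zeta = _fourier_coefficients(V0_profile, params, basis)
    i = np.arange(1, params.n_modes + 1)
    L = params.L_N
    decay = np.exp(
        -np.multiply.outer(t, np.pi**2 * i**2 / (L**2 * params.tau_l))
    )  # (..., n_modes)
    trig = np.cos if basis == "cosine" else np.sin
    spatial = trig(np.multiply.outer(x, np.pi * i / L))  # (..., n_modes)
    series = np.einsum("...i,...i->...", decay, spatial * zeta)
    if include_mean and basis == "cosine":
        mean0, _ = quad(V0_profile, 0.0, L, limit=200)
        series = series + mean0 / L
    return np.exp(-t / params.tau_m) * series


def axonal_delay(
    params: AxonParams, V0_profile=None, t_max: float | None = None
) -> tuple[float, bool]:
    """Time-to-peak of the response magnitude at the axon terminal x = L_N.

    Dense scan plus bounded scalar refinement.  Returns
    ``(delay_s, peaked)``; a profile whose terminal response only decays
    (peak at t = 0) returns 0 with ``peaked=False``.
    """
    if V0_profile is None:
        # localised depolarisation near the soma end
        w = params.L_N / 10.0
        V0_profile = lambda x: np.exp(-(x / w) ** 2)  # noqa: E731
    if t_max is None:
        t_max = 5.0 * params.L_N**2 * params.tau_l / np.pi**2 + 5.0 * params.tau_m

    def mag(t):
        return np.abs(cable_solution(V0_profile, params, params.L_N, t))

    ts = np.linspace(1e-9, t_max, 600)
    vals = mag(ts)
    k = int(np.argmax(vals))
    if k == 0 or vals[k] <= mag(1e-12):
        return 0.0, False
    lo = ts[max(k - 1, 0)]
    hi = ts[min(k + 1, len(ts) - 1)]
    res = minimize_scalar(
        lambda t: -float(mag(t)), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), True


def propagate_spike_train(
    spikes: SpikeTrain, params: AxonParams, delay: float | None = None
) -> SpikeTrain:
    """Shift every spike by the axonal delay; shape and ISIs preserved."""
    if delay is None:
        delay, _ = axonal_delay(params)
    return SpikeTrain(tuple(t + delay for t in spikes.times), spikes.waveform)
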