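"""Passive-diffusion hormone channel.

The transmitter releases bursts of hormone molecules that spread by free
3-D Brownian diffusion and degrade with a first-order rate ``iota``.  The
per-molecule concentration at distance ``d`` is the heat-kernel Green's
function

    g(d, t) = (4 pi D_H t)^(-3/2) * exp(-d^2 / (4 D_H t)),

and the concentration seen by an astrocyte is the superposition of the
Green's functions of all past release events, each damped by the survival
factor exp(-iota * (t - t_event)).

Slot-wise absorption weights ``u_n`` (release in slot 0, capture in slot
``n``) are integrals of ``g * exp(-iota t)`` over slot windows.  The raw
integral has units of a concentration; it is mapped to a genuine capture
probability through a configurable capture-efficiency constant ``kappa``
(the receptor cross-section the physical description leaves open), with
the whole vector clamped so it sums to at most one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import erf

from .signals import ReleaseSchedule, TimeGrid, Trace

__all__ = [
    "HormoneChannelParams",
    "green_function",
    "concentration_at",
    "absorption_probability",
    "absorption_weights",
    "capture_probabilities",
    "calibrate_capture_efficiency",
    "hormonal_delay",
    "sample_astrocyte_distances",
]

#: diffusion coefficient, um^2/s (4.8 um^2/ms converted once at config load)
DEFAULT_D_H = 4800.0
#: molecular degradation rate, 1/s
DEFAULT_IOTA = 0.2


@dataclass
class HormoneChannelParams:
    """Channel constants and Tx/astrocyte geometry (3-D positions, um)."""

    D_H: float = DEFAULT_D_H
    iota: float = DEFAULT_IOTA
    x_S: tuple[float, float, float] = (0.0, 0.0, 0.0)
    x_A: tuple[tuple[float, float, float], ...] = field(
        default_factory=lambda: ((5.0, 0.0, 0.0),)
    )
    kappa: float | None = None  # capture efficiency; None -> calibrate

    def __post_init__(self) -> None:
        if self.D_H <= 0:
            raise ValueError("D_H must be positive")
        if self.iota < 0:
            raise ValueError("iota must be nonnegative")
        if any(d <= 0 for d in self.distances):
            raise ValueError("astrocytes must sit away from the transmitter")

    @property
    def distances(self) -> np.ndarray:
        """Tx-to-astrocyte distances |x_A - x_S| (um)."""
        xs = np.asarray(self.x_S, dtype=float)
        xa = np.asarray(self.x_A, dtype=float).reshape(-1, 3)
        return np.linalg.norm(xa - xs, axis=1)


def sample_astrocyte_distances(
    n: int, rng: np.random.Generator, low: float = 1.0, high: float = 20.0
) -> np.ndarray:
    """Uniformly random Tx-astrocyte distances in [low, high] um."""
    return rng.uniform(low, high, size=n)


def green_function(d, t, D_H: float = DEFAULT_D_H):
    """Free-space 3-D point-source heat kernel at distance ``d`` and time ``t``.

    Units: um^-3 per released molecule.  ``t`` must be positive; the
    t -> 0+ limit (0 for d > 0) is the caller's responsibility.
    """
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("green_function requires t > 0")
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    return (4.0 * np.pi * D_H * t) ** -1.5 * np.exp(-(d**2) / (4.0 * D_H * t))


def concentration_at(
    schedule: ReleaseSchedule,
    d: float,
    grid: TimeGrid,
    params: HormoneChannelParams,
) -> Trace:
    """Hormone concentration at distance ``d`` for a release schedule.

    Superposition of per-event Green's functions with first-order
    degradation; identically zero before the first event (memory effect:
    tails of earlier slots persist into later ones).
    """
    if d <= 0:
        raise ValueError("d must be positive")
    t = grid.times
    out = np.zeros_like(t)
    for t_e, q in schedule.events:
        tau = t - t_e
        live = tau > 0
        out[live] += (
            q
            * green_function(d, tau[live], params.D_H)
            * np.exp(-params.iota * tau[live])
        )
    return Trace(grid, out, units="molecules um^-3")


def _raw_slot_integral(n: int, T: float, d: float, params: HormoneChannelParams) -> float:
    """Integral of g(d,t) exp(-iota t) over the n-th slot window (um^-3 * s)."""

    def integrand(t: float) -> float:
        return float(green_function(d, t, params.D_H)) * np.exp(-params.iota * t)

    lo = n * T
    hi = (n + 1) * T
    breaks = [lo if lo > 0 else 1e-12, hi]
    t_peak = d * d / (6.0 * params.D_H)  # mode of g(d, .)
    if breaks[0] < t_peak < hi:
        breaks.insert(1, t_peak)
    val = err = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        v, e = integrate.quad(
            integrand, a, b, limit=500, epsabs=1e-16, epsrel=1e-11
        )
        val += v
        err += e
    if not np.isfinite(val) or (val > 0 and err > 1e-8 * val + 1e-15):
        raise RuntimeError(
            f"slot-absorption quadrature did not converge: value={val}, abserr={err}"
        )
    return val


def absorption_probability(
    n: int, T: float, d: float, params: HormoneChannelParams, Q0: float = 1.0
) -> float:
    """Capture probability ``u_n``: released in slot 0, absorbed in slot ``n``.

    ``kappa``-scaled, Q0-aware map of the raw slot integral:
    ``u_n = 1 - exp(-Q0 * kappa * raw_n)``, so more released molecules
    mean more reliable capture while the value stays a probability.
    """
    if n < 0:
        raise ValueError("slot offset must be nonnegative")
    kappa = params.kappa
    if kappa is None:
        kappa = calibrate_capture_efficiency(params)
    raw = _raw_slot_integral(n, T, d, params)
    return float(1.0 - np.exp(-Q0 * kappa * raw))


def absorption_weights(
    Nb: int, T: float, d: float, params: HormoneChannelParams, Q0: float = 1.0
) -> np.ndarray:
    """Vector ``u_0..u_{Nb-1}`` of slot-capture probabilities, sum clamped to 1."""
    u = np.array(
        [absorption_probability(n, T, d, params, Q0=Q0) for n in range(Nb)]
    )
    s = u.sum()
    if s > 1.0:
        u = u / s
    return u


# alias matching the channel-probability layer's vocabulary
capture_probabilities = absorption_weights


def calibrate_capture_efficiency(
    params: HormoneChannelParams,
    d_ref: float = 5.0,
    T_ref: float = 10.0,
    Q0_ref: float = 5000.0,
    u0_target: float = 0.5,
) -> float:
    """Capture efficiency ``kappa`` giving ``u_0 = u0_target`` at a reference
    geometry (d = 5 um, T = 10 s, Q0 = 5000 molecules by default)."""
    raw0 = _raw_slot_integral(0, T_ref, d_ref, params)
    return float(-np.log1p(-u0_target) / (Q0_ref * raw0))


def _delay_density(omega, d: float, D_H: float):
    """Unnormalised first-passage-style delay weight on (0, T]."""
    omega = np.asarray(omega, dtype=float)
    return erf(np.sqrt(d * d / (4.0 * D_H * omega))) / np.sqrt(
        8.0 * np.pi * D_H * omega
    )


def hormonal_delay(
    d: float, T: float, D_H: float = DEFAULT_D_H, n_grid: int = 4001
) -> float:
    """Mean hormonal propagation delay Omega_H (seconds).

    The error-function delay weight is normalised to a density on (0, T]
    and its mean is returned.  Increases with distance (slower build-up of
    concentration) and with slot length (a fixed molecule budget spread
    over a longer slot).
    """
    if d <= 0 or T <= 0:
        raise ValueError("d and T must be positive")
    # substitute s = sqrt(omega): the omega^(-1/2) spike at 0 becomes a
    # bounded smooth integrand, so plain trapezoid converges fast
    a = d / (2.0 * np.sqrt(D_H))
    s = np.linspace(0.0, np.sqrt(T), n_grid)
    with np.errstate(divide="ignore"):
        e = erf(np.divide(a, s, out=np.full_like(s, np.inf), where=s > 0))
    e[0] = 1.0
    num = np.trapezoid(s * s * e, s)  # ~ int omega f domega (constants cancel)
    den = np.trapezoid(e, s)
    return float(num / den)
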