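"""Presynaptic vesicle release, neurotransmitter queueing, postsynaptic waveform.

Vesicles sit in a readily releasable pool (RRP, near the membrane) backed
by a reserve pool (RP) that refills vacancies with time constant
``tau_f``.  Each arriving action potential fuses at most one vesicle; the
chance that some vesicle fuses grows with the instantaneous RRP
occupancy ``n`` as ``1 - (1 - p_v)^n``, so a large, quickly refilled pool
releases reliably while a depleted one misses spikes.

Released neurotransmitter batches queue at the postsynaptic receptors,
modelled as an Mx/G/1/K system: compound-Poisson batch arrivals
(exponential inter-arrival, geometric batch sizes), a single server with
a general service distribution, finite capacity K with (by default)
partial-batch acceptance.  The discrete-event simulator is the normative
implementation and reports Monte-Carlo standard errors.

Each accepted release contributes an alpha-function bump
``G_max (t/t_p) exp(1 - t/t_p)`` to the postsynaptic waveform, scaled by
a Gamma-distributed amplitude jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .signals import RngHandle, TimeGrid, Trace
from .neuron import SpikeTrain

__all__ = [
    "VesiclePoolParams",
    "QueueParams",
    "PostsynapticParams",
    "QueueResult",
    "mean_firing_rate",
    "release_probability",
    "simulate_release",
    "release_error_probs",
    "pool_occupancy_distribution",
    "release_miss_probability",
    "queue_simulate",
    "mm1k_blocking_probability",
    "psp_waveform",
]


@dataclass
class VesiclePoolParams:
    """RRP/RP sizes, refill time constant and per-vesicle release scale."""

    N_RRP: int = 8
    N_RP: int = 60
    tau_f: float = 0.030       # s
    p_v: float = 0.4
    T_ref: float = 0.010       # normalisation window of the release-rate map, s
    tau_recycle: float | None = 0.5   # endocytosis return time, s; None = no recycling

    def __post_init__(self) -> None:
        if self.N_RRP < 1 or self.N_RP < 0:
            raise ValueError("pool sizes out of range")
        if self.tau_f <= 0 or self.T_ref <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_recycle is not None and self.tau_recycle <= 0:
            raise ValueError("tau_recycle must be positive")
        if not 0.0 <= self.p_v <= 1.0:
            raise ValueError("p_v must lie in [0, 1]")


@dataclass
class QueueParams:
    """Mx/G/1/K constants: batch arrivals, one server, finite capacity."""

    sigma: float = 0.5             # geometric batch parameter, mean size 1/sigma
    lambda_b: float = 20.0         # customer arrival intensity (= mu_b * tau_b), 1/s
    K: int = 10                    # receptor capacity (customers in system)
    service_mean: float = 0.01     # mean absorption time 1/mu, s
    service_dist: Literal["deterministic", "exponential", "gamma"] = "exponential"
    gamma_shape: float = 2.0
    partial_batch: bool = True     # accept the fitting head of a blocked batch

    def __post_init__(self) -> None:
        if not 0.0 < self.sigma < 1.0:
            raise ValueError("sigma must lie in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.service_mean <= 0 or self.lambda_b <= 0:
            raise ValueError("rates must be positive")

    @property
    def mu_b(self) -> float:
        """Mean batch size 1/sigma."""
        return 1.0 / self.sigma

    @property
    def tau_b(self) -> float:
        """Batch arrival rate sigma * lambda_b."""
        return self.sigma * self.lambda_b


@dataclass
class PostsynapticParams:
    """Alpha-function amplitude/time-to-peak and Gamma amplitude jitter."""

    G_max: float = 1.0
    t_p: float = 0.0015        # s
    q_shape: float = 16.0
    q_scale: float = 1.0 / 16.0  # mean jitter q_shape*q_scale = 1

    def __post_init__(self) -> None:
        if min(self.G_max, self.t_p, self.q_shape, self.q_scale) <= 0:
            raise ValueError("postsynaptic parameters must be positive")


def mean_firing_rate(rate: Trace, T: float, t_start: float = 0.0) -> float:
    """Slot-average firing rate: (1/T) * integral of lambda(t) (trapezoid)."""
    if T <= 0:
        raise ValueError("T must be positive")
    grid = rate.grid
    i0 = grid.index_of(grid.t0 + t_start)
    i1 = grid.index_of(grid.t0 + t_start + T)
    if i1 <= i0:
        raise ValueError("slot lies outside the grid")
    seg = rate.values[i0 : i1 + 1]
    return float(np.trapezoid(seg, dx=grid.dt) / T)


def release_probability(
    lambda_bar: float, pools: VesiclePoolParams, T: float | None = None
) -> float:
    """Per-vesicle release probability driven by the mean firing rate.

    ``P_rele = 1 - exp(-p_v * lambda_bar * T_ref / N_RRP)``, clamped to
    [0, 1]; for a small exponent this reduces to the linear relation
    ``p_v * lambda_bar * T_ref / N_RRP``.
    """
    if lambda_bar < 0:
        raise ValueError("lambda_bar must be nonnegative")
    z = pools.p_v * lambda_bar * pools.T_ref / pools.N_RRP
    return float(min(1.0, -np.expm1(-z)))


def simulate_release(
    spikes: SpikeTrain, pools: VesiclePoolParams, rng: RngHandle
) -> tuple[list[float], np.ndarray]:
    """Stochastic vesicle release along a spike train.

    Each spike releases one vesicle with probability
    ``1 - (1 - p_v)^n`` (n = current RRP occupancy); vacancies refill
    from the RP as a Poisson process with per-vacancy rate ``1/tau_f``
    while the RP lasts.  With ``tau_recycle`` set (the default),
    released vesicles are recycled back into the RP after an exponential
    endocytosis delay, so sustained firing does not exhaust the terminal;
    ``tau_recycle=None`` gives the strict finite-budget semantics.
    Vesicle number is conserved exactly either way:
    RRP + RP + in-transit recycling + lost-forever = N_RRP + N_RP.

    Returns the release times and the pool occupancy history as an
    array of rows ``(time, RRP, RP)``.
    """
    import heapq

    g = rng.generator
    n_rrp = pools.N_RRP
    n_rp = pools.N_RP
    t_now = spikes.times[0] if len(spikes) else 0.0
    releases: list[float] = []
    recycle_heap: list[float] = []   # completion times of vesicles in transit
    occupancy = [(t_now, n_rrp, n_rp)]

    def advance(t_target: float, n_rrp: int, n_rp: int, t_now: float):
        # interleave recycle completions and vacancy-proportional refills
        while True:
            t_rec = recycle_heap[0] if recycle_heap else np.inf
            if n_rp > 0 and n_rrp < pools.N_RRP:
                vac = pools.N_RRP - n_rrp
                t_ref = t_now + g.exponential(pools.tau_f / vac)
            else:
                t_ref = np.inf
            t_next = min(t_rec, t_ref)
            if t_next > t_target:
                break
            t_now = t_next
            if t_rec <= t_ref:
                heapq.heappop(recycle_heap)
                n_rp += 1
            else:
                n_rrp += 1
                n_rp -= 1
            occupancy.append((t_now, n_rrp, n_rp))
        return n_rrp, n_rp

    for t_spike in spikes.times:
        n_rrp, n_rp = advance(t_spike, n_rrp, n_rp, t_now)
        t_now = t_spike
        p_release = -np.expm1(n_rrp * np.log1p(-pools.p_v)) if n_rrp else 0.0
        if n_rrp > 0 and g.random() < p_release:
            n_rrp -= 1
            releases.append(t_spike)
            if pools.tau_recycle is not None:
                heapq.heappush(
                    recycle_heap, t_spike + g.exponential(pools.tau_recycle)
                )
        occupancy.append((t_now, n_rrp, n_rp))
    return releases, np.asarray(occupancy, dtype=float)


def release_error_probs(k_i: int, P_rele: float) -> tuple[float, float]:
    """Release-stage bit-error probabilities for a slot with ``k_i`` spikes.

    A "1" survives only if every spike releases: ``Pe1(1) = 1 - P^k``;
    a "0" is corrupted when all would-be releases occur: ``Pe1(0) = P^k``.
    ``k_i = 0`` is a degenerate upstream miss and is rejected here.
    """
    if k_i < 0:
        raise ValueError("spike count must be nonnegative")
    if not 0.0 <= P_rele <= 1.0:
        raise ValueError("P_rele must lie in [0, 1]")
    if k_i == 0:
        raise ValueError("k_i = 0 is an upstream miss, not a release error")
    pk = P_rele**k_i
    return float(1.0 - pk), float(pk)


def pool_occupancy_distribution(
    lambda_bar: float, pools: VesiclePoolParams
) -> np.ndarray:
    """Stationary RRP occupancy distribution of the birth-death pool model.

    Spikes arrive at rate ``lambda_bar`` and consume a vesicle with
    probability ``1 - (1-p_v)^n``; vacancies refill at rate
    ``(N_RRP - n)/tau_f`` (RP assumed ample).  Solved exactly by
    detailed balance on the n = 0..N_RRP chain.
    """
    N = pools.N_RRP
    pi = np.zeros(N + 1)
    pi[0] = 1.0
    for n in range(N):
        up = (N - n) / pools.tau_f
        down = lambda_bar * -np.expm1((n + 1) * np.log1p(-pools.p_v))
        pi[n + 1] = pi[n] * up / down if down > 0 else np.inf
    if not np.all(np.isfinite(pi)):  # p_v == 0: chain drifts to full pool
        pi = np.zeros(N + 1)
        pi[N] = 1.0
        return pi
    return pi / pi.sum()


def release_miss_probability(
    lambda_bar: float, pools: VesiclePoolParams
) -> float:
    """Per-spike probability that no vesicle fuses, under the stationary pool.

    Falls with larger RRP and faster refill (shorter tau_f); rises with
    the firing rate through pool depletion.
    """
    pi = pool_occupancy_distribution(lambda_bar, pools)
    n = np.arange(pools.N_RRP + 1)
    miss_given_n = np.exp(n * np.log1p(-pools.p_v)) if pools.p_v < 1 else (n == 0).astype(float)
    return float(np.sum(pi * miss_given_n))


@dataclass
class QueueResult:
    """Mx/G/1/K simulation summary (customer-average statistics)."""

    P_blo: float
    P_blo_se: float
    mean_wait: float           # omega, s
    mean_wait_se: float
    arrived: int
    served: int
    blocked: int
    in_system_at_end: int
    mean_number_waiting: float
    effective_arrival_rate: float
    congested: bool = False    # capacity reached > 99% of the time


def _service_sampler(params: QueueParams, g: np.random.Generator):
    m = params.service_mean
    if params.service_dist == "deterministic":
        return lambda size: np.full(size, m)
    if params.service_dist == "exponential":
        return lambda size: g.exponential(m, size)
    if params.service_dist == "gamma":
        k = params.gamma_shape
        return lambda size: g.gamma(k, m / k, size)
    raise ValueError(f"unknown service distribution {params.service_dist!r}")


def queue_simulate(
    params: QueueParams,
    horizon: float | None = None,
    rng: RngHandle | None = None,
    min_arrivals: int = 10_000,
    batch_size_override: int | None = None,
) -> QueueResult:
    """Discrete-event simulation of the Mx/G/1/K receptor queue.

    Batches arrive after Exp(sigma*lambda_b) gaps with Geometric(sigma)
    sizes (``batch_size_override`` forces a fixed size, e.g. 1 for the
    M/G/1/K special case).  The horizon auto-extends until at least
    ``min_arrivals`` customers arrived.  Waiting time is time-in-queue of
    served customers; blocking is the customer-average loss fraction.
    """
    if rng is None:
        rng = RngHandle(0, "queue")
    g = rng.generator
    draw_service = _service_sampler(params, g)
    rate_batches = params.tau_b

    if horizon is None:
        horizon = max(min_arrivals / params.lambda_b, 1.0)

    from collections import deque

    while True:
        t = 0.0
        queue: deque[float] = deque()  # arrival times of waiting customers
        server_free_at = 0.0
        in_service = 0
        arrived = completed = blocked = 0
        waits: list[float] = []
        area_waiting = 0.0             # time-integral of queue length
        area_full = 0.0
        t_prev = 0.0
        while t < horizon or arrived < min_arrivals:
            t += g.exponential(1.0 / rate_batches)
            if t > horizon and arrived >= min_arrivals:
                break
            # advance the clock to t, completing services on the way
            while in_service and server_free_at <= t:
                tc = server_free_at
                area_waiting += len(queue) * (tc - t_prev)
                if in_service + len(queue) >= params.K:
                    area_full += tc - t_prev
                t_prev = tc
                in_service = 0
                completed += 1
                if queue:
                    a = queue.popleft()
                    waits.append(tc - a)
                    in_service = 1
                    server_free_at = tc + float(draw_service(1)[0])
            area_waiting += len(queue) * (t - t_prev)
            if in_service + len(queue) >= params.K:
                area_full += t - t_prev
            t_prev = t
            if batch_size_override is not None:
                b = batch_size_override
            else:
                b = int(g.geometric(params.sigma))
            arrived += b
            n_sys = in_service + len(queue)
            room = params.K - n_sys
            if room <= 0:
                blocked += b
                continue
            accept = min(b, room) if params.partial_batch else (b if b <= room else 0)
            blocked += b - accept
            for _ in range(accept):
                if not in_service:
                    waits.append(0.0)
                    in_service = 1
                    server_free_at = t + float(draw_service(1)[0])
                else:
                    queue.append(t)
        if arrived >= min_arrivals:
            break
        horizon *= 2

    waits_a = np.asarray(waits)
    p_blo = blocked / arrived if arrived else 0.0
    p_se = np.sqrt(p_blo * (1 - p_blo) / arrived) if arrived else 0.0
    w_mean = float(waits_a.mean()) if waits_a.size else 0.0
    w_se = float(waits_a.std(ddof=1) / np.sqrt(waits_a.size)) if waits_a.size > 1 else 0.0
    return QueueResult(
        P_blo=float(p_blo),
        P_blo_se=float(p_se),
        mean_wait=w_mean,
        mean_wait_se=w_se,
        arrived=arrived,
        served=completed,
        blocked=blocked,
        in_system_at_end=in_service + len(queue),
        mean_number_waiting=float(area_waiting / max(t_prev, 1e-12)),
        effective_arrival_rate=float((arrived - blocked) / max(t_prev, 1e-12)),
        congested=bool(area_full / max(t_prev, 1e-12) > 0.99),
    )


def mm1k_blocking_probability(rho: float, K: int) -> float:
    """Closed-form M/M/1/K loss probability (oracle for unit batches)."""
    if rho == 1.0:
        return 1.0 / (K + 1)
    return float(rho**K * (1 - rho) / (1 - rho ** (K + 1)))


def alpha_function(t, params: PostsynapticParams):
    """Canonical postsynaptic bump: peaks at G_max when t = t_p; 0 for t < 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = params.G_max * (t[pos] / params.t_p) * np.exp(1.0 - t[pos] / params.t_p)
    return out


def psp_waveform(
    release_times: list[float],
    params: PostsynapticParams,
    grid: TimeGrid,
    rng: RngHandle | None = None,
    jitter: bool = True,
) -> Trace:
    """Superposed jittered alpha functions at the release times."""
    y = np.zeros(grid.n_points)
    t = grid.times
    if jitter:
        if rng is None:
            raise ValueError("jittered waveform needs an RNG")
        q = rng.generator.gamma(params.q_shape, params.q_scale, len(release_times))
    else:
        q = np.ones(len(release_times))
    # each bump only touches ~12 t_p of grid; add on its local support
    half = int(np.ceil(12.0 * params.t_p / grid.dt))
    for qj, tj in zip(q, release_times):
        i0 = max(grid.index_of(tj) - 1, 0)
        i1 = min(i0 + half, grid.n_points)
        y[i0:i1] += qj * alpha_function(t[i0:i1] - tj, params)
    return Trace(grid, y, units=f"x{params.G_max}")
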