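"""Receiver: waveform sampling, spike re-estimation, Poissonness test, decoding.

The receiver samples the postsynaptic waveform at interval ``tau_s``,
declares spikes where a short windowed mean of the samples exceeds the
amplitude threshold ``theta2``, and then decides each slot's bit from
the estimated train: bit "1" requires (a) the inter-spike intervals to
be consistent with a Poisson process (one-sample KS test against the
exponential law at the MLE rate ``lambda' = count/T``) and (b)
``lambda' >= theta3``.

The KS test uses the conventional sqrt(n)-scaled statistic against the
Kolmogorov critical value; because the rate is estimated from the same
data the test is conservative (Lilliefors effect) and under-rejects at
nominal level alpha.  A literal index-scaled variant (statistic
multiplied by the slot index) is available behind ``literal_index``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import find_peaks

from .neuron import SpikeTrain
from .signals import Trace

__all__ = [
    "DecoderParams",
    "SlotDecision",
    "sample_waveform",
    "detect_spikes",
    "ks_poisson_test",
    "decode_bit",
    "decode_slots",
    "decode_error_probs",
]


@dataclass
class DecoderParams:
    """Sampling, detection and decision constants."""

    tau_s: float = 0.001       # sampling interval, s
    N_sam: int = 4             # samples per waveform window (even)
    theta2: float = 0.2        # spike-presence amplitude threshold
    theta3: float = 10.0       # rate threshold, Hz
    alpha: float = 0.01        # KS significance level
    slot_offset: float = 0.0   # receiver slot synchronisation offset, s
    invert_threshold: bool = False   # literal low-mean => spike reading
    literal_index: bool = False      # literal slot-index KS scaling

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.N_sam < 2 or self.N_sam % 2:
            raise ValueError("N_sam must be a positive even count")
        if self.theta3 < 0:
            raise ValueError("theta3 must be nonnegative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SlotDecision:
    """Per-slot decoder diagnostics."""

    bit: int
    lambda_mle: float
    ks_statistic: float
    poisson_pass: bool
    n_spikes: int
    vacuous: bool = False      # fewer than 2 spikes: test passes by default


def sample_waveform(y: Trace, params: DecoderParams) -> tuple[np.ndarray, np.ndarray]:
    """Sample the waveform at multiples of tau_s (nearest-grid reading).

    Returns ``(sample_times, sample_values)``.
    """
    grid = y.grid
    if params.tau_s < grid.dt:
        raise ValueError("tau_s must be at least the grid step")
    n_samples = int(np.floor(grid.duration / params.tau_s)) + 1
    t_s = grid.t0 + params.tau_s * np.arange(n_samples)
    idx = np.clip(
        np.round((t_s - grid.t0) / grid.dt).astype(int), 0, grid.n_points - 1
    )
    return t_s, y.values[idx]


def detect_spikes(
    sample_times: np.ndarray,
    samples: np.ndarray,
    params: DecoderParams,
) -> SpikeTrain:
    """Estimate spike times from windowed means of the sampled waveform.

    A window of ``N_sam`` samples (N_sam/2 each side) is averaged; a
    spike is declared at local maxima of the windowed mean exceeding
    ``theta2``, at least tau_s apart.
    """
    if samples.size == 0:
        return SpikeTrain(())
    w = params.N_sam + 1
    kernel = np.ones(w) / w
    smooth = np.convolve(samples, kernel, mode="same")
    sig = -smooth if params.invert_threshold else smooth
    thr = -params.theta2 if params.invert_threshold else params.theta2
    peaks, _ = find_peaks(sig, height=thr, distance=max(1, params.N_sam // 2))
    times = np.unique(sample_times[peaks])
    return SpikeTrain(tuple(float(t) for t in times))


def ks_poisson_test(
    estimated: SpikeTrain,
    slot: tuple[float, float],
    alpha: float,
    slot_index: int = 1,
    literal_index: bool = False,
) -> tuple[float, bool, float, bool]:
    """KS Poissonness check and MLE rate for one slot.

    Returns ``(statistic, passes, lambda_mle, vacuous)``.  ``passes``
    means Poissonness is *not rejected*: scaled statistic below the
    Kolmogorov critical value at level ``alpha``.
    """
    start, T = slot
    if T <= 0:
        raise ValueError("slot length must be positive")
    times = np.asarray([t for t in estimated.times if start <= t < start + T])
    lam = times.size / T
    if times.size < 2:
        return 0.0, True, float(lam), True
    isis = np.diff(times)
    res = stats.kstest(isis, "expon", args=(0.0, 1.0 / lam))
    stat = float(res.statistic)
    k_alpha = stats.kstwobign.ppf(1.0 - alpha)
    scale = slot_index if literal_index else np.sqrt(isis.size)
    passes = bool(scale * stat <= k_alpha)
    return stat, passes, float(lam), False


def decode_bit(
    estimated: SpikeTrain,
    slot: tuple[float, float],
    params: DecoderParams,
    slot_index: int = 1,
) -> SlotDecision:
    """Slot decision: 1 iff Poissonness passes and lambda' >= theta3."""
    stat, passes, lam, vacuous = ks_poisson_test(
        estimated, slot, params.alpha, slot_index, params.literal_index
    )
    bit = int(passes and lam >= params.theta3)
    n = estimated.count_in(slot[0], slot[0] + slot[1])
    return SlotDecision(bit, lam, stat, passes, n, vacuous)


def decode_error_probs(
    lambda_1: float,
    lambda_0: float,
    T: float,
    pools,
    psp_params,
    params: DecoderParams,
    n_reps: int,
    rng,
    dt: float = 0.001,
) -> dict[str, float]:
    """Monte-Carlo decode-error probabilities over synapse + receiver.

    Simulates ``n_reps`` single slots each way: spikes at rate
    ``lambda_1`` (sent "1") or ``lambda_0`` (sent "0"), vesicle release,
    jittered postsynaptic waveform, sampling, spike re-estimation and
    the slot decision.  Returns ``Pe2_bit0 = P(decode 1 | sent 0)`` and
    ``Pe2_bit1 = P(decode 0 | sent 1)`` with binomial standard errors.
    """
    from .signals import TimeGrid
    from .synapse import psp_waveform, simulate_release

    if n_reps < 100:
        raise ValueError("need at least 100 replicates")
    # pad the grid so late-slot alpha bumps are representable
    grid = TimeGrid(0.0, T + 10 * psp_params.t_p + dt, dt)
    errors = {1: 0, 0: 0}
    for sent, lam in ((1, lambda_1), (0, lambda_0)):
        for rep in range(n_reps):
            sub = rng.stream(f"pe2/{sent}/{rep}")
            g = sub.generator
            n = g.poisson(lam * T)
            times = np.sort(g.uniform(0.0, T, size=n))
            train = SpikeTrain(tuple(np.unique(times)))
            releases, _ = simulate_release(train, pools, sub.stream("release"))
            y = psp_waveform(releases, psp_params, grid, sub.stream("amp"))
            t_s, samples = sample_waveform(y, params)
            est = detect_spikes(t_s, samples, params)
            decision = decode_bit(est, (0.0, T), params)
            if decision.bit != sent:
                errors[sent] += 1
    pe0 = errors[0] / n_reps
    pe1 = errors[1] / n_reps
    return {
        "Pe2_bit0": pe0,
        "Pe2_bit0_se": float(np.sqrt(pe0 * (1 - pe0) / n_reps)),
        "Pe2_bit1": pe1,
        "Pe2_bit1_se": float(np.sqrt(pe1 * (1 - pe1) / n_reps)),
    }


def decode_slots(
    estimated: SpikeTrain,
    t0: float,
    T: float,
    n_slots: int,
    params: DecoderParams,
) -> list[SlotDecision]:
    """Decode ``n_slots`` consecutive slots of length T starting at t0.

    Windows are shifted by ``slot_offset`` -- the receiver's clock is
    synchronised to the relay latency of the chain, so each window
    brackets the neural response to its own slot's stimulus.
    """
    off = params.slot_offset
    return [
        decode_bit(estimated, (t0 + off + i * T, T), params, slot_index=i + 1)
        for i in range(n_slots)
    ]
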