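"""End-to-end error probabilities, mutual information, capacity, and delay.

The chain is a Markov relay X -> Y -> Z per slot: X is the transmitted
bit, Y the hormone-relay outcome at the astrocytes, Z the decoded bit.
The X -> Y transitions come from the slot-capture probabilities ``u_n``
of the diffusion channel (with inter-slot memory: molecules released in
earlier slots can be captured later); the Y -> Z transitions combine the
vesicle-release error pair and the decoder error pair.  Mutual
information is in bits (base-2 logs); capacity maximises the per-slot
information over the input probability ``p`` by grid search with local
refinement.

Total transmission delay is the sum of the hormonal diffusion delay, the
calcium relay delay, and per-neuron axonal plus queueing delays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ChannelProbs",
    "DelayReport",
    "neural_bit_error",
    "hormone_relay_probs",
    "binary_entropy",
    "joint_distribution",
    "mutual_information_xy",
    "mutual_information",
    "mutual_information_joint",
    "capacity",
    "slot_error_pairs",
    "build_channel_family",
    "total_delay",
]


@dataclass
class ChannelProbs:
    """Per-slot transition probabilities of the relay chain.

    ``P_y0_x0 = P[Y=0|X=0]`` and ``P_y1_x1 = P[Y=1|X=1]`` describe the
    hormone stage; ``P_z1_y0`` and ``P_z0_y1`` the neural stage.
    """

    p: float
    P_y0_x0: float
    P_y1_x1: float
    P_z1_y0: float
    P_z0_y1: float

    def __post_init__(self) -> None:
        for name in ("p", "P_y0_x0", "P_y1_x1", "P_z1_y0", "P_z0_y1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability")


@dataclass
class DelayReport:
    """Delay components (seconds) and their total."""

    omega_H: float
    omega_Ca: float
    omega_Ax: float
    omega_queue: float
    N_N: int = 1

    def __post_init__(self) -> None:
        for name in ("omega_H", "omega_Ca", "omega_Ax", "omega_queue"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.N_N < 1:
            raise ValueError("N_N must be >= 1")

    @property
    def omega_N(self) -> float:
        """Neural-stage delay: N_N * (queue wait + axonal delay)."""
        return self.N_N * (self.omega_queue + self.omega_Ax)

    @property
    def omega_total(self) -> float:
        return self.omega_H + self.omega_Ca + self.omega_N


def neural_bit_error(
    p: float,
    Pe1_pair: tuple[float, float],
    Pe2_pair: tuple[float, float],
) -> tuple[float, float]:
    """Per-bit neural-stage error probabilities.

    ``Pe1_pair = (Pe1_bit1, Pe1_bit0)`` are the release-stage errors,
    ``Pe2_pair = (Pe2_bit0, Pe2_bit1)`` the decode-stage errors.  The
    combination keeps the printed prior-weighted form, including the
    (1-p) weight on the second term of the "0|1" expression.
    """
    pe1_1, pe1_0 = Pe1_pair
    pe2_0, pe2_1 = Pe2_pair
    for v in (p, pe1_1, pe1_0, pe2_0, pe2_1):
        if not 0.0 <= v <= 1.0:
            raise ValueError("inputs must be probabilities")
    p10 = (1 - p) * pe1_0 * (1 - pe2_1) + (1 - p) * (1 - pe1_0) * pe2_0
    p01 = p * pe1_1 * (1 - pe2_0) + (1 - p) * (1 - pe1_1) * pe2_1
    return float(p10), float(p01)


def hormone_relay_probs(
    p: float, u: np.ndarray, Nb: int
) -> tuple[float, float]:
    """Hormone-relay transitions from the slot-capture vector ``u``.

    ``P(1) = prod_{i=1..Nb-1} (1 - p u_i)`` is the probability of no
    interfering capture from other slots (correct silence); ``Q(1) = 1 -
    (1-u_0) P(1)`` the probability of detecting a transmitted pulse
    either in its own slot or via inter-slot memory.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("u values must be probabilities")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    tail = u[1:Nb]
    P1 = float(np.prod(1.0 - p * tail)) if tail.size else 1.0
    u0 = float(u[0]) if u.size else 0.0
    Q1 = 1.0 - (1.0 - u0) * P1
    return P1, Q1


def binary_entropy(x: float) -> float:
    """Psi(x) = -x log2 x - (1-x) log2 (1-x); 0 log 0 taken as 0."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("argument must lie in [0, 1]")
    out = 0.0
    for v in (x, 1.0 - x):
        if v > 0.0:
            out -= v * np.log2(v)
    return float(out)


def joint_distribution(ch: ChannelProbs) -> np.ndarray:
    """Joint P(X, Y, Z) over the 8 binary outcomes (Markov X -> Y -> Z)."""
    px = np.array([1.0 - ch.p, ch.p])
    py_x = np.array(
        [[ch.P_y0_x0, 1.0 - ch.P_y0_x0], [1.0 - ch.P_y1_x1, ch.P_y1_x1]]
    )  # [x, y]
    pz_y = np.array(
        [[1.0 - ch.P_z1_y0, ch.P_z1_y0], [ch.P_z0_y1, 1.0 - ch.P_z0_y1]]
    )  # [y, z]
    return np.einsum("x,xy,yz->xyz", px, py_x, pz_y)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def mutual_information_xy(ch: ChannelProbs) -> float:
    """I(X;Y) in bits via the binary-entropy expansion."""
    p = ch.p
    py0 = (1 - p) * ch.P_y0_x0 + p * (1 - ch.P_y1_x1)
    return (
        binary_entropy(py0)
        - p * binary_entropy(ch.P_y1_x1)
        - (1 - p) * binary_entropy(ch.P_y0_x0)
    )


def mutual_information(ch: ChannelProbs) -> float:
    """Per-slot I(X;Z) in bits, by the relay decomposition.

    ``I(X;Z) = I(X;Y) - I(X;Y|Z)`` with the conditional term expanded in
    joint entropies: ``I(X;Y|Z) = -H(Y,Z|X) + H(Y,Z) + H(Z|X) - H(Z)``.
    Valid because X and Z are conditionally independent given Y.
    """
    j = joint_distribution(ch)
    px = j.sum(axis=(1, 2))
    pz = j.sum(axis=(0, 1))
    pyz = j.sum(axis=0)
    pxz = j.sum(axis=1)
    h_yz_x = _entropy(j.ravel()) - _entropy(px)
    h_z_x = _entropy(pxz.ravel()) - _entropy(px)
    i_xy_given_z = -h_yz_x + _entropy(pyz.ravel()) + h_z_x - _entropy(pz)
    return mutual_information_xy(ch) - i_xy_given_z


def mutual_information_joint(ch: ChannelProbs) -> float:
    """Independent route: I(X;Z) directly from the (X, Z) marginal joint."""
    pxz = joint_distribution(ch).sum(axis=1)
    px = pxz.sum(axis=1)
    pz = pxz.sum(axis=0)
    return _entropy(px) + _entropy(pz) - _entropy(pxz.ravel())


def capacity(
    channel_family,
    Nb: int = 1,
    n_grid: int = 101,
) -> tuple[float, float]:
    """Channel capacity C = max_p mean-per-slot I(X;Z), and the maximiser.

    ``channel_family(p)`` returns a :class:`ChannelProbs` (or a list of
    them, one per slot).  Grid search over p in [0, 1] followed by a
    bounded scalar refinement around the best grid point.
    """

    def per_slot(p: float) -> float:
        ch = channel_family(p)
        if isinstance(ch, ChannelProbs):
            return mutual_information(ch)
        vals = [mutual_information(c) for c in ch]
        return float(np.sum(vals) / Nb)

    ps = np.linspace(0.0, 1.0, n_grid)
    vals = np.array([per_slot(float(p)) for p in ps])
    k = int(np.argmax(vals))
    lo = ps[max(k - 1, 0)]
    hi = ps[min(k + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda p: -per_slot(p), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    best_p = float(res.x)
    best_c = float(-res.fun)
    if vals[k] > best_c:
        best_p, best_c = float(ps[k]), float(vals[k])
    return best_c, best_p


def slot_error_pairs(
    lambda_bar: float,
    T: float,
    pools,
    lambda_0: float = 1e-3,
    theta3: float | None = None,
    alpha: float = 0.01,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Analytic release- and decode-stage error pairs for one slot.

    A "1" slot drives firing at ``lambda_bar``; a "0" slot only carries
    the spontaneous rate ``lambda_0``.  Release reliability per spike
    comes from the stationary vesicle-pool model; a "1" slot survives
    the release stage only if all its spikes release.  Decode errors
    follow the slot decision rule: a KS false alarm at level ``alpha``
    or an estimated rate on the wrong side of ``theta3`` (Poisson
    counting statistics).

    Returns ``((Pe1_bit1, Pe1_bit0), (Pe2_bit0, Pe2_bit1))``.
    """
    from scipy.stats import poisson

    from .synapse import release_miss_probability

    if theta3 is None:
        theta3 = 0.5 * lambda_bar
    lam1 = lambda_bar
    miss = release_miss_probability(lam1, pools)
    s = 1.0 - miss
    k1 = lam1 * T
    # all-spikes-release survival, Poisson-averaged over the spike count
    pe1_bit1 = float(-np.expm1(k1 * np.log(s))) if s > 0 else 1.0
    # a "0" slot errs when spurious spikes occur and all of them release
    k0 = lambda_0 * T
    pe1_bit0 = float(np.exp(-k0 * (1.0 - s)) - np.exp(-k0))
    # decoder: observed (released) spike counts are Poisson
    n_crit = np.ceil(theta3 * T)
    pe2_bit1 = float(alpha + (1 - alpha) * poisson.cdf(n_crit - 1, lam1 * s * T))
    pe2_bit0 = float((1 - alpha) * poisson.sf(n_crit - 1, lambda_0 * s * T))
    return (pe1_bit1, pe1_bit0), (pe2_bit0, pe2_bit1)


def multi_astrocyte_capture(u: np.ndarray, M_A: int) -> np.ndarray:
    """Slot-capture probabilities with ``M_A`` parallel astrocyte receivers.

    The relay detects a pulse when *any* astrocyte captures it:
    ``u_n -> 1 - (1 - u_n)^M_A``.  More relays raise detection (and,
    slightly, inter-slot interference).
    """
    u = np.asarray(u, dtype=float)
    if M_A < 1:
        raise ValueError("M_A must be >= 1")
    return 1.0 - (1.0 - u) ** M_A


def neural_transition_probs(
    Pe1_pair: tuple[float, float], Pe2_pair: tuple[float, float]
) -> tuple[float, float]:
    """Markov conditionals P(Z=1|Y=0), P(Z=0|Y=1) from the stage error pairs.

    The two stages act in sequence: a bit flips when exactly one of them
    errs.  (These are the prior-free counterparts of the prior-weighted
    per-bit expressions of :func:`neural_bit_error`, which are what the
    relay channel needs for its transition matrix.)
    """
    pe1_1, pe1_0 = Pe1_pair
    pe2_0, pe2_1 = Pe2_pair
    p_z1_y0 = pe1_0 * (1 - pe2_1) + (1 - pe1_0) * pe2_0
    p_z0_y1 = pe1_1 * (1 - pe2_0) + (1 - pe1_1) * pe2_1
    return float(p_z1_y0), float(p_z0_y1)


def build_channel_family(
    u: np.ndarray,
    Nb: int,
    lambda_bar: float,
    T: float,
    pools,
    M_A: int = 3,
    lambda_0: float = 1e-3,
    theta3: float | None = None,
    alpha: float = 0.01,
):
    """Family ``p -> ChannelProbs`` combining all three signalling stages.

    ``u`` is the per-astrocyte slot-capture probability vector of the
    hormone channel; ``M_A`` parallel astrocytes capture independently.
    Fed to :func:`capacity` to maximise the per-slot information over p.
    """
    u_eff = multi_astrocyte_capture(u, M_A)
    pe1, pe2 = slot_error_pairs(
        lambda_bar, T, pools, lambda_0=lambda_0, theta3=theta3, alpha=alpha
    )
    p10, p01 = neural_transition_probs(pe1, pe2)

    def family(p: float) -> ChannelProbs:
        P1, Q1 = hormone_relay_probs(p, u_eff, Nb)
        return ChannelProbs(
            p=p, P_y0_x0=P1, P_y1_x1=Q1, P_z1_y0=p10, P_z0_y1=p01
        )

    return family


def total_delay(
    omega_H: float,
    omega_Ca: float,
    omega_Ax: float,
    omega_queue: float,
    N_N: int = 1,
) -> DelayReport:
    """Assemble the delay report; components must be nonnegative."""
    return DelayReport(omega_H, omega_Ca, omega_Ax, omega_queue, N_N)
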