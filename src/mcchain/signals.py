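"""Shared time-grid and trace types, OOK encoding, and RNG plumbing.

Every stage of the chain operates on one common uniformly sampled time
grid; bit strings are modulated with on-off keying (OOK): a burst of
``Q0`` hormone molecules is released at the start of each slot carrying a
"1", nothing for a "0".  Internal units are seconds, micrometres,
micromolar and millivolts throughout.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "TimeGrid",
    "BitSequence",
    "ReleaseSchedule",
    "Trace",
    "RngHandle",
    "encode_ook",
    "count_waves",
    "random_bits",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid: ``t0``, total ``duration`` and step ``dt`` (seconds)."""

    t0: float
    duration: float
    dt: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValueError("duration must be an integer multiple of dt")

    @property
    def n_points(self) -> int:
        return int(round(self.duration / self.dt)) + 1

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_points)

    def index_of(self, t: float) -> int:
        """Nearest grid index for time ``t`` (clipped to the grid)."""
        i = int(round((t - self.t0) / self.dt))
        return min(max(i, 0), self.n_points - 1)


@dataclass(frozen=True)
class BitSequence:
    """An ordered binary message plus the Bernoulli parameter used to draw it."""

    bits: tuple[int, ...]
    p: float = 0.5

    def __post_init__(self) -> None:
        if len(self.bits) == 0:
            raise ValueError("bit sequence must be nonempty")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0 or 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    @classmethod
    def from_string(cls, s: str, p: float = 0.5) -> "BitSequence":
        if not s or any(c not in "01" for c in s):
            raise ValueError(f"not a binary string: {s!r}")
        return cls(tuple(int(c) for c in s), p)

    def __len__(self) -> int:
        return len(self.bits)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


@dataclass(frozen=True)
class ReleaseSchedule:
    """Timed impulses ``(time s, quantity molecules)`` produced by OOK encoding.

    Dirac impulses are kept as exact events rather than grid spikes so the
    diffusion channel can superpose Green's functions analytically.
    """

    events: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(q <= 0 for _, q in self.events):
            raise ValueError("quantities must be positive")

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled time series on a shared :class:`TimeGrid`."""

    grid: TimeGrid
    values: np.ndarray
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.grid.n_points,):
            raise ValueError(
                f"trace length {v.shape} does not match grid ({self.grid.n_points},)"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("trace contains non-finite values")


def _stream_entropy(label: str) -> int:
    # CRC32 gives a stable cross-session mapping label -> 32-bit word.
    return zlib.crc32(label.encode("utf-8"))


@dataclass
class RngHandle:
    """One root seed spawning labelled, mutually independent streams.

    The same ``(seed, label)`` pair always yields an identical draw
    sequence, giving stage-level reproducibility: e.g. changing the
    decoder's sampling noise never perturbs the firing stage.
    """

    seed: int
    label: str = "root"
    _gen: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ss = np.random.SeedSequence(
            entropy=int(self.seed), spawn_key=(_stream_entropy(self.label),)
        )
        self._gen = np.random.default_rng(ss)

    def stream(self, label: str) -> "RngHandle":
        """Independent generator for a named stage."""
        return RngHandle(self.seed, f"{self.label}/{label}")

    @property
    def generator(self) -> np.random.Generator:
        return self._gen


def encode_ook(bits: BitSequence, Q0: float, T: float) -> ReleaseSchedule:
    """OOK-encode a bit string into a hormone release schedule.

    One impulse of ``Q0`` molecules at ``t = i*T`` for every bit ``i``
    equal to 1; silence for 0-bits.
    """
    if Q0 <= 0:
        raise ValueError("Q0 must be positive")
    if T <= 0:
        raise ValueError("T must be positive")
    events = tuple((i * T, float(Q0)) for i, b in enumerate(bits.bits) if b == 1)
    return ReleaseSchedule(events)


def count_waves(trace: Trace, threshold: float, min_separation: float) -> int:
    """Count local maxima above ``threshold`` separated by >= ``min_separation``.

    Used to check wave/peak counts of concentration traces (e.g. three
    hormone waves for the message "1011" at slot length 10 s).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if min_separation < trace.grid.dt:
        raise ValueError("min_separation must be at least one grid step")
    v = trace.values
    if v.size == 0:
        raise ValueError("empty trace")
    distance = max(1, int(round(min_separation / trace.grid.dt)))
    peaks, _ = find_peaks(v, height=threshold, distance=distance)
    # An above-threshold first/last sample with an interior fall/rise is a
    # wave too (find_peaks ignores endpoints); handle the leading edge which
    # matters for impulse-response traces peaking immediately after release.
    count = len(peaks)
    if v.size >= 2 and v[0] > threshold and v[0] > v[1]:
        if len(peaks) == 0 or peaks[0] >= distance:
            count += 1
    return count


def random_bits(n: int, p: float, rng: RngHandle) -> BitSequence:
    """Draw ``n`` i.i.d. Bernoulli(p) bits, reproducible under the seed."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("need at least one bit")
    draws = rng.generator.random(n) < p
    return BitSequence(tuple(int(b) for b in draws), p)
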