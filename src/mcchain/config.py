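"""Run configuration: one nested, YAML-round-trippable record of every knob.

The default values are the published simulation constants of the chain
model (diffusion coefficient 4.8 um^2/ms, the Li-Rinzel astrocyte set,
the vesicle-pool and cable constants).  Calibrated quantities -- capture
efficiency, IP3 coupling midpoint, decoder thresholds -- are resolved
once at config build time by :func:`resolve_calibrations` so a loaded
config re-runs bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .astrocyte import AstrocyteParams, Ip3Coupling, calibrate_ip3_coupling
from .decoder import DecoderParams
from .hormone import HormoneChannelParams, calibrate_capture_efficiency
from .neuron import AxonParams, FiringParams
from .synapse import PostsynapticParams, QueueParams, VesiclePoolParams

__all__ = ["ChainConfig", "resolve_calibrations"]


@dataclass
class ChainConfig:
    """Everything one end-to-end run needs, grouped per stage."""

    bits: str = "1011"
    p: float = 0.5
    seed: int = 0
    T: float = 10.0            # slot length, s
    dt: float = 0.001          # grid step, s
    Q0: float = 5000.0         # molecules per "1" pulse
    M_A: int = 3               # astrocytes relaying to the neuron
    convention: str = "li_rinzel"
    distance_range: tuple[float, float] = (1.0, 20.0)
    distances: tuple[float, ...] | None = None   # explicit Tx-astrocyte distances
    lambda_0: float = 1e-3     # spontaneous firing rate, Hz

    channel: HormoneChannelParams = field(default_factory=HormoneChannelParams)
    astrocyte: AstrocyteParams = field(default_factory=AstrocyteParams)
    coupling: Ip3Coupling | None = None          # None -> calibrate at load
    firing: FiringParams = field(default_factory=FiringParams)
    axon: AxonParams = field(default_factory=AxonParams)
    pools: VesiclePoolParams = field(default_factory=VesiclePoolParams)
    queue: QueueParams = field(default_factory=QueueParams)
    psp: PostsynapticParams = field(default_factory=PostsynapticParams)
    decoder: DecoderParams = field(
        default_factory=lambda: DecoderParams(slot_offset=2.3)
    )

    def __post_init__(self) -> None:
        if self.T <= 0 or self.dt <= 0:
            raise ValueError("T and dt must be positive")
        if self.M_A < 1:
            raise ValueError("M_A must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    # -- serialisation ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {f.name: enc(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, tuple):
                return [enc(x) for x in v]
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ChainConfig":
        def tup(v):
            if isinstance(v, list):
                return tuple(tup(x) for x in v)
            return v

        kwargs: dict[str, Any] = {}
        sections = {
            "channel": HormoneChannelParams,
            "astrocyte": AstrocyteParams,
            "coupling": Ip3Coupling,
            "firing": FiringParams,
            "axon": AxonParams,
            "pools": VesiclePoolParams,
            "queue": QueueParams,
            "psp": PostsynapticParams,
            "decoder": DecoderParams,
        }
        for k, v in d.items():
            if k in sections:
                kwargs[k] = None if v is None else sections[k](
                    **{kk: tup(vv) for kk, vv in v.items()}
                )
            else:
                kwargs[k] = tup(v)
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ChainConfig":
        return cls.from_dict(yaml.safe_load(text))

    def high_snr(self) -> "ChainConfig":
        """Copy tuned for an essentially noiseless demonstration run.

        Strong drive, near-deterministic release and tight amplitude
        jitter: the regime in which decoding should be error-free.
        """
        cfg = ChainConfig.from_dict(self.to_dict())
        cfg.dt = 0.0005
        cfg.firing = dataclasses.replace(
            self.firing, lambda_max=16.0, kernel_gain=200.0
        )
        cfg.pools = dataclasses.replace(
            self.pools, N_RRP=10, tau_f=0.010, p_v=0.9
        )
        cfg.psp = dataclasses.replace(
            self.psp, t_p=0.001, q_shape=64.0, q_scale=1.0 / 64.0
        )
        cfg.decoder = dataclasses.replace(
            self.decoder, tau_s=0.0005, alpha=0.001, theta3=6.0
        )
        cfg.distances = tuple([5.0] * cfg.M_A)
        return cfg


def resolve_calibrations(cfg: ChainConfig) -> ChainConfig:
    """Fill in calibrated constants (capture efficiency, IP3 coupling).

    The capture efficiency pins u_0 = 0.5 at the reference geometry; the
    IP3 coupling midpoint is pinned to the mid-slot hormone concentration
    of a single pulse at the median astrocyte distance, placing a lone
    "1" inside the oscillatory window.  Idempotent: already-resolved
    values are kept.
    """
    import numpy as np

    from .hormone import concentration_at
    from .signals import BitSequence, TimeGrid, encode_ook

    if cfg.channel.kappa is None:
        cfg.channel.kappa = calibrate_capture_efficiency(cfg.channel)
    if cfg.coupling is None:
        d_med = float(np.median(cfg.distances)) if cfg.distances else 5.0
        grid = TimeGrid(0.0, cfg.T, cfg.dt)
        single = concentration_at(
            encode_ook(BitSequence.from_string("1"), cfg.Q0, cfg.T),
            d_med,
            grid,
            cfg.channel,
        )
        c_mid = float(single.values[grid.index_of(cfg.T / 2)])
        cfg.coupling = calibrate_ip3_coupling(c_mid)
    return cfg
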