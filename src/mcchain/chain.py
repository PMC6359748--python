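"""End-to-end chain runner, parameter sweeps and reporting.

One run executes the full relay: OOK encoding -> hormone diffusion to
each astrocyte -> IP3 transduction -> Ca2+ oscillation -> Ca2+ flux to
the neuron -> membrane potential -> inhomogeneous Poisson firing ->
axonal shift -> vesicle release -> postsynaptic waveform -> sampling,
spike re-estimation and slot decisions.  Everything is deterministic
given the root seed; each stochastic stage draws from its own labelled
stream.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import astrocyte as astro
from . import decoder as dec
from . import hormone as hor
from . import metrics as met
from . import neuron as neu
from . import synapse as syn
from .config import ChainConfig, resolve_calibrations
from .signals import BitSequence, RngHandle, TimeGrid, Trace, count_waves, encode_ook

__all__ = ["ChainResult", "run_chain", "sweep", "capacity_report", "delay_report",
           "make_fixture"]


@dataclass
class ChainResult:
    """Everything one run produced, per stage."""

    config: ChainConfig
    grid: TimeGrid
    bits_sent: str
    bits_decoded: str
    ber: float
    hormone_traces: list[Trace]
    ip3_traces: list[Trace]
    ca_traces: list[Trace]
    flux_traces: list[Trace]
    potential: Trace
    rate: Trace
    spikes: neu.SpikeTrain
    spikes_at_terminal: neu.SpikeTrain
    release_times: list[float]
    psp: Trace
    estimated_spikes: neu.SpikeTrain
    decisions: list[dec.SlotDecision]
    delays: met.DelayReport
    distances: tuple[float, ...]
    timings: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict[str, Any]:
        """JSON-ready run summary (no traces)."""
        return {
            "bits_sent": self.bits_sent,
            "bits_decoded": self.bits_decoded,
            "ber": self.ber,
            "n_spikes": len(self.spikes),
            "n_releases": len(self.release_times),
            "distances_um": list(self.distances),
            "delays_s": {
                "omega_H": self.delays.omega_H,
                "omega_Ca": self.delays.omega_Ca,
                "omega_Ax": self.delays.omega_Ax,
                "omega_queue": self.delays.omega_queue,
                "omega_N": self.delays.omega_N,
                "omega_total": self.delays.omega_total,
            },
            "slots": [
                {
                    "bit": s.bit,
                    "lambda_mle_Hz": s.lambda_mle,
                    "ks_statistic": s.ks_statistic,
                    "poisson_pass": s.poisson_pass,
                    "n_spikes": s.n_spikes,
                }
                for s in self.decisions
            ],
            "seed": self.config.seed,
        }


def _astrocyte_distances(cfg: ChainConfig, rng: RngHandle) -> tuple[float, ...]:
    if cfg.distances is not None:
        if len(cfg.distances) != cfg.M_A:
            raise ValueError("need one distance per astrocyte")
        return tuple(float(d) for d in cfg.distances)
    lo, hi = cfg.distance_range
    d = hor.sample_astrocyte_distances(
        cfg.M_A, rng.stream("positions").generator, lo, hi
    )
    return tuple(float(x) for x in np.sort(d))


def run_chain(cfg: ChainConfig) -> ChainResult:
    """Execute the full relay for ``cfg`` and decode the received bits."""
    cfg = resolve_calibrations(cfg)
    bits = BitSequence.from_string(cfg.bits, cfg.p)
    n_slots = len(bits)
    # pad by the receiver's synchronisation offset so the last decode
    # window is fully inside the simulated horizon
    pad = np.ceil(cfg.decoder.slot_offset / cfg.dt) * cfg.dt
    grid = TimeGrid(0.0, n_slots * cfg.T + pad, cfg.dt)
    rng = RngHandle(cfg.seed)
    timings: dict[str, float] = {}

    def tic(name):
        timings[name] = time.perf_counter()

    def toc(name):
        timings[name] = time.perf_counter() - timings[name]

    distances = _astrocyte_distances(cfg, rng)
    schedule = encode_ook(bits, cfg.Q0, cfg.T)

    tic("hormone")
    hormone_traces = [
        hor.concentration_at(schedule, d, grid, cfg.channel) for d in distances
    ]
    toc("hormone")

    tic("calcium")
    ip3_traces = [astro.hormone_to_ip3(h, cfg.coupling) for h in hormone_traces]
    ca_traces = []
    for ip3 in ip3_traces:
        init = astro.AstrocyteState.resting(
            cfg.astrocyte, C_CY=0.1, C_IP3=cfg.coupling.ip3_base
        )
        ca, _ = astro.simulate_astrocyte(
            ip3, init, cfg.astrocyte, grid, cfg.convention
        )
        ca_traces.append(ca)
    flux_traces = [
        astro.calcium_flux_to_neuron(ca, cfg.astrocyte) for ca in ca_traces
    ]
    toc("calcium")

    tic("firing")
    potential = neu.membrane_potential(
        flux_traces, [0.0] * len(flux_traces), cfg.firing, grid
    )
    rate = neu.firing_rate(potential, cfg.firing)
    spikes = neu.generate_spikes(rate, rng.stream("firing"))
    toc("firing")

    tic("axon")
    omega_ax, _ = neu.axonal_delay(cfg.axon)
    spikes_term = neu.propagate_spike_train(spikes, cfg.axon, delay=omega_ax)
    toc("axon")

    tic("synapse")
    release_times, _pools_hist = syn.simulate_release(
        spikes_term, cfg.pools, rng.stream("release")
    )
    psp = syn.psp_waveform(release_times, cfg.psp, grid, rng.stream("amplitude"))
    toc("synapse")

    tic("decode")
    t_s, samples = dec.sample_waveform(psp, cfg.decoder)
    estimated = dec.detect_spikes(t_s, samples, cfg.decoder)
    decisions = dec.decode_slots(estimated, 0.0, cfg.T, n_slots, cfg.decoder)
    decoded = "".join(str(s.bit) for s in decisions)
    ber = float(np.mean([a != b for a, b in zip(cfg.bits, decoded)]))
    toc("decode")

    tic("delay")
    d_med = float(np.median(distances))
    omega_h = hor.hormonal_delay(d_med, cfg.T, cfg.channel.D_H)
    neuron_absorbed = Trace(
        grid,
        cfg.astrocyte.ca_capture_fraction
        * np.sum([f.values for f in flux_traces], axis=0),
        units="uM",
    )
    omega_ca, _reached = astro.calcium_delay(ca_traces, neuron_absorbed, cfg.T)
    qres = syn.queue_simulate(
        cfg.queue, rng=rng.stream("queue"), min_arrivals=10_000
    )
    delays = met.total_delay(
        omega_h, omega_ca, omega_ax, qres.mean_wait, cfg.axon.N_N
    )
    toc("delay")

    return ChainResult(
        config=cfg,
        grid=grid,
        bits_sent=cfg.bits,
        bits_decoded=decoded,
        ber=ber,
        hormone_traces=hormone_traces,
        ip3_traces=ip3_traces,
        ca_traces=ca_traces,
        flux_traces=flux_traces,
        potential=potential,
        rate=rate,
        spikes=spikes,
        spikes_at_terminal=spikes_term,
        release_times=release_times,
        psp=psp,
        estimated_spikes=estimated,
        decisions=decisions,
        delays=delays,
        distances=distances,
        timings=timings,
    )


def _set_by_path(cfg: ChainConfig, path: str, value) -> None:
    """Assign ``value`` at a dotted config path like ``pools.N_RRP``."""
    parts = path.split(".")
    obj = cfg
    for part in parts[:-1]:
        if not hasattr(obj, part):
            raise KeyError(f"unknown config path: {path}")
        obj = getattr(obj, part)
    if not hasattr(obj, parts[-1]):
        raise KeyError(f"unknown config path: {path}")
    setattr(obj, parts[-1], value)


def sweep(
    cfg: ChainConfig,
    grid_spec: dict[str, list],
    metric: str = "ber",
    per_point_seeds: bool = False,
) -> pd.DataFrame:
    """One full chain run per grid point; long-format results table.

    ``grid_spec`` maps dotted config paths to value lists; the Cartesian
    product is enumerated.  The seed policy is fixed-seed by default
    (control-variate style: one random stream shared across points).
    """
    import itertools

    names = list(grid_spec)
    if not names or any(len(v) == 0 for v in grid_spec.values()):
        return pd.DataFrame(columns=[*names, "ber", "n_spikes", "omega_total"])
    # validate every path before any (possibly slow) run
    probe = ChainConfig.from_dict(cfg.to_dict())
    for name in names:
        _set_by_path(probe, name, grid_spec[name][0])
    rows = []
    for k, combo in enumerate(itertools.product(*grid_spec.values())):
        point = ChainConfig.from_dict(cfg.to_dict())
        for name, value in zip(names, combo):
            _set_by_path(point, name, value)
        if per_point_seeds:
            point.seed = cfg.seed + 1 + k
        res = run_chain(point)
        row = dict(zip(names, combo))
        row["ber"] = res.ber
        row["n_spikes"] = len(res.spikes)
        row["omega_total"] = res.delays.omega_total
        rows.append(row)
    df = pd.DataFrame(rows)
    if metric not in df.columns:
        raise KeyError(f"unknown metric {metric!r}")
    return df


def capacity_report(
    cfg: ChainConfig,
    T: float = 1.0,
    Nb: int = 8,
    d: float | None = None,
    Q0: float | None = None,
    lambda_bar: float = 20.0,
    M_A: int | None = None,
) -> dict[str, float]:
    """Analytic channel capacity for the configured physical constants.

    Slot length defaults to 1 s for capacity work (the informative
    regime of the release-error model); the chain's reference-scenario runs
    keep their own T.
    """
    cfg = resolve_calibrations(cfg)
    d = d if d is not None else 5.0
    Q0 = Q0 if Q0 is not None else cfg.Q0
    M_A = M_A if M_A is not None else cfg.M_A
    u = hor.absorption_weights(Nb, T, d, cfg.channel, Q0=Q0)
    family = met.build_channel_family(
        u, Nb, lambda_bar, T, cfg.pools, M_A=M_A, lambda_0=cfg.lambda_0,
        alpha=cfg.decoder.alpha,
    )
    C, p_star = met.capacity(family, Nb=1)
    return {"capacity_bits": C, "argmax_p": p_star, "T": T, "Nb": Nb,
            "lambda_bar": lambda_bar, "Q0": Q0, "M_A": M_A, "d": d}


def capacity_sweep(
    cfg: ChainConfig, parameter: str, values: list, **kw
) -> pd.DataFrame:
    """Capacity at each value of one named parameter (long format)."""
    rows = []
    for v in values:
        rep = capacity_report(cfg, **{**kw, parameter: v})
        rep[parameter] = v
        rows.append(rep)
    return pd.DataFrame(rows)


def delay_report(cfg: ChainConfig, result: ChainResult | None = None) -> dict:
    """Delay components for a config (running the chain if needed)."""
    if result is None:
        result = run_chain(cfg)
    d = result.delays
    return {
        "omega_H_s": d.omega_H,
        "omega_Ca_s": d.omega_Ca,
        "omega_Ax_s": d.omega_Ax,
        "omega_queue_s": d.omega_queue,
        "omega_N_s": d.omega_N,
        "omega_total_s": d.omega_total,
    }


_FIXTURES = {
    "message_1011": dict(bits="1011", waves_expected=3),
    "message_1111": dict(bits="1111", waves_expected=4),
    "queue_mm1k": dict(),
    "poisson_null": dict(),
}


def make_fixture(name: str, seed: int = 0) -> dict[str, Any]:
    """Bundled config + expected-property manifest for a named scenario."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    if name.startswith("message"):
        info = _FIXTURES[name]
        cfg = ChainConfig(bits=info["bits"], T=10.0, seed=seed,
                          distances=(5.0, 5.0, 5.0))
        return {
            "name": name,
            "config": cfg.to_dict(),
            "expect": {
                "hormone_waves": info["waves_expected"],
                "ca_peaks": info["waves_expected"],
            },
        }
    if name == "queue_mm1k":
        qp = syn.QueueParams(sigma=0.5, lambda_b=100.0, K=5, service_mean=0.01)
        rho = qp.tau_b * qp.service_mean
        return {
            "name": name,
            "queue": dataclasses.asdict(qp),
            "batch_size_override": 1,
            "seed": seed,
            "expect": {"P_blo": syn.mm1k_blocking_probability(rho, qp.K)},
        }
    return {
        "name": name,
        "rate_Hz": 20.0,
        "T": 10.0,
        "seed": seed,
        "expect": {"rejection_fraction_at_most": "alpha (conservative)"},
    }


def export_trace(trace: Trace, path: str, label: str = "value") -> None:
    """Two-column delimited text with a units header line."""
    header = f"time_s\t{label}_{trace.units.replace(' ', '_')}"
    np.savetxt(
        path,
        np.column_stack([trace.grid.times, trace.values]),
        delimiter="\t",
        header=header,
        comments="",
    )


def export_summary(result: ChainResult, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(result.summary(), fh, indent=2)
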