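"""Physiologically structured ABP/NIRS signal simulator.

Real recordings for this pipeline come from a finger-cuff niABP monitor
(100 Hz) and a multi-channel fNIRS device (250 Hz).  The simulator
replaces the hardware with a sinusoid-plus-noise model whose ground
truth is known, so every downstream stage — alignment, scalp
subtraction, decimation, sliding correlation, mapping — is testable.

Model
-----
niABP is a mean pressure plus sinusoidal components with seed-derived
random phases: cardiac (~1.1 Hz), respiratory (~0.25 Hz), Mayer
(~0.1 Hz) and slow vasogenic waves (0.005-0.05 Hz, the band carrying
cerebral-autoregulation information), plus white sensor noise.

Each NIRS channel mixes three parts:

* a *cerebral* part governed by the channel's ``reactivity_coupling``
  rho in [-1, +1]: ``rho`` times the (normalized, noiseless) ABP
  oscillation plus ``(1 - |rho|)`` times an independent slow-band
  process.  ``rho = +1`` is fully pressure-passive vasculature (the
  pressure waveform transmits into blood volume, so downstream
  correlation indices recover +1 by construction); ``rho = 0`` is
  perfectly decoupled (intact autoregulation); negative values give
  counter-regulation.
* a *scalp* part — the same realized waveform in the normal and the
  short reference channel of a given chromophore, scaled by
  ``scalp_fraction`` — which unit-gain short-channel subtraction
  cancels exactly.
* white sensor noise, independent per trace.

The NIRS stream's content is advanced by ``nirs_delay_true`` seconds
relative to the niABP stream, emulating the measured inter-device lag
(3.24 s mean) that the pipeline later corrects with its fixed 3.22 s
shift, leaving a small known residual.

Hemoglobin units are arbitrary concentration units: all downstream
indices are correlation-based and scale-invariant, so no absolute
calibration is attempted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import ContractError, DomainError
from .io_streams import MultiChannelRecord, write_recording  # re-export write_recording
from .preprocess import ChannelSignals
from .timeseries import TimeSeries

__all__ = [
    "SimulationConfig",
    "abp_waveform",
    "generate_abp",
    "generate_nirs_channel",
    "simulate_recording",
    "write_recording",
]

SLOW_BAND = (0.005, 0.05)  # Hz, slow vasogenic waves


class SimulationConfig(BaseModel):
    """Ground-truth scenario description for one simulated recording.

    Amplitudes of the pressure components are in mmHg; hemoglobin
    quantities are in arbitrary concentration units (a.u.).
    """

    duration: float = Field(default=600.0, gt=0, description="recording length, s")
    abp_rate: float = Field(default=100.0, gt=0, description="niABP sampling rate, Hz")
    nirs_rate: float = Field(default=250.0, gt=0, description="NIRS sampling rate, Hz")

    abp_mean: float = Field(default=90.0, description="mean arterial pressure, mmHg")
    cardiac_freq: float = Field(default=1.1, gt=0)
    cardiac_amp: float = Field(default=15.0, ge=0)
    resp_freq: float = Field(default=0.25, gt=0)
    resp_amp: float = Field(default=3.0, ge=0)
    mayer_freq: float = Field(default=0.1, gt=0)
    mayer_amp: float = Field(default=3.0, ge=0)
    slow_wave_freqs: tuple[float, ...] = (0.02, 0.033)
    slow_wave_amps: tuple[float, ...] = (5.0, 3.0)

    reactivity_coupling: tuple[float, ...] = (0.9, 0.9, 0.9, 0.9, -0.3, -0.3, -0.3, -0.3)
    cerebral_slow_amp: float = Field(default=1.0, ge=0, description="a.u.")
    hbo_weight: float = Field(default=0.7, description="share of cerebral signal in HbO")
    hhb_weight: float = Field(default=0.3, description="share of cerebral signal in HHb")
    scalp_amp: float = Field(default=1.0, ge=0, description="a.u.")
    scalp_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    sensor_noise_sd: float = Field(default=0.05, ge=0, description="signal units")
    hbo_baseline: float = 30.0
    hhb_baseline: float = 15.0
    short_baseline_fraction: float = 0.1

    nirs_delay_true: float = Field(
        default=3.24, ge=0, description="true NIRS lead over the niABP stream, s"
    )
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self):
        if len(self.slow_wave_freqs) != len(self.slow_wave_amps):
            raise ValueError("slow_wave_freqs and slow_wave_amps must have equal length")
        for f in self.slow_wave_freqs:
            if not SLOW_BAND[0] <= f <= SLOW_BAND[1]:
                raise ValueError(
                    f"slow_wave_freqs: {f} Hz outside the vasogenic band {SLOW_BAND}"
                )
        for rho in self.reactivity_coupling:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"reactivity_coupling: {rho} outside [-1, +1]")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    # -- component bookkeeping ---------------------------------------

    def components(self) -> list[tuple[float, float]]:
        """(freq, amplitude) of every deterministic ABP component."""
        out = [
            (self.cardiac_freq, self.cardiac_amp),
            (self.resp_freq, self.resp_amp),
            (self.mayer_freq, self.mayer_amp),
        ]
        out += list(zip(self.slow_wave_freqs, self.slow_wave_amps))
        return out


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    """Independent, reproducible generator for one noise/phase stream."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


def _abp_phases(config: SimulationConfig) -> np.ndarray:
    return _rng(config, 0).uniform(0.0, 2.0 * np.pi, len(config.components()))


def _sum_of_sines(t, freqs, amps, phases) -> np.ndarray:
    out = np.zeros_like(np.asarray(t, float))
    for f, a, p in zip(freqs, amps, phases):
        if a:
            out += a * np.sin(2.0 * np.pi * f * t + p)
    return out


def abp_waveform(config: SimulationConfig, t) -> np.ndarray:
    """Noiseless niABP waveform (mmHg) at arbitrary physiological times."""
    comps = config.components()
    return config.abp_mean + _sum_of_sines(
        t, [c[0] for c in comps], [c[1] for c in comps], _abp_phases(config)
    )


def _abp_oscillation_norm(config: SimulationConfig, t) -> np.ndarray:
    """ABP oscillation scaled to unit total amplitude (dimensionless)."""
    total = sum(a for _, a in config.components())
    if total == 0:
        return np.zeros_like(np.asarray(t, float))
    return (abp_waveform(config, t) - config.abp_mean) / total


#: sinusoids per independently drawn slow-band process; broad enough that
#: two independent draws decorrelate over a 300-s correlation window
_N_SLOW_COMPONENTS = 8


def _slow_process_norm(config: SimulationConfig, t, rng: np.random.Generator) -> np.ndarray:
    """Independent slow-band process with unit total amplitude.

    Frequencies are drawn uniformly within the vasogenic band and phases
    uniformly on the circle (a fresh draw per channel per seed), so a
    decoupled channel shares no spectral line with the ABP slow waves.
    """
    if sum(config.slow_wave_amps) == 0:
        return np.zeros_like(np.asarray(t, float))
    freqs = rng.uniform(SLOW_BAND[0], SLOW_BAND[1], _N_SLOW_COMPONENTS)
    phases = rng.uniform(0.0, 2.0 * np.pi, _N_SLOW_COMPONENTS)
    amps = np.full(_N_SLOW_COMPONENTS, 1.0 / _N_SLOW_COMPONENTS)
    return _sum_of_sines(t, freqs, amps, phases)


def generate_abp(config: SimulationConfig) -> TimeSeries:
    """Simulate the niABP stream: mean + sinusoids + white sensor noise."""
    n = int(round(config.duration * config.abp_rate))
    t = np.arange(n) / config.abp_rate
    values = abp_waveform(config, t)
    if config.sensor_noise_sd > 0:
        values = values + _rng(config, 1).normal(0.0, config.sensor_noise_sd, n)
    return TimeSeries(values, rate=config.abp_rate, label="abp", units="mmHg")


def generate_nirs_channel(
    abp: TimeSeries,
    coupling: float,
    config: SimulationConfig,
    channel_index: int = 0,
) -> ChannelSignals:
    """Simulate one channel's normal and short-reference NIRS traces.

    The recorded NIRS timestamps match the ABP stream's, but the NIRS
    content is advanced by ``config.nirs_delay_true`` seconds (the NIRS
    stream leads, since the niABP device output lags).
    """
    if not -1.0 <= coupling <= 1.0:
        raise DomainError(f"reactivity coupling {coupling} outside [-1, +1]")
    if abp.duration + 1e-9 < config.duration:
        raise ContractError(
            f"abp covers {abp.duration:.3f} s < requested {config.duration} s"
        )

    n = int(round(config.duration * config.nirs_rate))
    t_rec = abp.start_time + np.arange(n) / config.nirs_rate
    t_phys = t_rec + config.nirs_delay_true

    indep = _slow_process_norm(config, t_phys, _rng(config, 2, channel_index, 0))
    cerebral = config.cerebral_slow_amp * (
        coupling * _abp_oscillation_norm(config, t_phys)
        + (1.0 - abs(coupling)) * indep
    )

    scalp = (
        config.scalp_fraction
        * config.scalp_amp
        * _slow_process_norm(config, t_phys, _rng(config, 2, channel_index, 1))
    )

    def noise(k):
        if config.sensor_noise_sd == 0:
            return 0.0
        return _rng(config, 2, channel_index, 2 + k).normal(0, config.sensor_noise_sd, n)

    sb = config.short_baseline_fraction
    traces = {
        "HbO_norm": config.hbo_baseline + config.hbo_weight * cerebral + scalp + noise(0),
        "HHb_norm": config.hhb_baseline + config.hhb_weight * cerebral + scalp + noise(1),
        "HbO_short": sb * config.hbo_baseline + scalp + noise(2),
        "HHb_short": sb * config.hhb_baseline + scalp + noise(3),
    }
    cid = f"ch{channel_index + 1}"
    ch = ChannelSignals(channel_id=cid)
    for name, vals in traces.items():
        setattr(
            ch,
            name,
            TimeSeries(
                np.broadcast_to(vals, (n,)).astype(float),
                rate=config.nirs_rate,
                start_time=abp.start_time,
                label=f"{cid}_{name}",
                units="a.u.",
            ),
        )
    return ch


def simulate_recording(config: SimulationConfig) -> MultiChannelRecord:
    """Full recording: niABP plus one channel per configured coupling."""
    abp = generate_abp(config)
    channels = {}
    for i, rho in enumerate(config.reactivity_coupling):
        ch = generate_nirs_channel(abp, rho, config, channel_index=i)
        channels[ch.channel_id] = ch
    return MultiChannelRecord(
        abp=abp,
        channels=channels,
        meta={
            "simulation": config.model_dump(),
            "nirs_delay_true": config.nirs_delay_true,
        },
    )
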