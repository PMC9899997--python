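"""Shared fixtures: small synthetic scenarios and hand-built records."""

from __future__ import annotations

import numpy as np
import pytest

from cvrmap import (
    ChannelSignals,
    MultiChannelRecord,
    SimulationConfig,
    TimeSeries,
    generate_abp,
)


@pytest.fixture
def quiet_cfg():
    """Noiseless single-channel scenario, ideal alignment (no device lag)."""

    def make(**overrides):
        base = dict(
            duration=620.0,
            sensor_noise_sd=0.0,
            scalp_fraction=0.0,
            nirs_delay_true=0.0,
            reactivity_coupling=(1.0,),
            seed=11,
        )
        base.update(overrides)
        return SimulationConfig(**base)

    return make


@pytest.fixture
def affine_record():
    """Record whose five pure traces are ``a * niABP + b`` on the ABP grid.

    Emulates device-computed pure-cerebral columns (honored as-is by
    preprocessing), so that every CVR index sees an exactly affine
    surrogate of the pressure signal.
    """

    def make(a: float, b: float, duration: float = 600.0, seed: int = 11):
        cfg = SimulationConfig(duration=duration, sensor_noise_sd=0.0, seed=seed)
        abp = generate_abp(cfg)
        surr = abp.with_values(a * abp.values + b, label="surrogate")
        ch = ChannelSignals(
            channel_id="ch1",
            HbO_pure=surr.copy(),
            HHb_pure=surr.copy(),
            tHb_pure=surr.copy(),
            HbDiff_pure=surr.copy(),
            rSO2=surr.copy(),
        )
        return MultiChannelRecord(abp=abp, channels={"ch1": ch}, meta={"t0": 0.0})

    return make


@pytest.fixture
def impulse_record():
    """Impulse trains in both streams, NIRS content leading by a true delay."""

    def make(true_delay: float = 3.24, impulse_time: float = 15.0,
             duration: float = 30.0):
        abp = TimeSeries(np.zeros(int(duration * 100)), rate=100.0, label="abp")
        abp.values[int(round(impulse_time * 100))] = 1.0
        nirs = np.zeros(int(duration * 250))
        k = int(round((impulse_time - true_delay) * 250))
        nirs[k] = 1.0
        ch = ChannelSignals(
            channel_id="ch1", HbO_norm=TimeSeries(nirs, rate=250.0, label="HbO")
        )
        return MultiChannelRecord(abp=abp, channels={"ch1": ch}, meta={})

    return make
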