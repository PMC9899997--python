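"""Pure-cerebral trace derivation.

Multi-distance fNIRS separates cerebral from extracerebral signal by
pairing each 30 mm transmitter–receiver channel with a 10 mm short
reference channel that samples scalp only.  Subtracting the short
channel removes scalp contamination; from the resulting pure HbO and
HHb the derived traces follow:

    tHb    = HbO + HHb
    HbDiff = HbO - HHb
    rSO2   = 100 * numerator / tHb      (numerator HHb by default)

The default rSO2 numerator is HHb, matching the acquisition convention
this pipeline emulates; the conventional oxygen-saturation definition
(HbO/tHb) is available via ``rso2_numerator="HbO"``.  A warning is
logged when the default is used so the choice is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

from .errors import ContractError, DomainError
from .timeseries import TimeSeries

__all__ = ["ChannelSignals", "subtract_short", "derive_traces", "preprocess_record"]

log = logging.getLogger(__name__)

RSO2_NUMERATORS = ("HHb", "HbO")


@dataclass
class ChannelSignals:
    """The per-channel bundle of NIRS traces.

    ``*_norm`` are the 30 mm normal-channel traces (cerebral + scalp),
    ``*_short`` the 10 mm reference-channel traces (scalp only), and
    ``*_pure`` / ``rSO2`` the derived pure-cerebral traces.  Derived
    fields are ``None`` until filled, either by the acquisition device
    (used as-is) or by :func:`derive_traces`.
    """

    channel_id: str
    HbO_norm: Optional[TimeSeries] = None
    HHb_norm: Optional[TimeSeries] = None
    HbO_short: Optional[TimeSeries] = None
    HHb_short: Optional[TimeSeries] = None
    HbO_pure: Optional[TimeSeries] = None
    HHb_pure: Optional[TimeSeries] = None
    tHb_pure: Optional[TimeSeries] = None
    HbDiff_pure: Optional[TimeSeries] = None
    rSO2: Optional[TimeSeries] = None

    def trace_names(self) -> list[str]:
        """Names of the trace fields that are present."""
        return [
            f.name
            for f in fields(self)
            if f.name != "channel_id" and getattr(self, f.name) is not None
        ]


def subtract_short(
    normal: TimeSeries, short: TimeSeries, scale: float = 1.0
) -> TimeSeries:
    """Remove scalp contamination: ``normal - scale * short``.

    Both series must share the same timeline.  The output is missing
    wherever either input is missing.  ``scale`` defaults to unit gain;
    no regression fit is attempted.
    """
    normal.require_same_timeline(short, "normal/short channel")
    out = normal.values - scale * short.values
    return normal.with_values(out, label=f"{normal.label}_pure")


def derive_traces(
    ch: ChannelSignals,
    rso2_numerator: str = "HHb",
    short_scale: float = 1.0,
) -> ChannelSignals:
    """Fill the derived pure-cerebral traces of a channel.

    Device-computed traces already present on ``ch`` are kept as-is;
    derivation only fills the gaps.  ``HbO_pure``/``HHb_pure`` come from
    short-channel subtraction when absent, then::

        tHb_pure    = HbO_pure + HHb_pure
        HbDiff_pure = HbO_pure - HHb_pure
        rSO2        = 100 * numerator / tHb_pure   (missing where tHb <= 0)

    Missingness is monotone: a derived sample is missing wherever any of
    its inputs is missing.
    """
    if rso2_numerator not in RSO2_NUMERATORS:
        raise DomainError(
            f"rso2_numerator must be one of {RSO2_NUMERATORS}, got {rso2_numerator!r}"
        )
    if rso2_numerator == "HHb":
        log.debug(
            "rSO2 computed as 100*HHb/tHb (acquisition convention); "
            "pass rso2_numerator='HbO' for the oxygen-saturation definition"
        )

    if ch.HbO_pure is None:
        if ch.HbO_norm is None or ch.HbO_short is None:
            raise ContractError(f"channel {ch.channel_id}: no HbO traces to derive from")
        ch.HbO_pure = subtract_short(ch.HbO_norm, ch.HbO_short, short_scale)
    if ch.HHb_pure is None:
        if ch.HHb_norm is None or ch.HHb_short is None:
            raise ContractError(f"channel {ch.channel_id}: no HHb traces to derive from")
        ch.HHb_pure = subtract_short(ch.HHb_norm, ch.HHb_short, short_scale)

    hbo, hhb = ch.HbO_pure, ch.HHb_pure
    hbo.require_same_timeline(hhb, f"channel {ch.channel_id} HbO/HHb")

    if ch.tHb_pure is None:
        ch.tHb_pure = hbo.with_values(hbo.values + hhb.values, label="tHb_pure")
    if ch.HbDiff_pure is None:
        ch.HbDiff_pure = hbo.with_values(hbo.values - hhb.values, label="HbDiff_pure")
    if ch.rSO2 is None:
        thb = ch.tHb_pure.values
        num = hhb.values if rso2_numerator == "HHb" else hbo.values
        with np.errstate(divide="ignore", invalid="ignore"):
            rso2 = 100.0 * num / thb
        rso2 = np.where(thb <= 0, np.nan, rso2)
        ch.rSO2 = hbo.with_values(rso2, label="rSO2")
        ch.rSO2.units = "%"
    return ch


def preprocess_record(record, rso2_numerator: str = "HHb", short_scale: float = 1.0):
    """Derive pure traces for every channel of a MultiChannelRecord in place."""
    for ch in record.channels.values():
        derive_traces(ch, rso2_numerator=rso2_numerator, short_scale=short_scale)
    record.meta["rso2_numerator"] = rso2_numerator
    record.meta["short_scale"] = short_scale
    return record
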