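"""Cerebrovascular reactivity (CVR) index computation.

The core statistic is a moving Pearson correlation between slow-wave
fluctuations of a NIRS surrogate for cerebral blood volume and the
non-invasive arterial blood pressure (niABP):

1.  Every raw trace is decimated with non-overlapping moving-average
    filters of 10-s duration.  This isolates the slow vasogenic band
    (0.005-0.05 Hz) carrying autoregulatory information and analytically
    nulls faster confounders — a 0.1 Hz Mayer wave completes exactly one
    period per window, so its uniform-sample mean is zero.
2.  Pearson correlation coefficients are computed over 30 consecutive
    10-s means of the surrogate and of niABP, updated every 10 s
    (a 300-s window sliding in 10-s hops).

Five indices are derived per channel, each bounded in [-1, +1]:

========  =========================  =============================
index     surrogate                  correlated with
========  =========================  =============================
HbOx      oxyhemoglobin (HbO)        niABP
HHbx      deoxyhemoglobin (HHb)      niABP
tHbx      total hemoglobin (tHb)     niABP
HbDiffx   HbO - HHb                  niABP
COx       rSO2                       niABP
========  =========================  =============================

Positive values (toward +1, red) indicate pressure-passive flow —
impaired reactivity; values near zero or negative (toward -1, blue)
indicate intact reactivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .errors import ConfigurationError, ContractError
from .io_streams import MultiChannelRecord
from .timeseries import TimeSeries

__all__ = [
    "EngineConfig",
    "CvrIndexSeries",
    "INDEX_TYPES",
    "INDEX_SURROGATE",
    "decimate",
    "pearson",
    "sliding_index",
    "compute_all_indices",
]

INDEX_TYPES = ("HbOx", "HHbx", "tHbx", "HbDiffx", "COx")

#: which pure-cerebral trace each index correlates with niABP
INDEX_SURROGATE = {
    "HbOx": "HbO_pure",
    "HHbx": "HHb_pure",
    "tHbx": "tHb_pure",
    "HbDiffx": "HbDiff_pure",
    "COx": "rSO2",
}


class EngineConfig(BaseModel):
    """Parameters of the decimation + sliding-correlation engine.

    Defaults reproduce the published construction: 10-s non-overlapping
    means, correlation over 30 consecutive means, updated every mean.
    """

    decim_window: float = Field(default=10.0, gt=0, description="mean-filter duration, s")
    corr_window: int = Field(default=30, ge=3, description="means per correlation window")
    update_step: int = Field(default=1, ge=1, description="hop between windows, in means")
    min_valid_fraction_per_mean: float = Field(default=0.5, ge=0.0, le=1.0)
    min_valid_means_per_window: int | None = Field(
        default=None, description="None -> corr_window (all means required)"
    )
    index_types: tuple[str, ...] = INDEX_TYPES

    @field_validator("index_types")
    @classmethod
    def _known_types(cls, v):
        bad = [t for t in v if t not in INDEX_TYPES]
        if bad:
            raise ValueError(f"unknown index types {bad}; choose from {INDEX_TYPES}")
        return tuple(v)

    @property
    def min_valid_means(self) -> int:
        return self.corr_window if self.min_valid_means_per_window is None else self.min_valid_means_per_window


@dataclass
class CvrIndexSeries:
    """One index type's correlation values over time for one channel.

    Timestamps mark the right edge of each correlation window; values
    lie in [-1, +1] or are NaN where the window had insufficient valid
    data or zero variance.
    """

    channel_id: str
    index_type: str
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, float)
        self.values = np.asarray(self.values, float)
        if self.timestamps.shape != self.values.shape:
            raise ContractError("timestamps and values must have equal length")

    @property
    def n(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------


def decimate(
    series: TimeSeries,
    window: float = 10.0,
    min_valid_fraction: float = 0.5,
    anchor: float | None = None,
) -> TimeSeries:
    """Non-overlapping moving-average decimation.

    Each complete wall-clock window ``[anchor + k*window, anchor +
    (k+1)*window)`` yields one output value: the arithmetic mean of the
    valid samples it contains, or NaN if fewer than
    ``min_valid_fraction`` of its scheduled samples are valid.  Windows
    that extend beyond the sampled span (leading when ``anchor`` is
    later than the first sample's window start, and the incomplete
    trailing window) are dropped.  Output timestamps are window right
    edges; the output rate is ``1/window``.
    """
    if window < 2.0 / series.rate:
        raise ConfigurationError(
            f"decim_window={window} s is shorter than 2 sample periods at {series.rate} Hz"
        )
    if anchor is None:
        anchor = series.start_time
    t = series.timestamps
    ids = np.floor((t - anchor) / window + 1e-9).astype(int)

    # complete windows lie fully inside the sampled span
    k_min = int(np.ceil((series.start_time - anchor) / window - 1e-9))
    k_max = int(np.floor((series.end_time - anchor) / window + 1e-9)) - 1
    if k_max < k_min:
        return TimeSeries(
            np.empty(0), rate=1.0 / window,
            start_time=anchor + (k_min + 1) * window,
            label=series.label, units=series.units,
        )

    sel = (ids >= k_min) & (ids <= k_max)
    ids_sel = ids[sel] - k_min
    vals = series.values[sel]
    nwin = k_max - k_min + 1
    scheduled = np.bincount(ids_sel, minlength=nwin)
    valid_mask = ~np.isnan(vals)
    nvalid = np.bincount(ids_sel[valid_mask], minlength=nwin)
    sums = np.bincount(ids_sel[valid_mask], weights=vals[valid_mask], minlength=nwin)

    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / nvalid
    frac = np.where(scheduled > 0, nvalid / np.maximum(scheduled, 1), 0.0)
    means[frac < min_valid_fraction] = np.nan

    return TimeSeries(
        means,
        rate=1.0 / window,
        start_time=anchor + (k_min + 1) * window,  # right-edge timestamps
        label=series.label,
        units=series.units,
    )


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length sequences.

    Returns NaN (missing, not an error) when either input has zero
    variance — a flatlined or clamped signal is physiologically
    meaningful, not exceptional.  NaN pairs must be removed by the
    caller.  Result is clipped to [-1, +1] against rounding.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ContractError("pearson inputs must have equal length")
    if x.size < 3:
        raise ContractError("pearson needs at least 3 points")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def _common_window(a: TimeSeries, b: TimeSeries):
    """Trim two same-rate series to their common timestamp grid."""
    if abs(a.rate - b.rate) > 1e-9 * a.rate:
        raise ContractError(f"decimated rates differ: {a.rate} vs {b.rate}")
    off = (b.start_time - a.start_time) * a.rate
    if abs(off - round(off)) > 1e-6:
        raise ContractError(
            "decimated series are on offset grids; decimate with a common anchor"
        )
    t0 = max(a.start_time, b.start_time)
    t1 = min(a.end_time, b.end_time)
    return a.slice_time(t0, t1), b.slice_time(t0, t1)


def sliding_index(
    surrogate: TimeSeries,
    abp: TimeSeries,
    cfg: EngineConfig | None = None,
    channel_id: str = "",
    index_type: str = "",
) -> CvrIndexSeries:
    """Moving Pearson correlation over ``corr_window`` decimated means.

    Both inputs are decimated series sharing one timestamp grid.  For
    each window position (advancing by ``update_step`` means) the
    correlation over the most recent ``corr_window`` means is emitted,
    timestamped at the window's right edge.  A window is missing (NaN)
    when fewer than ``min_valid_means_per_window`` pairs are jointly
    valid or when either side has zero variance.
    """
    cfg = cfg or EngineConfig()
    surrogate, abp = _common_window(surrogate, abp)
    w, step = cfg.corr_window, cfg.update_step
    n = surrogate.n
    if n < w:
        warnings.warn(
            f"overlap of {n} decimated means is shorter than the "
            f"{w}-mean correlation window; no index values emitted",
            stacklevel=2,
        )
        return CvrIndexSeries(channel_id, index_type, np.empty(0), np.empty(0))

    x = surrogate.values
    y = abp.values
    both = ~np.isnan(x) & ~np.isnan(y)
    # global demeaning (correlation-invariant) keeps the windowed-sum
    # formula well conditioned when signals ride a large offset
    gx = x[both].mean() if both.any() else 0.0
    gy = y[both].mean() if both.any() else 0.0
    x0 = np.where(both, x - gx, 0.0)
    y0 = np.where(both, y - gy, 0.0)

    def winsum(v):
        c = np.concatenate(([0.0], np.cumsum(v)))
        return c[w:] - c[:-w]

    cnt = winsum(both.astype(float))
    sx, sy = winsum(x0), winsum(y0)
    sxx, syy, sxy = winsum(x0 * x0), winsum(y0 * y0), winsum(x0 * y0)

    ends = np.arange(w - 1, n, step)
    pos = ends - (w - 1)
    m = cnt[pos]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = m * sxy[pos] - sx[pos] * sy[pos]
        varx = m * sxx[pos] - sx[pos] ** 2
        vary = m * syy[pos] - sy[pos] ** 2
        r = cov / np.sqrt(varx * vary)
    r = np.clip(r, -1.0, 1.0)
    # zero-variance guard, relative to each window's own magnitude
    bad = (
        (m < cfg.min_valid_means)
        | (varx <= 1e-10 * np.maximum(m * sxx[pos], 1e-300))
        | (vary <= 1e-10 * np.maximum(m * syy[pos], 1e-300))
    )
    r[bad] = np.nan

    timestamps = surrogate.timestamps[ends]
    return CvrIndexSeries(channel_id, index_type, timestamps, r)


def compute_all_indices(
    record: MultiChannelRecord, cfg: EngineConfig | None = None
) -> list[CvrIndexSeries]:
    """All configured CVR indices for every channel of an aligned record.

    The record must be aligned (common timeline) and preprocessed (pure
    traces present).  Decimation windows for every stream are anchored
    at the record's common start so that the 100 Hz niABP and 250 Hz
    NIRS streams are averaged over identical wall-clock windows; no
    cross-rate resampling is ever performed.
    """
    cfg = cfg or EngineConfig()
    anchor = record.meta.get("t0", record.abp.start_time)
    abp_dec = decimate(
        record.abp, cfg.decim_window, cfg.min_valid_fraction_per_mean, anchor=anchor
    )
    out: list[CvrIndexSeries] = []
    for cid, ch in record.channels.items():
        for itype in cfg.index_types:
            trace = getattr(ch, INDEX_SURROGATE[itype])
            if trace is None:
                warnings.warn(
                    f"channel {cid}: trace {INDEX_SURROGATE[itype]} missing; "
                    f"{itype} skipped",
                    stacklevel=2,
                )
                continue
            dec = decimate(
                trace, cfg.decim_window, cfg.min_valid_fraction_per_mean, anchor=anchor
            )
            out.append(sliding_index(dec, abp_dec, cfg, channel_id=cid, index_type=itype))
    return out
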