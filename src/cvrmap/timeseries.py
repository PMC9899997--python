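"""Uniformly sampled, time-stamped physiological traces.

A :class:`TimeSeries` is the basic container for every raw and derived
signal in the pipeline: non-invasive arterial blood pressure (niABP),
the NIRS hemoglobin traces (HbO, HHb, tHb, HbDiff) and regional oxygen
saturation (rSO2).  Samples are implicitly timestamped
``start_time + k / rate``; missing samples are explicit NaN markers and
are never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ContractError

__all__ = ["TimeSeries"]

# tolerance (in sample periods) when comparing timestamps of two series
_TICK_TOL = 1e-6


@dataclass
class TimeSeries:
    """A uniformly sampled trace with NaN missing-value markers.

    Parameters
    ----------
    values
        Sample values; coerced to a float64 array.  ``NaN`` marks a
        scheduled-but-missing sample.
    rate
        Sampling rate in Hz; must be positive.
    start_time
        Wall-clock time of the first sample, in seconds.
    label, units
        Free-text descriptors (e.g. ``"abp"``, ``"mmHg"``).
    """

    values: np.ndarray
    rate: float
    start_time: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ContractError(f"rate must be > 0, got {self.rate}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ContractError("values must be one-dimensional")

    # -- timeline -----------------------------------------------------

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def period(self) -> float:
        return 1.0 / self.rate

    @property
    def end_time(self) -> float:
        """Wall-clock end of the sampled span (exclusive right edge)."""
        return self.start_time + self.n / self.rate

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def timestamps(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    # -- operations ---------------------------------------------------

    def copy(self) -> "TimeSeries":
        return replace(self, values=self.values.copy())

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        """Same timeline, new values (and optionally a new label)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            label=self.label if label is None else label,
        )

    def slice_time(self, t0: float, t1: float) -> "TimeSeries":
        """Samples with ``t0 <= t < t1`` (half-open, tick-tolerant)."""
        k0 = int(np.ceil((t0 - self.start_time) * self.rate - _TICK_TOL))
        k0 = max(k0, 0)
        # ticks strictly below t1; a tick within tolerance of t1 is excluded
        k1 = int(np.ceil((t1 - self.start_time) * self.rate - _TICK_TOL))
        k1 = min(max(k1, k0), self.n)
        return replace(
            self,
            values=self.values[k0:k1].copy(),
            start_time=self.start_time + k0 / self.rate,
        )

    def same_timeline(self, other: "TimeSeries") -> bool:
        """True if both series share rate, start time and length."""
        return (
            self.n == other.n
            and abs(self.rate - other.rate) <= _TICK_TOL * self.rate
            and abs(self.start_time - other.start_time) <= _TICK_TOL * self.period
        )

    def require_same_timeline(self, other: "TimeSeries", what: str = "series") -> None:
        if not self.same_timeline(other):
            raise ContractError(
                f"{what} timelines differ: "
                f"(n={self.n}, rate={self.rate}, start={self.start_time}) vs "
                f"(n={other.n}, rate={other.rate}, start={other.start_time})"
            )
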