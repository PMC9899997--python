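"""Recording and index-file I/O plus dual-stream delay alignment.

Recordings emulate an ICM+-style delimited export of two devices: a
100 Hz niABP stream and a 250 Hz multi-channel NIRS stream.  Two
dialects are supported and round-trip losslessly:

``merged``
    One CSV whose rows are the union of both tick grids (the grids do
    not nest: 0.01 s is not a multiple of 0.004 s).  A cell is empty on
    ticks where its stream has no scheduled sample, and ``nan`` where a
    sample was scheduled but is missing.

``split``
    One file per device: ``<base>.abp.csv`` and ``<base>.nirs.csv``.

Both dialects carry ``#``-prefixed header lines declaring each stream's
rate, start time and length; these are mandatory (a uniform grid cannot
be reconstructed from row times alone once samples are missing).

The two streams arrive with a known inter-device lag: the niABP output
trails the NIRS output, so alignment shifts NIRS timestamps forward by
a fixed correction (3.22 s by default, the mean measured device lag).
The shift is applied in whole samples; any sub-sample residual is
recorded in the record's metadata rather than interpolated away.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ContractError, FormatError
from .preprocess import ChannelSignals
from .timeseries import TimeSeries

__all__ = [
    "MultiChannelRecord",
    "write_recording",
    "read_recording",
    "align_streams",
    "write_index_csv",
    "read_index_csv",
    "DEFAULT_NIRS_DELAY",
]

#: Fixed NIRS delay correction in seconds (mean measured niABP output lag).
DEFAULT_NIRS_DELAY = 3.22

_MAGIC = "cvrmap-recording"
_TICK_TOL = 1e-6  # fraction of a sample period

# trace-column suffixes recognised in recording files, in write order
_TRACE_FIELDS = (
    "HbO_norm",
    "HHb_norm",
    "HbO_short",
    "HHb_short",
    "HbO_pure",
    "HHb_pure",
    "tHb_pure",
    "HbDiff_pure",
    "rSO2",
)


@dataclass
class MultiChannelRecord:
    """One recording: the niABP trace plus per-channel NIRS bundles."""

    abp: TimeSeries
    channels: dict[str, ChannelSignals] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def iter_series(self):
        """Yield ``(stream_name, TimeSeries)`` over ABP and all NIRS traces."""
        yield "abp", self.abp
        for cid, ch in self.channels.items():
            for name in ch.trace_names():
                yield f"{cid}_{name}", getattr(ch, name)

    def nirs_series(self):
        for name, s in self.iter_series():
            if name != "abp":
                yield name, s


# ---------------------------------------------------------------------------
# writing


def _header_lines(abp: TimeSeries, nirs_rate, nirs_start, nirs_n, channel_ids,
                  kind="merged") -> list[str]:
    lines = [f"# {_MAGIC} v1 dialect={kind}"]
    lines.append(
        f"# abp: rate={abp.rate!r} start={abp.start_time!r} n={abp.n} units={abp.units or 'mmHg'}"
    )
    if nirs_rate is not None:
        lines.append(f"# nirs: rate={nirs_rate!r} start={nirs_start!r} n={nirs_n}")
    if channel_ids:
        lines.append("# channels: " + ",".join(channel_ids))
    return lines


def _channel_frame(channels: Sequence[ChannelSignals]):
    """Column name -> TimeSeries for every present trace, plus grid info."""
    cols: dict[str, TimeSeries] = {}
    ref = None
    for ch in channels:
        for name in ch.trace_names():
            s = getattr(ch, name)
            if ref is None:
                ref = s
            else:
                ref.require_same_timeline(s, f"{ch.channel_id}_{name}")
            cols[f"{ch.channel_id}_{name}"] = s
    return cols, ref


def write_recording(
    abp: TimeSeries,
    channels: Sequence[ChannelSignals],
    path: str | Path,
    dialect: str = "merged",
) -> list[Path]:
    """Write a recording; returns the file(s) written.

    ``merged`` writes a single union-grid CSV at ``path``;  ``split``
    writes ``<path minus .csv>.abp.csv`` and ``....nirs.csv``.
    """
    path = Path(path)
    cols, nirs_ref = _channel_frame(channels)
    channel_ids = list(dict.fromkeys(c.channel_id for c in channels))

    if dialect == "split":
        base = path.with_suffix("") if path.suffix == ".csv" else path
        abp_path = base.with_suffix(".abp.csv")
        nirs_path = base.with_suffix(".nirs.csv")
        _write_grid_csv(abp_path, _header_lines(abp, None, None, None, [], "split"),
                        abp.timestamps, {"abp": abp.values})
        written = [abp_path]
        if cols:
            hdr = [f"# {_MAGIC} v1 dialect=split",
                   f"# nirs: rate={nirs_ref.rate!r} start={nirs_ref.start_time!r} n={nirs_ref.n}",
                   "# channels: " + ",".join(channel_ids)]
            _write_grid_csv(nirs_path, hdr, nirs_ref.timestamps,
                            {k: v.values for k, v in cols.items()})
            written.append(nirs_path)
        return written

    if dialect != "merged":
        raise ContractError(f"unknown dialect {dialect!r}")

    # union-of-grids merged file
    if cols:
        nirs_t = nirs_ref.timestamps
        times = np.union1d(abp.timestamps, nirs_t)
    else:
        nirs_ref = None
        times = abp.timestamps
    frame = pd.DataFrame({"time": times})
    frame["abp"] = _scatter(abp, times)
    for name, s in cols.items():
        frame[name] = _scatter(s, times)
    hdr = _header_lines(
        abp,
        nirs_ref.rate if nirs_ref is not None else None,
        nirs_ref.start_time if nirs_ref is not None else None,
        nirs_ref.n if nirs_ref is not None else None,
        channel_ids,
    )
    _write_frame(path, hdr, frame)
    return [path]


def _scatter(series: TimeSeries, times: np.ndarray) -> np.ndarray:
    """Place series samples onto the union grid; '' elsewhere (as object)."""
    out = np.full(times.size, "", dtype=object)
    k = np.round((times - series.start_time) * series.rate).astype(int)
    on_grid = (
        (k >= 0)
        & (k < series.n)
        & (np.abs(times - (series.start_time + k / series.rate)) < _TICK_TOL / series.rate)
    )
    vals = series.values[k[on_grid]]
    out[on_grid] = [("nan" if np.isnan(v) else repr(float(v))) for v in vals]
    return out


def _write_grid_csv(path, header_lines, times, columns: Mapping[str, np.ndarray]):
    frame = pd.DataFrame({"time": times})
    for name, vals in columns.items():
        frame[name] = [("nan" if np.isnan(v) else repr(float(v))) for v in vals]
    _write_frame(path, header_lines, frame)


def _write_frame(path, header_lines, frame: pd.DataFrame):
    buf = io.StringIO()
    frame.insert(0, "time_txt", [repr(float(t)) for t in frame.pop("time")])
    frame = frame.rename(columns={"time_txt": "time"})
    frame.to_csv(buf, index=False)
    Path(path).write_text("\n".join(header_lines) + "\n" + buf.getvalue())


# ---------------------------------------------------------------------------
# reading


def _parse_header(text: str) -> dict:
    meta: dict = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if body.startswith(_MAGIC):
            meta["magic"] = body
        m = re.match(r"(abp|nirs):\s*(.*)", body)
        if m:
            stream, rest = m.groups()
            d = {}
            for kv in rest.split():
                k, _, v = kv.partition("=")
                d[k] = v
            meta[stream] = {
                "rate": float(d["rate"]),
                "start": float(d.get("start", 0.0)),
                "n": int(d["n"]) if "n" in d else None,
                "units": d.get("units", ""),
            }
        m = re.match(r"channels:\s*(.*)", body)
        if m:
            meta["channels"] = [c for c in m.group(1).split(",") if c]
    return meta


def _read_csv_file(path: Path):
    text = path.read_text()
    meta = _parse_header(text)
    if "magic" not in meta:
        raise FormatError(f"{path}: missing mandatory cvrmap recording header")
    df = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")
    if "time" not in df.columns:
        raise FormatError(f"{path}: missing mandatory 'time' column")
    quality: dict[str, dict] = {}
    for col in df.columns:
        if df[col].dtype == object:
            as_num = pd.to_numeric(df[col], errors="coerce")
            bad = int((as_num.isna() & df[col].notna()
                       & ~df[col].astype(str).str.strip().str.lower().isin(["nan", ""])).sum())
            if bad:
                quality[col] = {"unparseable": bad}
            df[col] = as_num
    t = df["time"].to_numpy(float)
    if np.isnan(t).any():
        row = int(np.flatnonzero(np.isnan(t))[0])
        raise FormatError(f"{path}: unparseable timestamp at data row {row}")
    nonmono = np.flatnonzero(np.diff(t) <= 0)
    if nonmono.size:
        raise FormatError(
            f"{path}: non-monotone timestamps, first offending data row {int(nonmono[0]) + 1}"
        )
    return meta, df, quality


def _gather(df: pd.DataFrame, col: str, rate: float, start: float, n: int) -> TimeSeries:
    """Reconstruct one uniform stream from union-grid rows."""
    t = df["time"].to_numpy(float)
    k = np.round((t - start) * rate).astype(int)
    on_grid = (k >= 0) & (k < n) & (np.abs(t - (start + k / rate)) < _TICK_TOL / rate)
    values = np.full(n, np.nan)
    if col in df.columns:
        values[k[on_grid]] = df[col].to_numpy(float)[on_grid]
    return TimeSeries(values, rate=rate, start_time=start, label=col)


def _split_trace_column(col: str) -> tuple[str, str] | None:
    for suffix in _TRACE_FIELDS:
        if col.endswith("_" + suffix):
            return col[: -(len(suffix) + 1)], suffix
    return None


def read_recording(path: str | Path) -> MultiChannelRecord:
    """Read a recording in either dialect into a :class:`MultiChannelRecord`.

    ``path`` may be a merged file, either half of a split pair, or the
    split pair's base path.  Per-column counts of missing and
    unparseable cells are reported in ``record.meta["quality"]``.
    """
    path = Path(path)
    name = path.name
    if name.endswith(".abp.csv") or name.endswith(".nirs.csv"):
        base = Path(str(path)[: -len(".abp.csv" if name.endswith(".abp.csv") else ".nirs.csv")])
        return _read_split(base)
    if not path.exists():
        for ext in (".abp.csv",):
            if path.with_suffix(ext).exists():
                return _read_split(path)
        raise FormatError(f"{path}: no such recording")
    return _read_merged(path)


def _read_merged(path: Path) -> MultiChannelRecord:
    meta, df, quality = _read_csv_file(path)
    if "abp" not in meta or "abp" not in df.columns:
        raise FormatError(f"{path}: merged recording lacks the abp stream declaration")
    record = _assemble(meta, df, df, quality)
    record.meta["path"] = str(path)
    record.meta["dialect"] = "merged"
    return record


def _read_split(base: Path) -> MultiChannelRecord:
    abp_path = base.with_suffix(".abp.csv")
    nirs_path = base.with_suffix(".nirs.csv")
    if not abp_path.exists():
        raise FormatError(f"{abp_path}: missing abp half of split recording")
    meta_a, df_a, q_a = _read_csv_file(abp_path)
    if nirs_path.exists():
        meta_n, df_n, q_n = _read_csv_file(nirs_path)
    else:
        meta_n, df_n, q_n = {}, pd.DataFrame({"time": []}), {}
    meta = {**meta_n, **meta_a}
    meta["channels"] = meta_n.get("channels", [])
    record = _assemble(meta, df_a, df_n, {**q_a, **q_n})
    record.meta["path"] = str(base)
    record.meta["dialect"] = "split"
    return record


def _assemble(meta, df_abp, df_nirs, quality) -> MultiChannelRecord:
    a = meta["abp"]
    n_abp = a["n"] if a["n"] is not None else len(df_abp)
    abp = _gather(df_abp, "abp", a["rate"], a["start"], n_abp)
    abp.label, abp.units = "abp", a.get("units", "mmHg")

    channels: dict[str, ChannelSignals] = {}
    if "nirs" in meta:
        ninfo = meta["nirs"]
        n_nirs = ninfo["n"] if ninfo["n"] is not None else len(df_nirs)
        for col in df_nirs.columns:
            parts = _split_trace_column(col)
            if parts is None:
                continue
            cid, trace = parts
            ch = channels.setdefault(cid, ChannelSignals(channel_id=cid))
            setattr(ch, trace, _gather(df_nirs, col, ninfo["rate"], ninfo["start"], n_nirs))

    for name, s in [("abp", abp)] + [
        (f"{cid}_{tr}", getattr(ch, tr))
        for cid, ch in channels.items()
        for tr in ch.trace_names()
    ]:
        entry = quality.setdefault(name if name == "abp" else name, {})
        entry["missing"] = s.n_missing

    return MultiChannelRecord(abp=abp, channels=channels, meta={"quality": quality})


# ---------------------------------------------------------------------------
# alignment


def align_streams(
    record: MultiChannelRecord,
    nirs_delay: float = DEFAULT_NIRS_DELAY,
    min_overlap: float = 10.0,
) -> MultiChannelRecord:
    """Shift NIRS timestamps forward by ``nirs_delay`` and trim to overlap.

    The niABP stream's output lags the NIRS stream, so adding the fixed
    correction to the NIRS timestamps places both on a common
    wall-clock.  The shift is quantised to whole samples per stream
    (e.g. exactly 805 samples at 250 Hz for 3.22 s); the sub-sample
    residual is stored in ``meta["delay_residual"]``.  No resampling is
    performed: each stream keeps its native rate and only samples
    outside the common overlap interval are dropped.
    """
    abp = record.abp.copy()
    new_channels: dict[str, ChannelSignals] = {}
    residual: dict[float, float] = {}
    shifts: dict[float, int] = {}
    for cid, ch in record.channels.items():
        nch = ChannelSignals(channel_id=cid)
        for name in ch.trace_names():
            s = getattr(ch, name).copy()
            nsamp = int(round(nirs_delay * s.rate))
            shifts[s.rate] = nsamp
            residual[s.rate] = nirs_delay - nsamp / s.rate
            s.start_time += nsamp / s.rate
            setattr(nch, name, s)
        new_channels[cid] = nch

    all_series = [abp] + [
        getattr(ch, nm) for ch in new_channels.values() for nm in ch.trace_names()
    ]
    t0 = max(s.start_time for s in all_series)
    t1 = min(s.end_time for s in all_series)
    if t1 - t0 < min_overlap:
        raise AlignmentError(
            f"streams overlap for {max(t1 - t0, 0.0):.3f} s, "
            f"shorter than one {min_overlap:.0f}-s decimation window"
        )

    abp = abp.slice_time(t0, t1)
    for ch in new_channels.values():
        for nm in ch.trace_names():
            setattr(ch, nm, getattr(ch, nm).slice_time(t0, t1))

    meta = dict(record.meta)
    meta.update(
        delay_applied=nirs_delay,
        delay_shift_samples=shifts,
        delay_residual=residual,
        t0=t0,
        t1=t1,
    )
    return MultiChannelRecord(abp=abp, channels=new_channels, meta=meta)


# ---------------------------------------------------------------------------
# index CSV


def write_index_csv(indices, path: str | Path) -> Path:
    """Write CVR index series as ``time,<ch>_<index>,...`` CSV.

    All series must share one timestamp grid; missing values become
    empty cells (never zeros).
    """
    indices = list(indices)
    if not indices:
        raise ContractError("no index series to write")
    ref_t = np.asarray(indices[0].timestamps, float)
    frame = pd.DataFrame({"time": ref_t})
    for s in indices:
        t = np.asarray(s.timestamps, float)
        if t.shape != ref_t.shape or not np.allclose(t, ref_t, atol=1e-6):
            raise ContractError(
                f"index series {s.channel_id}_{s.index_type} is on a different grid"
            )
        frame[f"{s.channel_id}_{s.index_type}"] = np.asarray(s.values, float)
    path = Path(path)
    frame.to_csv(path, index=False, na_rep="")
    return path


def read_index_csv(path: str | Path) -> pd.DataFrame:
    """Read an index CSV into a DataFrame with a float ``time`` column."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise FormatError(f"{path}: index CSV lacks a 'time' column")
    return df
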