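"""Optode layouts and topographic CVR heat maps.

A layout places transmitter/receiver/reference optodes on a normalized
[0,1]^2 top-view head template and declares the channels they form:
normal channels (transmitter-receiver, 30 mm nominal separation,
cerebral + scalp sensitivity) and short channels (transmitter-reference,
10 mm, scalp only).  Two built-ins are provided:

``lobar8``
    Eight normal channels, one per lobe (frontal, parietal, temporal,
    occipital) per hemisphere, each with a short reference channel.

``grid4x4``
    Sixteen optodes in a 4x4 alternating transmitter/receiver
    checkerboard over one hemisphere; every orthogonally adjacent pair
    forms a channel, giving 24 normal channels.

Heat-map frames replay an index CSV "offline": every ``cadence``
seconds (10 s by default) each channel is drawn at its
transmitter-receiver midpoint, colored by its most recent index value
through a symmetric diverging colormap — Blue = -1 (intact
reactivity) to Red = +1 (impaired), gray for missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .errors import ContractError, DomainError, FormatError
from .io_streams import read_index_csv

__all__ = [
    "Optode",
    "Channel",
    "OptodeLayout",
    "HeatMapFrame",
    "build_layout",
    "enumerate_grid_channels",
    "index_to_color",
    "render_frames",
    "BUILTIN_LAYOUTS",
]

ROLES = ("transmitter", "receiver", "reference")
NORMAL_SEPARATION_MM = 30.0
SHORT_SEPARATION_MM = 10.0
MISSING_COLOR = (0.6, 0.6, 0.6)
DEFAULT_CMAP = "bwr"  # symmetric blue-white-red diverging map


@dataclass(frozen=True)
class Optode:
    id: str
    role: str
    position: tuple[float, float]  # normalized (x, y) on the template
    hemisphere: str = ""


@dataclass(frozen=True)
class Channel:
    channel_id: str
    tx_id: str
    rx_id: str
    kind: str = "normal"  # "normal" | "short"
    separation_mm: float = NORMAL_SEPARATION_MM


@dataclass
class OptodeLayout:
    layout_id: str
    optodes: list[Optode]
    channels: list[Channel]
    template: str = "head-outline-v1"

    def __post_init__(self):
        by_id = {}
        for o in self.optodes:
            if o.role not in ROLES:
                raise ContractError(f"optode {o.id}: unknown role {o.role!r}")
            if o.id in by_id:
                raise ContractError(f"duplicate optode id {o.id!r}")
            by_id[o.id] = o
        seen = set()
        for ch in self.channels:
            if ch.channel_id in seen:
                raise ContractError(f"duplicate channel id {ch.channel_id!r}")
            seen.add(ch.channel_id)
            if ch.tx_id not in by_id or ch.rx_id not in by_id:
                raise ContractError(
                    f"channel {ch.channel_id}: endpoint references unknown optode"
                )
            tx, rx = by_id[ch.tx_id], by_id[ch.rx_id]
            if tx.role != "transmitter":
                raise ContractError(
                    f"channel {ch.channel_id}: tx optode {tx.id} has role {tx.role!r}"
                )
            want_rx = "receiver" if ch.kind == "normal" else "reference"
            if rx.role != want_rx:
                raise ContractError(
                    f"channel {ch.channel_id} ({ch.kind}): rx optode {rx.id} "
                    f"has role {rx.role!r}, expected {want_rx!r}"
                )
            want_sep = NORMAL_SEPARATION_MM if ch.kind == "normal" else SHORT_SEPARATION_MM
            if abs(ch.separation_mm - want_sep) > 1e-9:
                raise ContractError(
                    f"channel {ch.channel_id} ({ch.kind}): nominal separation must "
                    f"be {want_sep:g} mm, got {ch.separation_mm:g}"
                )
        self._optodes_by_id = by_id

    def optode(self, oid: str) -> Optode:
        return self._optodes_by_id[oid]

    def normal_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.kind == "normal"]

    def channel_midpoint(self, ch: Channel) -> tuple[float, float]:
        a = self.optode(ch.tx_id).position
        b = self.optode(ch.rx_id).position
        return ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "layout_id": self.layout_id,
            "template": self.template,
            "optodes": [
                {"id": o.id, "role": o.role, "position": list(o.position),
                 "hemisphere": o.hemisphere}
                for o in self.optodes
            ],
            "channels": [
                {"channel_id": c.channel_id, "tx_id": c.tx_id, "rx_id": c.rx_id,
                 "kind": c.kind, "separation_mm": c.separation_mm}
                for c in self.channels
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(doc, indent=1))
        return path


# ---------------------------------------------------------------------------
# built-ins


def enumerate_grid_channels(rows: int, cols: int) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Orthogonally adjacent optode pairs of a ``rows x cols`` checkerboard.

    With alternating transmitter/receiver roles every orthogonal
    neighbor pair is a valid channel; the count is
    ``rows*(cols-1) + cols*(rows-1)``.  Pairs are listed row-major,
    horizontal neighbors first, then vertical.
    """
    if rows < 1 or cols < 1:
        raise DomainError("rows and cols must be >= 1")
    pairs = []
    for r in range(rows):
        for c in range(cols - 1):
            pairs.append(((r, c), (r, c + 1)))
    for r in range(rows - 1):
        for c in range(cols):
            pairs.append(((r, c), (r + 1, c)))
    return pairs


def _grid_role(r: int, c: int) -> str:
    return "transmitter" if (r + c) % 2 == 0 else "receiver"


def _builtin_grid4x4() -> OptodeLayout:
    rows = cols = 4
    xs = np.linspace(0.14, 0.44, cols)  # left hemisphere
    ys = np.linspace(0.68, 0.26, rows)  # anterior (top) to posterior
    optodes = [
        Optode(
            id=f"O{r}{c}",
            role=_grid_role(r, c),
            position=(float(xs[c]), float(ys[r])),
            hemisphere="left",
        )
        for r in range(rows)
        for c in range(cols)
    ]
    channels = []
    for i, (a, b) in enumerate(enumerate_grid_channels(rows, cols), start=1):
        pa, pb = f"O{a[0]}{a[1]}", f"O{b[0]}{b[1]}"
        if _grid_role(*a) != "transmitter":
            pa, pb = pb, pa
        channels.append(Channel(channel_id=f"ch{i}", tx_id=pa, rx_id=pb))
    return OptodeLayout("grid4x4", optodes, channels)


# (hemisphere, lobe, center-x-left, center-y); x mirrored for the right side
_LOBES = [
    ("frontal", 0.35, 0.72),
    ("parietal", 0.34, 0.52),
    ("temporal", 0.17, 0.44),
    ("occipital", 0.36, 0.26),
]


def _builtin_lobar8() -> OptodeLayout:
    optodes: list[Optode] = []
    channels: list[Channel] = []
    # ch1..ch4 left hemisphere, ch5..ch8 right, frontal to occipital
    i = 0
    for hemi in ("left", "right"):
        for lobe, x_left, y in _LOBES:
            i += 1
            x = x_left if hemi == "left" else 1.0 - x_left
            tx = Optode(f"T{i}", "transmitter", (x - 0.03, y), hemi)
            rx = Optode(f"R{i}", "receiver", (x + 0.03, y), hemi)
            ref = Optode(f"S{i}", "reference", (x - 0.02, y - 0.03), hemi)
            optodes += [tx, rx, ref]
            channels.append(Channel(f"ch{i}", tx.id, rx.id, "normal", NORMAL_SEPARATION_MM))
            channels.append(
                Channel(f"ch{i}_short", tx.id, ref.id, "short", SHORT_SEPARATION_MM)
            )
    return OptodeLayout("lobar8", optodes, channels)


BUILTIN_LAYOUTS = {"lobar8": _builtin_lobar8, "grid4x4": _builtin_grid4x4}


def build_layout(spec: str | Path | Mapping) -> OptodeLayout:
    """Build and validate a layout from a built-in name, JSON file or dict."""
    if isinstance(spec, str) and spec in BUILTIN_LAYOUTS:
        return BUILTIN_LAYOUTS[spec]()
    if isinstance(spec, (str, Path)):
        try:
            doc = json.loads(Path(spec).read_text())
        except OSError as e:
            raise FormatError(f"cannot read layout {spec!r}: {e}") from e
        except json.JSONDecodeError as e:
            raise FormatError(f"layout {spec!r} is not valid JSON: {e}") from e
        return build_layout(doc)
    doc = dict(spec)
    try:
        optodes = [
            Optode(
                id=o["id"],
                role=o["role"],
                position=tuple(float(v) for v in o["position"]),
                hemisphere=o.get("hemisphere", ""),
            )
            for o in doc["optodes"]
        ]
        channels = [
            Channel(
                channel_id=c["channel_id"],
                tx_id=c["tx_id"],
                rx_id=c["rx_id"],
                kind=c.get("kind", "normal"),
                separation_mm=float(
                    c.get(
                        "separation_mm",
                        NORMAL_SEPARATION_MM
                        if c.get("kind", "normal") == "normal"
                        else SHORT_SEPARATION_MM,
                    )
                ),
            )
            for c in doc["channels"]
        ]
    except KeyError as e:
        raise FormatError(f"layout document missing required key {e}") from e
    return OptodeLayout(
        layout_id=doc.get("layout_id", "custom"),
        optodes=optodes,
        channels=channels,
        template=doc.get("template", "head-outline-v1"),
    )


# ---------------------------------------------------------------------------
# colors and frames


def index_to_color(
    value: float, cmap: str = DEFAULT_CMAP, missing_color=MISSING_COLOR
) -> tuple[float, float, float]:
    """Map an index in [-1, +1] to RGB via a diverging blue-white-red map.

    -1 maps to the pure-blue endpoint (intact reactivity), +1 to the
    pure-red endpoint (impaired), 0 to the neutral midpoint; values are
    clamped to [-1, +1] and missing (NaN/None) maps to a fixed gray.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return tuple(missing_color)
    v = float(np.clip(value, -1.0, 1.0))
    if cmap == DEFAULT_CMAP:
        # exact linear blue-white-red ramp (no lookup-table quantization,
        # so color(-v) is the exact hue mirror of color(+v))
        if v <= 0.0:
            return (1.0 + v, 1.0 + v, 1.0)
        return (1.0, 1.0 - v, 1.0 - v)
    r, g, b, _ = colormaps[cmap]((v + 1.0) / 2.0)
    return (r, g, b)


@dataclass
class HeatMapFrame:
    """One timed per-channel color assignment, renderable as an image."""

    timestamp: float
    index_type: str
    values: dict[str, float]
    colors: dict[str, tuple[float, float, float]]
    raster: np.ndarray | None = None


def _head_outline(n: int = 120) -> np.ndarray:
    """Cosmetic top-view head polygon: ellipse plus a nose wedge."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = 0.5 + 0.44 * np.sin(th)
    y = 0.5 + 0.46 * np.cos(th)
    pts = np.column_stack([x, y])
    nose = np.array([[0.47, 0.958], [0.5, 1.0], [0.53, 0.958]])
    k = int(np.argmin(np.abs(th)))  # insert at the anterior pole
    return np.vstack([pts[: k + 1], nose, pts[k + 1 :]])


def _available_index_types(df: pd.DataFrame) -> set[str]:
    from .cvr_engine import INDEX_TYPES

    return {t for t in INDEX_TYPES for c in df.columns if c.endswith("_" + t)}


def frame_values(
    df: pd.DataFrame,
    channel_ids: Sequence[str],
    index_type: str,
    cadence: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tick, per-channel index values for the replay.

    Ticks run from the CSV's first to last timestamp inclusive, every
    ``cadence`` seconds.  Each channel shows its most recent value at or
    before the tick (last observation carried forward), going missing
    when the latest value is older than one cadence interval.
    Returns ``(ticks, matrix)`` with ``matrix[i, j]`` the value of
    channel ``j`` at tick ``i``.
    """
    t = df["time"].to_numpy(float)
    nticks = int(np.floor((t[-1] - t[0]) / cadence + 1e-9)) + 1
    ticks = t[0] + cadence * np.arange(nticks)
    mat = np.full((nticks, len(channel_ids)), np.nan)
    for j, cid in enumerate(channel_ids):
        col = f"{cid}_{index_type}"
        if col not in df.columns:
            continue
        vals = df[col].to_numpy(float)
        idx = np.searchsorted(t, ticks + 1e-9) - 1
        ok = (idx >= 0) & (ticks - t[np.clip(idx, 0, len(t) - 1)] <= cadence + 1e-9)
        mat[ok, j] = vals[idx[ok]]
    return ticks, mat


def render_frames(
    indices: str | Path | pd.DataFrame,
    layout: OptodeLayout | str,
    index_type: str,
    cadence: float = 10.0,
    out_dir: str | Path | None = None,
    gif_path: str | Path | None = None,
    cmap: str = DEFAULT_CMAP,
    marker_size: float = 900.0,
) -> list[HeatMapFrame]:
    """Replay an index CSV as timed heat-map frames on the brain template.

    Each normal channel is drawn as a filled disc at its
    transmitter-receiver midpoint, colored by :func:`index_to_color`.
    When ``out_dir`` is given, frames are also written as numbered PNG
    files (and optionally combined into an animated GIF).
    """
    if isinstance(layout, str):
        layout = build_layout(layout)
    df = indices if isinstance(indices, pd.DataFrame) else read_index_csv(indices)
    avail = _available_index_types(df)
    if index_type not in avail:
        raise DomainError(
            f"index type {index_type!r} not present in the index file; "
            f"available: {sorted(avail) or 'none'}"
        )

    chans = layout.normal_channels()
    cids = [c.channel_id for c in chans]
    ticks, mat = frame_values(df, cids, index_type, cadence)

    render = out_dir is not None or gif_path is not None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    frames: list[HeatMapFrame] = []
    images = []
    outline = _head_outline()
    midpoints = np.array([layout.channel_midpoint(c) for c in chans])
    for i, tick in enumerate(ticks):
        values = {cid: float(mat[i, j]) for j, cid in enumerate(cids)}
        colors = {cid: index_to_color(values[cid], cmap) for cid in cids}
        frame = HeatMapFrame(float(tick), index_type, values, colors)
        if render:
            frame.raster = _draw_frame(
                outline, midpoints, [colors[c] for c in cids], tick, index_type,
                cmap, marker_size,
            )
            if out_dir is not None:
                _save_png(out_dir / f"frame_{i:04d}.png", frame.raster)
            if gif_path is not None:
                images.append(frame.raster)
        frames.append(frame)

    if gif_path is not None and images:
        from PIL import Image

        pil = [Image.fromarray(im) for im in images]
        pil[0].save(
            Path(gif_path), save_all=True, append_images=pil[1:],
            duration=200, loop=0,
        )
    return frames


def _draw_frame(outline, midpoints, colors, tick, index_type, cmap, marker_size):
    fig = Figure(figsize=(5, 5), dpi=100)
    canvas = FigureCanvasAgg(fig)
    ax = fig.add_axes([0.02, 0.02, 0.8, 0.9])
    ax.set_aspect("equal")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.06)
    ax.axis("off")
    ax.plot(outline[:, 0], outline[:, 1], color="0.2", lw=1.5)
    ax.plot([0.5, 0.5], [0.06, 0.94], color="0.8", lw=0.8)  # midline
    ax.scatter(
        midpoints[:, 0], midpoints[:, 1], s=marker_size, c=colors,
        edgecolors="0.3", linewidths=0.8, zorder=3,
    )
    ax.set_title(f"{index_type}  t = {tick:.0f} s", fontsize=11)

    import matplotlib as mpl

    cax = fig.add_axes([0.86, 0.15, 0.04, 0.7])
    mpl.colorbar.ColorbarBase(
        cax,
        cmap=colormaps[cmap],
        norm=mpl.colors.Normalize(-1.0, 1.0),
        label="CVR index  (blue = intact, red = impaired)",
    )
    canvas.draw()
    buf = np.asarray(canvas.buffer_rgba())
    return buf[:, :, :3].copy()


def _save_png(path: Path, rgb: np.ndarray) -> None:
    from PIL import Image

    Image.fromarray(rgb).save(path)
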