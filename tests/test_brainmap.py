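"""Layouts, channel enumeration, colormap and heat-map frame replay."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cvrmap import build_layout, enumerate_grid_channels, index_to_color, render_frames
from cvrmap.brainmap import MISSING_COLOR, frame_values
from cvrmap.errors import ContractError, DomainError


def test_lobar8_has_eight_normal_channels_four_per_hemisphere():
    layout = build_layout("lobar8")
    normal = layout.normal_channels()
    assert len(normal) == 8
    hemis = [layout.optode(c.tx_id).hemisphere for c in normal]
    assert hemis.count("left") == 4 and hemis.count("right") == 4
    assert all(c.separation_mm == 30.0 for c in normal)
    shorts = [c for c in layout.channels if c.kind == "short"]
    assert len(shorts) == 8 and all(c.separation_mm == 10.0 for c in shorts)


def test_grid4x4_has_24_normal_channels_on_one_hemisphere():
    layout = build_layout("grid4x4")
    assert len(layout.normal_channels()) == 24
    assert {o.hemisphere for o in layout.optodes} == {"left"}
    # every channel joins one transmitter and one receiver
    for c in layout.normal_channels():
        assert layout.optode(c.tx_id).role == "transmitter"
        assert layout.optode(c.rx_id).role == "receiver"


def test_channel_referencing_wrong_role_optode_is_rejected():
    doc = {
        "layout_id": "bad",
        "optodes": [
            {"id": "A", "role": "receiver", "position": [0.2, 0.5]},
            {"id": "B", "role": "receiver", "position": [0.3, 0.5]},
        ],
        "channels": [{"channel_id": "ch1", "tx_id": "A", "rx_id": "B"}],
    }
    with pytest.raises(ContractError, match="role"):
        build_layout(doc)


def test_layout_json_round_trip(tmp_path):
    layout = build_layout("lobar8")
    path = layout.to_json(tmp_path / "lobar8.json")
    back = build_layout(path)
    assert back.layout_id == layout.layout_id
    assert back.channels == layout.channels
    assert back.optodes == layout.optodes


def _brute_force_adjacent_pairs(r, c):
    count = 0
    for i in range(r):
        for j in range(c):
            for di, dj in ((0, 1), (1, 0)):
                if i + di < r and j + dj < c:
                    count += 1
    return count


@settings(derandomize=True, max_examples=36, deadline=None)
@given(r=st.integers(1, 6), c=st.integers(1, 6))
def test_grid_channel_count_matches_closed_form_and_brute_force(r, c):
    pairs = enumerate_grid_channels(r, c)
    assert len(pairs) == r * (c - 1) + c * (r - 1)
    assert len(pairs) == _brute_force_adjacent_pairs(r, c)


@pytest.mark.parametrize("r,c,n", [(4, 4, 24), (2, 2, 4), (1, 2, 1)])
def test_grid_channel_count_examples(r, c, n):
    assert len(enumerate_grid_channels(r, c)) == n


def test_colormap_endpoints_midpoint_and_missing():
    assert index_to_color(-1.0) == pytest.approx((0.0, 0.0, 1.0))  # blue = intact
    assert index_to_color(+1.0) == pytest.approx((1.0, 0.0, 0.0))  # red = impaired
    assert index_to_color(0.0) == pytest.approx((1.0, 1.0, 1.0), abs=0.01)
    assert index_to_color(float("nan")) == MISSING_COLOR
    assert index_to_color(None) == MISSING_COLOR
    # out-of-range values clamp to the endpoints
    assert index_to_color(3.0) == index_to_color(1.0)
    assert index_to_color(-3.0) == index_to_color(-1.0)


def test_colormap_symmetry_under_sign_flip():
    for v in np.linspace(0.0, 1.0, 11):
        pos = index_to_color(float(v))
        neg = index_to_color(float(-v))
        assert neg == pytest.approx(pos[::-1], abs=1e-9)  # hue-mirrored


def _index_df(n_ch=8, t0=0.0, t1=100.0, value=None):
    t = np.arange(t0, t1 + 1e-9, 10.0)
    rng = np.random.default_rng(4)
    df = {"time": t}
    for c in range(n_ch):
        v = rng.uniform(-1, 1, t.size) if value is None else np.full(t.size, value)
        df[f"ch{c+1}_tHbx"] = v
    return pd.DataFrame(df)


def test_frame_count_over_inclusive_span():
    frames = render_frames(_index_df(), "lobar8", "tHbx", cadence=10.0)
    assert len(frames) == 11  # 0..100 s inclusive at 10-s cadence


def test_constant_plus_one_paints_every_marker_red():
    frames = render_frames(_index_df(value=1.0), "lobar8", "tHbx")
    for f in frames:
        assert all(c == pytest.approx((1.0, 0.0, 0.0)) for c in f.colors.values())


def test_channel_without_data_stays_gray_in_every_frame():
    df = _index_df(n_ch=7)  # ch8 column absent
    frames = render_frames(df, "lobar8", "tHbx")
    assert all(f.colors["ch8"] == MISSING_COLOR for f in frames)
    assert all(np.isnan(f.values["ch8"]) for f in frames)


def test_stale_values_beyond_one_cadence_interval_go_missing():
    df = pd.DataFrame({"time": [0.0, 10.0, 50.0], "ch1_tHbx": [0.5, 0.7, 0.2]})
    ticks, mat = frame_values(df, ["ch1"], "tHbx", cadence=10.0)
    assert mat[0, 0] == 0.5 and mat[1, 0] == 0.7
    assert mat[2, 0] == 0.7  # carried forward exactly one interval
    assert np.isnan(mat[3, 0]) and np.isnan(mat[4, 0])  # older than one interval
    assert mat[5, 0] == 0.2


def test_frame_values_are_deterministic():
    df = _index_df()
    _, m1 = frame_values(df, [f"ch{i+1}" for i in range(8)], "tHbx", 10.0)
    _, m2 = frame_values(df, [f"ch{i+1}" for i in range(8)], "tHbx", 10.0)
    assert np.array_equal(m1, m2, equal_nan=True)


def test_absent_index_type_error_lists_available(tmp_path):
    with pytest.raises(DomainError, match="tHbx"):
        render_frames(_index_df(), "lobar8", "COx")


def test_rendered_frames_written_as_png(tmp_path):
    frames = render_frames(
        _index_df(t1=20.0), "lobar8", "tHbx", out_dir=tmp_path / "frames",
        gif_path=tmp_path / "anim.gif",
    )
    pngs = sorted((tmp_path / "frames").glob("frame_*.png"))
    assert len(pngs) == len(frames) == 3
    assert (tmp_path / "anim.gif").exists()
    assert frames[0].raster is not None and frames[0].raster.ndim == 3
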