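"""Decimation, Pearson, and sliding-index engine against independent oracles."""


import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cvrmap import (
    ChannelSignals,
    EngineConfig,
    MultiChannelRecord,
    TimeSeries,
    compute_all_indices,
    decimate,
    pearson,
    sliding_index,
)
from cvrmap.errors import ConfigurationError, ContractError


def _ts(vals, rate=1.0, start=0.0):
    return TimeSeries(np.asarray(vals, float), rate=rate, start_time=start)


# ---------------------------------------------------------------------------
# decimate


def test_decimate_constant_and_hand_computed_means():
    out = decimate(_ts(np.full(5000, 5.0), rate=250.0), 10.0)
    assert np.array_equal(out.values, [5.0, 5.0])
    out = decimate(_ts(np.arange(20.0), rate=1.0), 10.0)
    assert np.array_equal(out.values, [4.5, 14.5])
    assert np.array_equal(out.timestamps, [10.0, 20.0])  # right edges
    assert out.rate == pytest.approx(0.1)


def test_decimate_drops_incomplete_trailing_window():
    out = decimate(_ts(np.arange(25.0), rate=1.0), 10.0)
    assert out.n == 2  # the 5 trailing samples form no complete window


@pytest.mark.parametrize("phase", [0.0, 0.7, 2.1])
@pytest.mark.parametrize("amp", [1.0, 50.0])
def test_decimate_nulls_full_period_oscillations(phase, amp):
    # 0.1 Hz completes exactly one period per 10-s window: the uniform-
    # sample mean is analytically zero (Mayer-wave rejection).
    t = np.arange(250 * 60) / 250.0
    s = _ts(amp * np.sin(2 * np.pi * 0.1 * t + phase), rate=250.0)
    out = decimate(s, 10.0)
    assert np.max(np.abs(out.values)) < 1e-9 * amp


def test_decimate_missing_fraction_policy():
    vals = np.arange(20.0)
    vals[:4] = np.nan  # window 1: 40% missing -> keep; 60% missing -> drop
    out = decimate(_ts(vals, rate=1.0), 10.0, min_valid_fraction=0.5)
    assert out.values[0] == pytest.approx(np.nanmean(vals[:10]))
    vals[:6] = np.nan
    out = decimate(_ts(vals, rate=1.0), 10.0, min_valid_fraction=0.5)
    assert np.isnan(out.values[0]) and out.values[1] == 14.5


def test_decimate_rejects_window_below_two_sample_periods():
    with pytest.raises(ConfigurationError):
        decimate(_ts(np.arange(100.0), rate=0.1), 10.0)


# ---------------------------------------------------------------------------
# pearson


def test_pearson_known_values():
    assert pearson([1, 2, 3], [2, 4, 6]) == 1.0
    assert pearson([1, 2, 3], [3, 2, 1]) == -1.0
    # direct product-moment evaluation gives exactly 0.8
    assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-15)


def test_pearson_zero_variance_is_missing_not_error():
    assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
    assert np.isnan(pearson([1.0, 2.0, 3.0], [7.0, 7.0, 7.0]))


def test_pearson_contract_errors():
    with pytest.raises(ContractError):
        pearson([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ContractError):
        pearson([1.0, 2.0, 3.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# sliding_index


def _dec(vals, start=10.0):
    return TimeSeries(np.asarray(vals, float), rate=0.1, start_time=start)


def test_sliding_window_count_and_timestamps():
    rng = np.random.default_rng(0)
    x, y = _dec(rng.normal(size=40)), _dec(rng.normal(size=40))
    out = sliding_index(x, y, EngineConfig())
    assert out.n == 11  # 40 - 30 + 1
    assert out.timestamps[0] == pytest.approx(10.0 + 29 * 10.0)
    assert np.all(np.diff(out.timestamps) == pytest.approx(10.0))


def test_sliding_index_of_affine_surrogate_is_exactly_one():
    y = _dec(90.0 + np.sin(np.arange(45)))
    x = _dec(2.0 * y.values + 5.0)
    out = sliding_index(x, y)
    assert out.values == pytest.approx(np.ones(16), abs=1e-12)
    out_neg = sliding_index(_dec(-3.0 * y.values + 40.0), y)
    assert out_neg.values == pytest.approx(-np.ones(16), abs=1e-12)


def test_sliding_index_missing_mean_invalidates_whole_window():
    rng = np.random.default_rng(1)
    y = _dec(rng.normal(size=40))
    xv = rng.normal(size=40)
    xv[31] = np.nan
    out = sliding_index(_dec(xv), y, EngineConfig())  # all 30 means required
    hit_any = False
    for i in range(out.n):
        in_window = 31 in range(i, i + 30)
        hit_any = hit_any or in_window
        assert np.isnan(out.values[i]) == in_window
    assert hit_any


def test_sliding_index_partial_validity_policy():
    rng = np.random.default_rng(2)
    y = _dec(rng.normal(size=40))
    xv = rng.normal(size=40)
    xv[5] = np.nan
    cfg = EngineConfig(min_valid_means_per_window=29)
    out = sliding_index(_dec(xv), y, cfg)
    assert not np.isnan(out.values).any()
    # windows containing the gap must equal pairwise-deleted recomputation
    ok = ~np.isnan(xv[:30])
    expect = stats.pearsonr(xv[:30][ok], y.values[:30][ok]).statistic
    assert out.values[0] == pytest.approx(expect, abs=1e-12)


def test_sliding_index_short_overlap_warns_and_is_empty():
    x, y = _dec(np.arange(10.0)), _dec(np.arange(10.0))
    with pytest.warns(UserWarning, match="correlation window"):
        out = sliding_index(x, y)
    assert out.n == 0


def test_sliding_index_matches_naive_two_pass_oracle():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n = int(rng.integers(30, 80))
        base = rng.normal(90.0, 4.0, n)
        x = base * rng.normal(1.0, 0.3) + rng.normal(0, 1.0, n)
        y = base + rng.normal(0, 2.0, n)
        out = sliding_index(_dec(x), _dec(y))
        for i, v in enumerate(out.values):
            expect = stats.pearsonr(x[i : i + 30], y[i : i + 30]).statistic
            assert v == pytest.approx(expect, abs=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    a=st.floats(min_value=0.01, max_value=50.0),
    b=st.floats(min_value=-100.0, max_value=100.0),
    flip=st.booleans(),
)
def test_affine_invariance_of_indices(a, b, flip):
    rng = np.random.default_rng(12)
    x = rng.normal(size=35)
    y = rng.normal(size=35)
    base = sliding_index(_dec(x), _dec(y)).values
    slope = -a if flip else a
    trans = sliding_index(_dec(slope * x + b), _dec(y)).values
    sign = -1.0 if flip else 1.0
    assert np.allclose(trans, sign * base, atol=1e-9)


def test_all_emitted_values_bounded():
    rng = np.random.default_rng(3)
    x = _dec(rng.normal(90, 0.001, 60))
    y = _dec(rng.normal(90, 0.001, 60))
    out = sliding_index(x, y)
    ok = ~np.isnan(out.values)
    assert np.all(out.values[ok] <= 1.0) and np.all(out.values[ok] >= -1.0)


# ---------------------------------------------------------------------------
# compute_all_indices


def _pure_record(n_ch=1, n=80000, hhb_zero=False):
    rng = np.random.default_rng(5)
    abp = TimeSeries(90 + rng.normal(0, 4, n // 2), rate=100.0)
    channels = {}
    for c in range(n_ch):
        hbo = TimeSeries(30 + rng.normal(0, 1, n), rate=200.0)
        hhb = TimeSeries(
            np.zeros(n) if hhb_zero else 15 + rng.normal(0, 1, n), rate=200.0
        )
        ch = ChannelSignals(f"ch{c+1}", HbO_pure=hbo, HHb_pure=hhb)
        channels[f"ch{c+1}"] = ch
    from cvrmap import preprocess_record

    rec = MultiChannelRecord(abp=abp, channels=channels, meta={"t0": 0.0})
    return preprocess_record(rec)


def test_five_indices_per_channel_by_default():
    out = compute_all_indices(_pure_record(n_ch=1))
    assert len(out) == 5
    assert {s.index_type for s in out} == {"HbOx", "HHbx", "tHbx", "HbDiffx", "COx"}
    out8 = compute_all_indices(_pure_record(n_ch=8))
    assert len(out8) == 40


def test_zero_hhb_makes_volume_indices_coincide():
    out = {s.index_type: s for s in compute_all_indices(_pure_record(hhb_zero=True))}
    assert np.allclose(out["tHbx"].values, out["HbOx"].values, equal_nan=True)
    assert np.allclose(out["HbDiffx"].values, out["HbOx"].values, equal_nan=True)


def test_missing_trace_warns_and_skips_index():
    rec = _pure_record()
    rec.channels["ch1"].rSO2 = None
    with pytest.warns(UserWarning, match="COx skipped"):
        out = compute_all_indices(rec)
    assert len(out) == 4
    assert "COx" not in {s.index_type for s in out}
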