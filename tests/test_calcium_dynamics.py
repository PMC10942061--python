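import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betacal import calcium_dynamics as cad
from betacal import synth
from betacal.errors import AlignmentError, NoBackgroundError
from betacal.io_stack import FrameStack
from betacal.segment import LabelMask
from betacal.tracks import measure_tracks


def trace_table(traces: dict[int, list[float]]) -> pd.DataFrame:
    rows = [
        (tid, f, v, 10, 0.0, 0.0)
        for tid, vals in traces.items()
        for f, v in enumerate(vals)
    ]
    return pd.DataFrame(
        rows,
        columns=["TRACK_ID", "FRAME", "MEAN_INTENSITY", "AREA", "POSITION_X", "POSITION_Y"],
    )


# --- background sampling ---------------------------------------------------

def test_sampling_deterministic_per_seed(small_stack):
    mask = LabelMask(np.zeros((16, 16), dtype=int))
    a = cad.sample_background(small_stack, mask, n=100, seed=5)
    b = cad.sample_background(small_stack, mask, n=100, seed=5)
    np.testing.assert_array_equal(a.pixel_coords, b.pixel_coords)
    c = cad.sample_background(small_stack, mask, n=100, seed=6)
    assert not np.array_equal(a.pixel_coords, c.pixel_coords)


def test_sampling_avoids_rois_and_is_unique(small_stack):
    mask = np.zeros((16, 16), dtype=int)
    mask[:8, :] = 1  # half the image is one big cell
    bg = cad.sample_background(small_stack, LabelMask(mask), n=100, seed=0)
    assert len(bg.pixel_coords) == 100
    assert all(mask[r, c] == 0 for r, c in bg.pixel_coords)
    assert len({tuple(rc) for rc in bg.pixel_coords}) == 100


def test_sampling_short_supply_warns(small_stack, caplog):
    mask = np.ones((16, 16), dtype=int)
    mask[0, :8] = 0  # only 8 background pixels
    with caplog.at_level(logging.WARNING, logger="betacal.calcium_dynamics"):
        bg = cad.sample_background(small_stack, LabelMask(mask), n=100, seed=0)
    assert len(bg.pixel_coords) == 8
    assert any("8 background pixels" in r.message for r in caplog.records)


def test_sampling_no_background_error(small_stack):
    with pytest.raises(NoBackgroundError):
        cad.sample_background(small_stack, LabelMask(np.ones((16, 16), dtype=int)), 10, 0)


def test_constant_background_mean():
    stack = FrameStack(np.full((5, 8, 8), 200.0))
    bg = cad.sample_background(stack, LabelMask(np.zeros((8, 8), dtype=int)), 20, 1)
    np.testing.assert_array_equal(bg.per_frame_mean, np.full(5, 200.0))


def test_subtraction_arithmetic_and_identity():
    table = trace_table({1: [500.0, 500.0, 500.0, 500.0]})
    bg = cad.BackgroundSample(np.zeros((1, 2), int), np.array([0.0, 0.0, 0.0, 200.0]))
    out = cad.subtract_background(table, bg)
    assert out.query("FRAME == 3")["MEAN_INTENSITY"].iloc[0] == 300.0
    zero = cad.BackgroundSample(np.zeros((1, 2), int), np.zeros(4))
    pd.testing.assert_frame_equal(cad.subtract_background(table, zero), table)


def test_subtraction_frame_mismatch():
    table = trace_table({1: [1.0] * 5})
    bg = cad.BackgroundSample(np.zeros((1, 2), int), np.zeros(3))
    with pytest.raises(AlignmentError):
        cad.subtract_background(table, bg)


def test_subtraction_recovers_synth_truth():
    """With offset b=200 and read noise sigma=5, subtracted traces sit within
    3*sigma/sqrt(100) + per-cell noise of the noise-free truth on average."""
    params = synth.SynthParams(
        background_offset=200.0, read_noise_sd=5.0, seed=9, n_cells=12
    )
    stack, _, truth = synth.generate_movie(params)
    table = measure_tracks(stack, truth.true_mask)
    bg = cad.sample_background(stack, truth.true_mask, 100, seed=2)
    sub = cad.subtract_background(table, bg)
    for tid, g in sub.sort_values("FRAME").groupby("TRACK_ID"):
        measured = g["MEAN_INTENSITY"].to_numpy()
        expected = truth.noise_free_traces[tid - 1] - 200.0
        area = (truth.true_mask.labels == tid).sum()
        tol = 3 * 5.0 / np.sqrt(100) + 3 * 5.0 / np.sqrt(area)
        assert np.mean(np.abs(measured - expected)) < tol


# --- normalization ---------------------------------------------------------

def test_baseline_hand_example():
    raw = [100.0, 105.0, 115.0, 120.0, 110.0]
    (tr,) = cad.normalize_traces(trace_table({1: raw}), threshold_pct=10)
    assert tr.baseline_n == 2
    assert tr.baseline == pytest.approx(102.5)
    np.testing.assert_allclose(tr.values[:3], [0.97561, 1.02439, 1.12195], atol=1e-4)
    np.testing.assert_allclose(tr.values * tr.baseline, raw, rtol=1e-12)


def test_no_crossing_uses_whole_trace_mean():
    (tr,) = cad.normalize_traces(trace_table({1: [100.0] * 25}), threshold_pct=10)
    assert tr.baseline_n == 25
    assert tr.baseline == 100.0
    np.testing.assert_array_equal(tr.values, np.ones(25))


def test_downward_crossing_counts():
    """The crossing test is a change in either direction."""
    raw = [100.0, 95.0, 85.0, 90.0]
    (tr,) = cad.normalize_traces(trace_table({1: raw}), threshold_pct=10)
    assert tr.baseline_n == 2  # 85 is a 15% drop
    assert tr.baseline == pytest.approx(97.5)


@pytest.mark.parametrize("c", [0.1, 1.0, 7.0, 100.0])
def test_scale_invariance(c):
    raw = [100.0, 105.0, 115.0, 108.0, 130.0, 95.0]
    (base,) = cad.normalize_traces(trace_table({1: raw}), 10)
    (scaled,) = cad.normalize_traces(trace_table({1: [c * v for v in raw]}), 10)
    np.testing.assert_allclose(scaled.values, base.values, rtol=1e-12)
    assert scaled.baseline_n == base.baseline_n


def test_zero_first_point_falls_back():
    (tr,) = cad.normalize_traces(trace_table({1: [0.0, 50.0, 100.0]}), 10)
    assert tr.baseline == pytest.approx(50.0)  # whole-trace mean
    assert tr.valid


def test_nonpositive_baseline_invalid():
    (tr,) = cad.normalize_traces(trace_table({1: [-5.0, -5.0, -5.0]}), 10)
    assert not tr.valid
    assert cad.detect_spikes(tr) == []


# --- spike detection -------------------------------------------------------

def make_trace(values, track_id=1):
    v = np.asarray(values, dtype=float)
    return cad.NormalizedTrace(track_id, v, 1.0, 1, v, True)


def test_single_step_rule_hand_example():
    calls = cad.detect_spikes(make_trace([1.0, 1.15, 1.0]))
    assert len(calls) == 1
    (c,) = calls
    assert (c.peak_frame, c.rule) == (1, "single_step")
    assert c.magnitude_pct == pytest.approx(15.0)


def test_cumulative_rule_hand_example():
    calls = cad.detect_spikes(make_trace([1.0, 1.04, 1.09, 1.15, 1.0]))
    assert len(calls) == 1
    (c,) = calls
    assert c.rule == "cumulative"
    assert c.peak_frame == 3
    # 4.0% + 4.807...% + 5.504...% = 14.31...%
    assert c.magnitude_pct == pytest.approx(14.3119, abs=1e-3)


def test_constant_trace_no_spikes():
    assert cad.detect_spikes(make_trace([1.0] * 25)) == []


def test_rising_final_frame_counts_as_peak():
    calls = cad.detect_spikes(make_trace([1.0, 1.0, 1.2]))
    assert [c.peak_frame for c in calls] == [2]


def test_plateau_reports_first_index():
    calls = cad.detect_spikes(make_trace([1.0, 1.2, 1.2, 1.0]))
    assert [c.peak_frame for c in calls] == [1]


def test_cumulative_window_resets_at_trough():
    # rise 8%, drop, rise 8%: neither window alone reaches 10%
    calls = cad.detect_spikes(make_trace([1.0, 1.08, 1.0, 1.08, 1.0]))
    assert calls == []


def test_spike_calls_scale_invariant_end_to_end():
    raw = [100.0, 101.0, 118.0, 102.0, 100.0, 125.0, 99.0]
    for c in (0.5, 1.0, 20.0):
        table = trace_table({1: [c * v for v in raw]})
        (tr,) = cad.normalize_traces(table, 10)
        calls = cad.detect_spikes(tr, 10)
        assert [(s.peak_frame, s.rule) for s in calls] == [(2, "single_step"), (5, "single_step")]


def test_threshold_monotonicity_random_traces(rng):
    for _ in range(50):
        v = np.round(1.0 + 0.1 * rng.standard_normal(25).cumsum() * 0.1 + 0.2 * rng.random(25), 3)
        v = np.abs(v) + 0.5
        counts = [
            len(cad.detect_spikes(make_trace(v), thr)) for thr in (5, 10, 15, 20)
        ]
        assert counts == sorted(counts, reverse=True)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    raw=st.lists(st.floats(10.0, 1000.0, allow_nan=False), min_size=2, max_size=30),
    c=st.floats(0.01, 1000.0),
)
def test_scale_invariance_property(raw, c):
    """Normalized values and spike calls are invariant to trace scaling."""
    (base,) = cad.normalize_traces(trace_table({1: raw}), 10)
    (scaled,) = cad.normalize_traces(trace_table({1: [c * v for v in raw]}), 10)
    assert scaled.baseline_n == base.baseline_n
    assert scaled.valid == base.valid
    if base.valid:
        np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9)
        a = [(s.peak_frame, s.rule) for s in cad.detect_spikes(base, 10)]
        b = [(s.peak_frame, s.rule) for s in cad.detect_spikes(scaled, 10)]
        assert a == b


@settings(deadline=None, derandomize=True, max_examples=200)
@given(v=st.lists(st.floats(0.5, 2.0, allow_nan=False), min_size=2, max_size=30))
def test_threshold_monotonicity_property(v):
    trace = make_trace(v)
    counts = [len(cad.detect_spikes(trace, thr)) for thr in (5.0, 10.0, 15.0, 20.0)]
    assert counts == sorted(counts, reverse=True)


def test_active_cells():
    calls = [
        cad.SpikeCall(2, 3, "single_step", 12.0),
        cad.SpikeCall(2, 9, "cumulative", 11.0),
        cad.SpikeCall(5, 4, "single_step", 20.0),
    ]
    assert cad.active_cells(calls) == {2, 5}
    assert cad.active_cells([]) == set()


def test_active_cells_end_to_end_on_schedule():
    schedule = (
        synth.SpikeEvent(1, 10, 0.25),
        synth.SpikeEvent(3, 15, 0.25),
    )
    params = synth.SynthParams(n_cells=6, spike_schedule=schedule, seed=4)
    stack, _, truth = synth.generate_movie(params)
    table = measure_tracks(stack, truth.true_mask)
    bg = cad.sample_background(stack, truth.true_mask, 100, 0)
    traces = cad.normalize_traces(cad.subtract_background(table, bg), 10)
    calls = [s for t in traces for s in cad.detect_spikes(t, 10)]
    assert cad.active_cells(calls) == {1, 3}
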