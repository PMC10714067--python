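"""Jerk computation, RMS smoothing, event detection/merging, survival curve
and event contextualization, each checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sealforage.movement import segment_dives
from sealforage.prca import (
    DetectorConfig,
    compute_jerk,
    contextualize_events,
    detect_events,
    rms_jerk,
    survival_curve,
)


# ---------------------------------------------------------------------------
# jerk

def test_jerk_of_constant_acceleration_is_zero():
    a = np.tile([1.0, -2.0, 9.8], (100, 1))
    assert np.allclose(compute_jerk(a, 250.0), 0.0)


def test_jerk_of_single_axis_ramp():
    t = np.arange(1000) / 250.0
    a = np.column_stack([2.0 * t, np.zeros_like(t), np.zeros_like(t)])
    j = compute_jerk(a, 250.0)
    assert np.allclose(j, 2.0, atol=1e-9)


def test_jerk_matches_per_sample_oracle():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(300, 3))
    fs = 200.0
    j = compute_jerk(a, fs)
    for k in range(a.shape[0] - 1):
        expected = fs * np.sqrt(((a[k + 1] - a[k]) ** 2).sum())
        assert j[k] == pytest.approx(expected)


def test_jerk_rejects_single_sample():
    with pytest.raises(ValueError):
        compute_jerk(np.zeros((1, 3)), 250.0)


# ---------------------------------------------------------------------------
# RMS

def test_rms_of_constant_and_alternating_signals():
    c = np.full(500, 7.0)
    assert np.allclose(rms_jerk(c, 250.0, 0.2), 7.0)
    alt = 7.0 * (-1.0) ** np.arange(500)
    assert np.allclose(rms_jerk(alt, 250.0, 0.2), 7.0)


def test_rms_matches_windowed_oracle():
    rng = np.random.default_rng(1)
    j = rng.exponential(size=200)
    fs, window = 100.0, 0.1
    out = rms_jerk(j, fs, window)
    half = int(round(window * fs)) // 2
    for k in range(len(j)):
        lo = max(k - half, 0)
        hi = min(k + half + 1, len(j))
        assert out[k] == pytest.approx(np.sqrt(np.mean(j[lo:hi] ** 2)))


def test_rms_rejects_oversized_window():
    with pytest.raises(ValueError):
        rms_jerk(np.ones(10), 250.0, 1.0)


# ---------------------------------------------------------------------------
# event detection

def _series(fs, segments):
    """Build an RMS series from (duration_s, value) segments."""
    return np.concatenate([np.full(int(round(d * fs)), v) for d, v in segments])


def test_single_supra_threshold_excursion():
    fs = 50.0
    r = _series(fs, [(10, 10), (6, 300), (10, 10)])
    ev = detect_events(r, fs)
    assert len(ev) == 1
    assert ev.start[0] == pytest.approx(10.0)
    assert ev.end[0] == pytest.approx(16.0)
    assert ev.peak_rms[0] == 300.0


def test_short_excursion_is_ignored():
    fs = 50.0
    r = _series(fs, [(10, 10), (3, 300), (10, 10)])
    assert len(detect_events(r, fs)) == 0


def test_nearby_excursions_merge_into_one_long_event():
    fs = 50.0
    r = _series(fs, [(10, 10), (4, 300), (3, 10), (4, 300), (10, 10)])
    ev = detect_events(r, fs)
    assert len(ev) == 1
    assert ev.duration_s[0] == pytest.approx(11.0)


def _oracle_detect(r, fs, cfg):
    """Exhaustive per-sample run scan + merge + duration filter."""
    events, in_ev, start = [], False, 0
    for i, v in enumerate(r):
        if v > cfg.threshold and not in_ev:
            in_ev, start = True, i
        elif v <= cfg.threshold and in_ev:
            events.append([start, i])
            in_ev = False
    if in_ev:
        events.append([start, len(r)])
    merged = []
    for s, e in events:
        if merged and (s - merged[-1][1]) / fs < cfg.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s / fs, e / fs) for s, e in merged
            if (e - s) / fs >= cfg.min_duration]


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(0, 100_000))
def test_detection_matches_run_scan_oracle(seed):
    rng = np.random.default_rng(seed)
    fs = 5.0
    r = rng.exponential(120.0, size=rng.integers(30, 300))
    cfg = DetectorConfig(threshold=150.0, min_duration=1.0, merge_gap=1.4)
    ev = detect_events(r, fs, cfg)
    expected = _oracle_detect(r, fs, cfg)
    assert len(ev) == len(expected)
    for (s, e), (_, row) in zip(expected, ev.iterrows()):
        assert row["start"] == pytest.approx(s)
        assert row["end"] == pytest.approx(e)


def test_threshold_monotonicity_and_merge_conservation():
    """Raising the threshold shrinks the total supra-threshold time, and on
    single-burst events (one excursion per event, as the capture signal
    model produces) it never increases the event count; merging can only
    extend, never shrink, the covered time before the duration filter."""
    rng = np.random.default_rng(7)
    fs = 5.0
    r = rng.exponential(120.0, size=2000)
    times, counts = [], []
    for thr in (50.0, 100.0, 150.0, 250.0):
        cfg = DetectorConfig(threshold=thr, min_duration=1e-9, merge_gap=1e-9)
        ev = detect_events(r, fs, cfg)
        times.append(ev["duration_s"].sum())
        counts.append(len(ev))
    assert all(a >= b for a, b in zip(times, times[1:]))

    bursts = _series(fs, [(10, 10), (6, 200), (8, 10), (6, 400), (8, 10),
                          (6, 800), (10, 10)])
    burst_counts = [len(detect_events(bursts, fs, DetectorConfig(
        threshold=t, min_duration=1e-9, merge_gap=1e-9)))
        for t in (150.0, 300.0, 600.0, 900.0)]
    assert burst_counts == sorted(burst_counts, reverse=True)

    raw = DetectorConfig(threshold=150.0, min_duration=1e-9, merge_gap=1e-9)
    merged = DetectorConfig(threshold=150.0, min_duration=1e-9, merge_gap=2.0)
    t_raw = detect_events(r, fs, raw)["duration_s"].sum()
    t_merged = detect_events(r, fs, merged)["duration_s"].sum()
    assert t_merged >= t_raw - 1e-9


def test_merging_is_idempotent():
    """Treating detected events as a new supra-threshold mask and merging
    again yields the same events."""
    rng = np.random.default_rng(11)
    fs = 10.0
    r = rng.exponential(130.0, size=1000)
    cfg = DetectorConfig()
    ev = detect_events(r, fs, cfg)
    mask = np.zeros_like(r)
    for _, row in ev.iterrows():
        mask[int(row["start"] * fs):int(row["end"] * fs)] = 1000.0
    ev2 = detect_events(mask, fs, cfg)
    assert np.allclose(ev2["start"], ev["start"])
    assert np.allclose(ev2["end"], ev["end"])


def test_detector_rejects_non_positive_threshold():
    with pytest.raises(ValueError):
        DetectorConfig(threshold=0.0)


# ---------------------------------------------------------------------------
# survival curve

def test_survival_curve_counting():
    grid, s, _ = survival_curve([1.0, 2.0, 10.0], grid=np.array([0.0, 5.0, 10.0]))
    assert s[1] == pytest.approx(1.0 / 3.0)
    grid, s, _ = survival_curve([7.0] * 5, grid=np.linspace(0, 10, 11))
    assert np.all(s[grid < 7] == 1.0)
    assert np.all(s[grid >= 7] == 0.0)


def test_survival_curve_empty():
    grid, s, thr = survival_curve([])
    assert grid.size == 0 and s.size == 0 and thr is None


def test_survival_knee_sits_between_bimodal_gap_modes():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        gaps = np.concatenate([rng.uniform(0.5, 2.0, 60),
                               rng.uniform(20.0, 40.0, 30)])
        _, _, thr = survival_curve(gaps)
        # the knee must separate the two modes: above (nearly all of) the
        # within-burst gaps and below every between-burst gap
        hits += (np.mean(gaps[:60] <= thr + 0.2) > 0.9) and np.all(gaps[60:] > thr)
    assert hits >= 18


# ---------------------------------------------------------------------------
# contextualization

def test_event_depth_and_dive_link():
    depth = np.concatenate([np.zeros(50), np.full(100, 88.0), np.zeros(50)])
    dives, _ = segment_dives(depth, fs=5)
    ev = pd.DataFrame({"event_id": [0, 1], "start": [15.0, 5.0],
                       "end": [21.0, 6.0], "duration_s": [6.0, 1.0],
                       "peak_rms": [300.0, 200.0]})
    out = contextualize_events(ev, dives, depth, fs=5)
    assert out.depth_m[0] == 88.0
    assert out.dive_id[0] == dives[0].id
    assert not out.excluded[0]
    assert out.excluded[1]  # event at the surface is excluded


def test_event_during_shallow_activity_is_excluded():
    depth = np.concatenate([np.zeros(20), np.full(60, 3.0), np.zeros(20)])
    dives, _ = segment_dives(depth, fs=5)
    ev = pd.DataFrame({"event_id": [0], "start": [8.0], "end": [14.0],
                       "duration_s": [6.0], "peak_rms": [200.0]})
    out = contextualize_events(ev, dives, depth, fs=5)
    assert out.excluded[0]


def test_event_outside_record_raises():
    depth = np.zeros(100)
    ev = pd.DataFrame({"event_id": [0], "start": [100.0], "end": [101.0],
                       "duration_s": [1.0], "peak_rms": [200.0]})
    with pytest.raises(ValueError):
        contextualize_events(ev, [], depth, fs=5)


def test_per_dive_event_counts_match_truth(small_deployment, small_result):
    _, truth = small_deployment
    ev = small_result.events
    ev_ok = ev[~ev["excluded"].astype(bool)]
    got = ev_ok.groupby("individual").size().to_dict()
    want = truth.prcas.groupby("individual").size().to_dict()
    assert got == want
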