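"""ENR computation, seafloor detection, trace extraction, reaction
classification and acoustic sizing on constructed and simulated echograms."""

import numpy as np
import pytest

from sealforage.echogram import (
    GUARD_BINS,
    Echogram,
    classify_reaction,
    compute_enr,
    detect_seafloor,
    extract_prey_traces,
    measure_acoustic_size,
    summarize_prey,
)
from sealforage.pipeline import analyze_echogram
from sealforage.simulate import simulate_echogram


def _blank(n_pings=200, n_bins=700, t0=0.0):
    return Echogram(ping_times=t0 + np.arange(n_pings) / 25.0,
                    ranges=(np.arange(n_bins) + 0.5) * 0.01,
                    enr=np.zeros((n_pings, n_bins)))


def _with_floor(eg, floor_bin=90, level=25.0):
    eg.enr[:, floor_bin - 2:floor_bin + 3] = level
    return eg


def _truth(**kw):
    base = dict(benthic=True, visible=True, reaction="none", onset_rel_s=1.0,
                onset_range_cm=60.0, size_cm=5.0, school=False,
                seafloor_range_m=0.9)
    base.update(kw)
    return base


# ---------------------------------------------------------------------------
# ENR

def test_enr_is_floored_subtraction():
    echo = np.full((10, 20), 30.0)
    noise = np.full(20, 30.0)
    eg = compute_enr(echo, noise)
    assert np.all(eg.enr == 0.0)
    echo[3, 7] += 12.0
    eg = compute_enr(echo, noise)
    assert eg.enr[3, 7] == 12.0
    assert eg.enr.sum() == 12.0


def test_enr_matches_elementwise_oracle():
    rng = np.random.default_rng(0)
    echo = rng.uniform(0, 40, (30, 50))
    noise = rng.uniform(0, 40, (30, 50))
    eg = compute_enr(echo, noise)
    assert np.allclose(eg.enr, np.maximum(echo - noise, 0.0))


def test_enr_rejects_shape_mismatch():
    with pytest.raises(ValueError):
        compute_enr(np.zeros((5, 10)), np.zeros(9))


# ---------------------------------------------------------------------------
# seafloor

def test_seafloor_found_within_two_bins():
    eg = _with_floor(_blank(), floor_bin=90)
    floor = detect_seafloor(eg)
    assert floor.present
    assert abs(np.nanmedian(floor.ranges) - 0.905) < 0.02


def test_pure_noise_window_is_pelagic():
    rng = np.random.default_rng(1)
    eg = _blank()
    eg.enr[:] = rng.exponential(1.2, eg.enr.shape)
    floor = detect_seafloor(eg)
    assert not floor.present
    assert np.all(np.isnan(floor.ranges))


def test_benthic_fraction_recovered_over_simulated_batch():
    """With 98 % of windows scheduled benthic, the detected benthic
    fraction lands within 2 points of the schedule."""
    rng = np.random.default_rng(2)
    n = 150
    benthic = rng.random(n) < 0.98
    detected = 0
    for k in range(n):
        eg = simulate_echogram(0.0, 6.0, _truth(benthic=bool(benthic[k]),
                                                visible=False),
                               rng=np.random.default_rng(k))
        detected += detect_seafloor(eg).present
    assert abs(detected / n - benthic.mean()) <= 0.02


# ---------------------------------------------------------------------------
# trace extraction

def _paint_line(eg, t_on, r_on, v, dur, size_bins=5, level=18.0):
    """Paint a linear trace r(t) = r_on - v (t - t_on) into eg."""
    for p in range(eg.enr.shape[0]):
        t = eg.ping_times[p]
        if t_on <= t <= t_on + dur:
            c = int(round((r_on - v * (t - t_on)) / 0.01))
            eg.enr[p, max(c - size_bins // 2, 0):c + size_bins // 2 + 1] = level
    return eg


def test_single_trace_extracted_as_one_target():
    eg = _with_floor(_blank())
    _paint_line(eg, 2.0, 0.60, 0.12, 3.0)
    traces = extract_prey_traces(eg, detect_seafloor(eg))
    assert len(traces) == 1
    assert traces[0].n_targets == "one"


def test_overlapping_traces_flagged_as_several():
    eg = _with_floor(_blank())
    _paint_line(eg, 2.0, 0.60, 0.12, 3.0)
    _paint_line(eg, 2.0, 0.40, 0.12, 3.0)
    traces = extract_prey_traces(eg, detect_seafloor(eg))
    assert len(traces) == 2
    assert all(t.n_targets == "several" for t in traces)


def test_noise_only_yields_no_traces():
    rng = np.random.default_rng(3)
    eg = _with_floor(_blank())
    eg.enr += rng.exponential(1.2, eg.enr.shape)
    assert extract_prey_traces(eg, detect_seafloor(eg)) == []


def test_no_trace_pixel_inside_guard_band():
    """Masking safety: extracted pixels never sit on the ridge or in the
    guard band above it."""
    for seed in range(10):
        eg = simulate_echogram(0.0, 7.0, _truth(reaction="leave_seafloor",
                                                onset_range_cm=70.0,
                                                seafloor_range_m=0.70),
                               rng=np.random.default_rng(seed))
        floor = detect_seafloor(eg)
        for tr in extract_prey_traces(eg, floor):
            for p, b in tr.pixels:
                top = floor.top_bins[p]
                if top >= 0:
                    assert b < top - GUARD_BINS


# ---------------------------------------------------------------------------
# reaction classification

def test_linear_departing_trace_is_leave_seafloor():
    eg = _with_floor(_blank(), floor_bin=60)
    _paint_line(eg, 2.0, 0.60, 0.12, 3.0)
    floor = detect_seafloor(eg)
    tr = extract_prey_traces(eg, floor)[0]
    classify_reaction(tr, floor, eg, prca_start=1.0)
    assert tr.reaction == "leave_seafloor"
    assert tr.onset_time == pytest.approx(1.0, abs=0.3)
    assert tr.onset_range_cm == pytest.approx(60.0, abs=5.0)


def test_curved_trace_above_floor_is_escape():
    eg = _with_floor(_blank(), floor_bin=90)
    # down-then-up parabola 30 cm above the ridge
    for p in range(eg.enr.shape[0]):
        t = eg.ping_times[p]
        if 2.0 <= t <= 5.0:
            r = 0.60 - 0.15 * (t - 2.0) + 0.05 * (t - 2.0) ** 2
            c = int(round(r / 0.01))
            eg.enr[p, c - 2:c + 3] = 18.0
    floor = detect_seafloor(eg)
    tr = extract_prey_traces(eg, floor)[0]
    classify_reaction(tr, floor, eg, prca_start=1.0)
    assert tr.reaction == "escape"
    assert tr.onset_range_cm == pytest.approx(60.0, abs=5.0)


def test_stationary_blob_is_not_a_reaction():
    eg = _with_floor(_blank(), floor_bin=90)
    eg.enr[40:120, 58:63] = 18.0
    floor = detect_seafloor(eg)
    tr = extract_prey_traces(eg, floor)[0]
    classify_reaction(tr, floor, eg, prca_start=1.0)
    assert tr.reaction == "none"


def test_degenerate_trace_is_none():
    eg = _with_floor(_blank())
    eg.enr[50:53, 58:63] = 18.0
    floor = detect_seafloor(eg)
    traces = extract_prey_traces(eg, floor, min_pings=3)
    tr = traces[0]
    classify_reaction(tr, floor, eg, prca_start=1.0)
    assert tr.reaction == "none"


def test_classification_agreement_on_simulated_round_trip():
    """>= 90 % reaction-class agreement with ground truth over simulated
    labelled traces at default noise (20 seeds x 25 windows)."""
    rng = np.random.default_rng(10)
    agree = total = 0
    for seed in range(20):
        for k in range(25):
            u = rng.random()
            reaction = ("leave_seafloor" if u < 0.4
                        else "escape" if u < 0.7 else "none")
            dist = float(np.clip(rng.normal(51, 18), 16, 121))
            floor_m = dist / 100.0 if reaction == "leave_seafloor" \
                else dist / 100.0 + rng.uniform(0.12, 0.28)
            truth = _truth(reaction=reaction, onset_range_cm=dist,
                           onset_rel_s=float(rng.uniform(-2, 4)),
                           seafloor_range_m=min(floor_m, 6.8))
            eg = simulate_echogram(0.0, 7.0, truth,
                                   rng=np.random.default_rng([seed, k]))
            row = analyze_echogram(eg, prca_start=0.0)
            total += 1
            agree += row["reaction"] == reaction
    assert agree / total >= 0.90


def test_onset_recovery_on_clean_traces():
    """Estimated onset within +-5 cm and +-0.2 s of schedule for noiseless
    traces."""
    for seed in range(10):
        dist = 40.0 + 5 * seed
        truth = _truth(reaction="leave_seafloor", onset_range_cm=dist,
                       onset_rel_s=1.5, seafloor_range_m=dist / 100.0)
        eg = simulate_echogram(0.0, 7.0, truth, noise_enr_db=1e-9,
                               rng=np.random.default_rng(seed))
        row = analyze_echogram(eg, prca_start=0.0)
        assert row["reaction"] == "leave_seafloor"
        assert row["onset_range_cm"] == pytest.approx(dist, abs=5.0)
        assert row["onset_time"] == pytest.approx(1.5, abs=0.2)


def test_classification_invariances():
    """Classification is unchanged by a uniform ENR offset above threshold
    and by translating the window in time."""
    def run(eg, start):
        return analyze_echogram(eg, prca_start=start)["reaction"]

    eg = _with_floor(_blank(), floor_bin=60)
    _paint_line(eg, 2.0, 0.60, 0.12, 3.0)
    base = run(eg, 1.0)
    shifted = Echogram(ping_times=eg.ping_times, ranges=eg.ranges,
                       enr=np.where(eg.enr > 0, eg.enr + 7.0, eg.enr))
    assert run(shifted, 1.0) == base
    translated = Echogram(ping_times=eg.ping_times + 1234.5,
                          ranges=eg.ranges, enr=eg.enr)
    assert run(translated, 1235.5) == base


# ---------------------------------------------------------------------------
# acoustic size

def test_five_pixel_columns_give_five_cm():
    eg = _with_floor(_blank())
    _paint_line(eg, 2.0, 0.60, 0.12, 3.0, size_bins=5)
    floor = detect_seafloor(eg)
    tr = extract_prey_traces(eg, floor)[0]
    assert measure_acoustic_size(tr, eg) == pytest.approx(5.0)


def test_single_pixel_columns_give_one_cm():
    eg = _blank()
    eg.enr[50:60, 70] = 18.0
    tr = extract_prey_traces(eg, detect_seafloor(eg), min_pixels=5)[0]
    assert measure_acoustic_size(tr, eg) == pytest.approx(1.0)


def test_non_isolated_trace_size_undefined():
    eg = _with_floor(_blank())
    _paint_line(eg, 2.0, 0.60, 0.12, 3.0)
    _paint_line(eg, 2.0, 0.40, 0.12, 3.0)
    traces = extract_prey_traces(eg, detect_seafloor(eg))
    assert np.isnan(measure_acoustic_size(traces[0], eg))


def test_size_distribution_recovery():
    """Sizes ~ N(5, 1) truncated to [3, 13] over n = 96 simulated prey are
    recovered with mean error below 0.5 cm."""
    rng = np.random.default_rng(4)
    sizes, est = [], []
    for k in range(96):
        size = float(np.clip(rng.normal(5.0, 1.0), 3.0, 13.0))
        truth = _truth(reaction="leave_seafloor", size_cm=size,
                       onset_range_cm=60.0, seafloor_range_m=0.60,
                       onset_rel_s=1.0)
        eg = simulate_echogram(0.0, 6.0, truth,
                               rng=np.random.default_rng(1000 + k))
        row = analyze_echogram(eg, prca_start=0.0)
        if np.isfinite(row["size_cm"]):
            sizes.append(size)
            est.append(row["size_cm"])
    assert len(est) > 80
    assert abs(np.mean(est) - np.mean(sizes)) < 0.5


# ---------------------------------------------------------------------------
# summary

def test_prey_summary_counts_and_empty():
    import pandas as pd

    prey = pd.DataFrame({
        "individual": ["a"] * 4 + ["b"],
        "visible": [True, True, False, True, True],
        "n_targets": ["one", "several", "one", "one", "one"],
        "reaction": ["leave_seafloor", "escape", "none", "none", "escape"],
        "onset_time": [1.0, 2.0, np.nan, np.nan, 3.0],
        "onset_range_cm": [50.0, 70.0, np.nan, np.nan, 60.0],
        "size_cm": [5.0, 6.0, np.nan, 4.0, 7.0],
    })
    out = summarize_prey(prey)
    total = out[out["individual"] == "total"].iloc[0]
    assert total["n_with_traces"] == 4
    assert total["n_reactive"] == 3
    assert total["n_leave_seafloor"] == 1
    assert total["n_school"] == 1
    assert total["distance_cm_mean"] == pytest.approx(60.0)
    assert summarize_prey(pd.DataFrame()).empty
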