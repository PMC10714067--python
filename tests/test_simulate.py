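"""Generator tests: dive archetype geometry, acceleration signal model,
echogram construction, deployment consistency and distributional fidelity."""

import numpy as np
import pytest
from scipy import signal as sp_signal
from scipy import stats

from sealforage import SimulationConfig
from sealforage.prca import DetectorConfig, compute_jerk, detect_events, rms_jerk
from sealforage.simulate import (
    simulate_acceleration,
    simulate_deployment,
    simulate_dive_profile,
    simulate_echogram,
)
from sealforage.simulate.deployment import echogram_for


# ---------------------------------------------------------------------------
# dive profiles

@pytest.mark.parametrize("arch", [1, 2, 3, 4, 5])
def test_profile_endpoints_and_max(arch):
    rng = np.random.default_rng(arch)
    p = simulate_dive_profile(arch, 80.0, 240.0, 50.0, rng)
    assert p[0] < 5.0 and p[-1] < 5.0
    assert p.max() == pytest.approx(80.0, rel=0.02)
    assert p.min() >= 0.0


def test_v_dive_single_bottom_near_middle():
    """Archetype 2 is a symmetric V: one prominent depth maximum near
    mid-dive and monotone-trend limbs."""
    p = simulate_dive_profile(2, 100.0, 300.0, 50.0, np.random.default_rng(3))
    peaks, _ = sp_signal.find_peaks(p, prominence=0.2 * p.max())
    assert len(peaks) == 1
    assert 0.35 < peaks[0] / p.size < 0.65
    coarse = p[:: p.size // 20]
    imax = np.argmax(coarse)
    assert np.all(np.diff(coarse[: imax + 1]) > -5)  # descending trend
    assert np.all(np.diff(coarse[imax:]) < 5)  # ascending trend


def test_w_dive_has_exactly_two_bottom_excursions():
    p = simulate_dive_profile(5, 30.0, 300.0, 50.0, np.random.default_rng(4))
    peaks, _ = sp_signal.find_peaks(p, prominence=0.2 * p.max())
    assert len(peaks) == 2


def test_square_dive_flat_bottom_at_least_30pct():
    p = simulate_dive_profile(1, 60.0, 200.0, 50.0, np.random.default_rng(5))
    assert (p > 0.95 * p.max()).mean() >= 0.30


def test_boundary_dive_just_over_threshold():
    p = simulate_dive_profile(1, 5.01, 10.0, 50.0, np.random.default_rng(0))
    assert p.max() == pytest.approx(5.01)


def test_profile_rejects_bad_arguments():
    with pytest.raises(ValueError):
        simulate_dive_profile(7, 50.0, 100.0)
    with pytest.raises(ValueError):
        simulate_dive_profile(1, 50.0, -5.0)
    with pytest.raises(ValueError):
        simulate_dive_profile(1, 4.0, 100.0)


# ---------------------------------------------------------------------------
# acceleration

def test_no_events_stays_below_threshold():
    rng = np.random.default_rng(0)
    a = simulate_acceleration(60.0, 250.0, prca_schedule=[], rng=rng)
    rms = rms_jerk(compute_jerk(a, 250.0), 250.0)
    assert rms.max() < 150.0


def test_quiet_record_has_negligible_jerk():
    a = simulate_acceleration(10.0, 250.0, stroke_amp=0.0, jerk_noise_rms=0.0,
                              rng=np.random.default_rng(0))
    jerk = compute_jerk(a, 250.0)
    assert jerk.max() < 1e-9


def test_injected_event_found_by_detector_across_seeds():
    """Closed loop: a single injected 6 s event is recovered as exactly one
    detection overlapping the scheduled interval, for 20 seeds."""
    for seed in range(20):
        a = simulate_acceleration(60.0, 250.0, prca_schedule=[(25.0, 31.0)],
                                  rng=np.random.default_rng(seed))
        rms = rms_jerk(compute_jerk(a, 250.0), 250.0)
        ev = detect_events(rms, 250.0, DetectorConfig())
        assert len(ev) == 1
        assert ev.start[0] < 31.0 and ev.end[0] > 25.0


def test_acceleration_rejects_bad_rate():
    with pytest.raises(ValueError):
        simulate_acceleration(10.0, 100.0)


# ---------------------------------------------------------------------------
# echograms

def _truth(**kw):
    base = dict(benthic=True, visible=False, reaction="none", onset_rel_s=1.0,
                onset_range_cm=51.0, size_cm=5.0, school=False,
                seafloor_range_m=0.9)
    base.update(kw)
    return base


def test_benthic_no_prey_shows_only_ridge():
    from sealforage.echogram import detect_seafloor, extract_prey_traces

    eg = simulate_echogram(0.0, 6.0, _truth(), rng=np.random.default_rng(0))
    floor = detect_seafloor(eg)
    assert floor.present
    assert abs(np.nanmedian(floor.ranges) - 0.9) < 0.03
    assert extract_prey_traces(eg, floor) == []


def test_leave_seafloor_trace_departs_at_scheduled_bin():
    eg = simulate_echogram(0.0, 6.0, _truth(visible=True,
                                             reaction="leave_seafloor",
                                             onset_rel_s=0.5,
                                             onset_range_cm=51.0,
                                             seafloor_range_m=0.51),
                           rng=np.random.default_rng(1))
    # the first supra-threshold prey pixels away from the ridge appear at
    # the scheduled onset range (bin 51 at 1 cm/bin), then move shallower
    from sealforage.echogram import detect_seafloor, extract_prey_traces

    floor = detect_seafloor(eg)
    traces = extract_prey_traces(eg, floor)
    assert traces
    tr = max(traces, key=lambda t: t.pixels.shape[0])
    first_bin = tr.pixels[tr.pixels[:, 0] == tr.pings[0], 1].max()
    assert abs(first_bin - 51) <= 6  # at the ridge edge minus the guard band
    assert tr.polyline_center[-1] < tr.polyline_center[0]


def test_acoustic_size_maps_to_pixel_extent():
    eg = simulate_echogram(0.0, 6.0, _truth(visible=True, size_cm=5.0,
                                            onset_range_cm=60.0),
                           noise_enr_db=1e-6, rng=np.random.default_rng(2))
    cols = eg.enr[:, :80] > 9.0  # away from the 0.9 m ridge
    widths = cols.sum(axis=1)
    assert np.median(widths[widths > 0]) == 5


def test_school_paints_two_traces_in_shared_pings():
    from sealforage.echogram import detect_seafloor, extract_prey_traces

    eg = simulate_echogram(0.0, 6.0, _truth(visible=True, school=True,
                                            reaction="none",
                                            onset_range_cm=60.0),
                           rng=np.random.default_rng(3))
    traces = extract_prey_traces(eg, detect_seafloor(eg))
    assert len(traces) >= 2
    assert any(t.n_targets == "several" for t in traces)


def test_echogram_rejects_bad_resolution():
    with pytest.raises(ValueError):
        simulate_echogram(0.0, 6.0, _truth(), range_resolution=0.0)


# ---------------------------------------------------------------------------
# deployments

def test_same_seed_is_bit_identical(small_cfg):
    b1, t1 = simulate_deployment(small_cfg)
    b2, t2 = simulate_deployment(small_cfg)
    assert np.array_equal(b1[0].accel, b2[0].accel)
    assert np.array_equal(b1[0].mag, b2[0].mag)
    assert np.array_equal(b1[0].depth, b2[0].depth)
    assert t1.prcas.equals(t2.prcas)
    assert t1.dives.equals(t2.dives)


def test_truth_counts_match_requested_totals(small_cfg, small_deployment):
    _, truth = small_deployment
    assert len(truth.dives) == sum(small_cfg.dives_per_individual)
    assert len(truth.prcas) == sum(small_cfg.prcas_per_individual)
    assert truth.dives["foraging"].sum() == sum(
        small_cfg.foraging_dives_per_individual)
    # every PrCA lies inside its labelled dive
    dv = truth.dives.set_index(["individual", "dive_id"])
    for _, ev in truth.prcas.iterrows():
        d = dv.loc[(ev["individual"], ev["dive_id"])]
        assert d["start"] <= ev["start"] < ev["end"] <= d["end"]


def test_empty_deployment():
    cfg = SimulationConfig(seed=0, n_individuals=1, accel_fs=(250.0,),
                           dives_per_individual=(0,),
                           foraging_dives_per_individual=(0,),
                           prcas_per_individual=(0,))
    bundles, truth = simulate_deployment(cfg)
    assert bundles[0].accel.shape[0] == 0
    assert truth.dives.empty and truth.prcas.empty


def test_gps_stays_near_colony(small_deployment):
    from sealforage.report import haversine_km

    bundles, _ = small_deployment
    for b in bundles:
        d = haversine_km(b.gps.lat.iloc[0], b.gps.lon.iloc[0],
                         b.gps.lat.to_numpy(), b.gps.lon.to_numpy())
        assert np.all(d <= 3.5)


def test_deployment_echograms_exist_for_every_prca(small_cfg, small_deployment):
    _, truth = small_deployment
    row = truth.prcas.iloc[0]
    eg = echogram_for(row, small_cfg, 0)
    assert eg.enr.shape[0] == pytest.approx(
        25 * (row["end"] - row["start"] + 10.0), abs=2)
    assert eg.ranges.max() <= 7.0


def _truncnorm_mean(mu, sd, lo, hi):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.mean(a, b, mu, sd)


def test_prey_distributional_fidelity():
    """With n = 500 simulated prey per deployment, the sample means of
    reaction distance, acoustic size, and onset time match the configured
    distributions within 2 standard errors.

    A 2-SE bound holds with ~95 % probability per draw, so three fixed
    replicate deployments are checked and each quantity must satisfy it in
    at least two of them (false-alarm probability < 1 % under a correctly
    parameterized generator).
    """
    hits = {"distance": 0, "size": 0, "onset": 0}
    for seed in (5, 12, 20):
        cfg = SimulationConfig(
            seed=seed,
            dives_per_individual=(125, 0, 0),
            foraging_dives_per_individual=(125, 0, 0),
            prcas_per_individual=(500, 0, 0),
            p_trace_visible=1.0, p_reactive=1.0, p_benthic=1.0,
        )
        _, truth = simulate_deployment(cfg)
        pr = truth.prcas
        assert len(pr) == 500

        def within(sample, mean):
            se = sample.std(ddof=1) / np.sqrt(len(sample))
            return abs(sample.mean() - mean) < 2 * se

        hits["distance"] += within(
            pr["onset_range_cm"],
            _truncnorm_mean(*cfg.reaction_distance_mean_sd,
                            *cfg.reaction_distance_range))
        hits["size"] += within(
            pr["size_cm"],
            _truncnorm_mean(*cfg.acoustic_size_mean_sd,
                            *cfg.acoustic_size_range))

        # onset time: analytic mean of the timing-category truncnorm mixture
        mu_t, sd_t = cfg.reaction_time_mean_sd
        p_b, p_d, p_a = cfg.reaction_timing_probs
        expected = np.mean([
            p_b * _truncnorm_mean(mu_t, sd_t, -4.5, -0.4)
            + p_d * _truncnorm_mean(mu_t, sd_t, 0.2, max(d - 2.5, 0.5))
            + p_a * _truncnorm_mean(mu_t, sd_t, d + 0.3, d + 4.3)
            for d in (pr["end"] - pr["start"])
        ])
        hits["onset"] += within(pr["onset_rel_s"], expected)
    assert all(v >= 2 for v in hits.values()), hits
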