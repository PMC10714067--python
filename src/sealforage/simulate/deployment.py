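"""Full synthetic deployments: multi-rate sensor streams plus ground truth.

One deployment = one or more individuals, each with a 50 Hz depth and
magnetometry record, a 200/250 Hz triaxial acceleration record, sparse GPS
surface fixes near a fixed colony location, and a labelled schedule of
dives, prey-capture attempts, prey interactions and approach behavior.
Echograms are synthesized on demand per PrCA (see :func:`echogram_for`)
rather than stored, since a full deployment carries hundreds of them.

Foraging dives place their capture attempts inside a flat bottom phase at
the dive's maximum depth, so the depths of injected PrCAs follow the
configured truncated-normal distribution (88 +- 30 m by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from ..behavior import body_vector
from ..config import SimulationConfig
from ..echogram import Echogram
from .accel import simulate_acceleration
from .dives import profile_with_hold
from .echo import simulate_echogram

__all__ = ["SensorBundle", "GroundTruth", "simulate_deployment", "echogram_for"]

PRCA_COLUMNS = [
    "individual", "prca_id", "dive_id", "start", "end", "depth_m", "benthic",
    "visible", "reactive", "reaction", "onset_rel_s", "onset_range_cm",
    "size_cm", "school", "seafloor_range_m", "timing", "strokes_before",
    "strokes_during", "head_turn", "t_reaction",
]
DIVE_COLUMNS = ["individual", "dive_id", "start", "end", "max_depth",
                "archetype", "foraging", "n_prcas"]


@dataclass
class SensorBundle:
    """Synchronized multi-rate streams for one individual; times are seconds
    from the deployment start ``t0_utc``."""

    individual: str
    t0_utc: str
    accel: np.ndarray = field(repr=False)  # (n, 3) m/s^2
    accel_fs: float = 250.0
    mag: np.ndarray = field(default=None, repr=False)  # (m, 3) uT
    depth: np.ndarray = field(default=None, repr=False)  # (m,) m, 50 Hz
    mag_depth_fs: float = 50.0
    gps: pd.DataFrame = field(default=None, repr=False)  # t, lat, lon

    @property
    def duration_s(self) -> float:
        return self.depth.size / self.mag_depth_fs


@dataclass
class GroundTruth:
    """Labelled schedule of everything the generator injected."""

    dives: pd.DataFrame
    prcas: pd.DataFrame
    config: SimulationConfig = None


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    if sd <= 0:
        return np.full(size, mean) if size else float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _relief_bottom(profile, fs, hold, ev_t, depths):
    """Reshape the flat bottom hold into a seafloor-relief line passing
    through each scheduled event's depth at its start time, cross-faded
    into the original profile at the hold edges."""
    i0 = int(hold[0] * fs)
    i1 = min(int(hold[1] * fs), profile.size)
    if i1 - i0 < 3:
        return profile
    tt = np.arange(i0, i1) / fs
    knot_t = np.concatenate([[tt[0]], ev_t, [tt[-1]]])
    knot_v = np.concatenate([[depths[0]], depths, [depths[-1]]])
    order = np.argsort(knot_t)
    line = np.interp(tt, knot_t[order], knot_v[order])
    fade = np.clip(np.minimum(tt - tt[0], tt[-1] - tt) / 1.5, 0.0, 1.0)
    out = profile.copy()
    out[i0:i1] = profile[i0:i1] * (1 - fade) + line * fade
    return out


def _plan_foraging_dive(rng, cfg, n_events):
    """Durations/gaps for the bottom phase and the total dive length."""
    durs = rng.uniform(*cfg.prca_duration_range, size=n_events)
    gaps = rng.uniform(*cfg.prca_gap_range, size=max(n_events - 1, 0))
    bottom = durs.sum() + gaps.sum() + 6.0
    return durs, gaps, bottom


def _simulate_individual(idx, cfg: SimulationConfig):
    rng = np.random.default_rng([cfg.seed, 101 + idx])
    name = f"ind{idx + 1}"
    fs_md = cfg.mag_depth_fs
    n_dives = cfg.dives_per_individual[idx]
    n_forage = cfg.foraging_dives_per_individual[idx]
    n_prcas = cfg.prcas_per_individual[idx]

    # distribute PrCAs over foraging dives (at least one each)
    events_per_dive = np.zeros(n_forage, dtype=int)
    if n_forage:
        events_per_dive += 1
        extra = n_prcas - n_forage
        if extra > 0:
            events_per_dive += rng.multinomial(extra, np.full(n_forage, 1.0 / n_forage))
    forage_slots = set(rng.choice(n_dives, size=n_forage, replace=False).tolist()) \
        if n_forage else set()

    # every PrCA depth is an independent draw from the configured
    # distribution; sorted depths are partitioned into dives (a seal works
    # similar seafloor within one dive) so each dive's bottom phase spans a
    # narrow depth band while the pooled event depths stay i.i.d.
    depth_draws = np.sort(np.atleast_1d(_truncnorm(
        rng, *cfg.prca_depth_mean_sd, cfg.min_dive_depth, cfg.max_dive_depth,
        size=n_prcas))) if n_prcas else np.zeros(0)
    bounds = np.concatenate([[0], np.cumsum(events_per_dive)])
    chunk_order = rng.permutation(n_forage) if n_forage else np.zeros(0, int)
    depth_chunks_sched = [rng.permutation(depth_draws[bounds[j]:bounds[j + 1]])
                          for j in range(n_forage)]

    dive_rows, prca_rows = [], []
    depth_chunks = ([np.zeros(int(rng.uniform(*cfg.surface_interval_range) * fs_md))]
                    if n_dives else [])
    stroke_intervals = []
    t_cursor = depth_chunks[0].size / fs_md if depth_chunks else 0.0
    forage_i = 0
    arches = np.arange(1, 6)

    for d in range(n_dives):
        foraging = d in forage_slots
        if foraging:
            chunk = depth_chunks_sched[chunk_order[forage_i]]
            n_e = chunk.size
            forage_i += 1
            arch = int(rng.choice(arches, p=cfg.foraging_archetype_weights))
            depth_d = float(chunk.max())
            durs, gaps, bottom = _plan_foraging_dive(rng, cfg, n_e)
            target = 0.28 if arch == 5 else (0.5 if arch == 1 else 0.42)
            T = bottom / target + 2.0 * depth_d / cfg.vertical_speed
            profile = hold = None
            for _ in range(5):
                profile, hold = profile_with_hold(
                    arch, depth_d, T, fs_md, rng,
                    bottom_hold_frac=min(bottom / T * 1.08, 0.65))
                if hold[1] - hold[0] >= bottom - 2.0:
                    break
                T *= 1.3
        else:
            n_e, durs, gaps = 0, [], []
            arch = int(rng.choice(arches, p=cfg.archetype_weights))
            mean, sd = cfg.depth_mean_sd
            sigma2 = np.log(1.0 + (sd / mean) ** 2)
            depth_d = float(np.exp(rng.normal(np.log(mean) - sigma2 / 2,
                                              np.sqrt(sigma2))))
            if arch == 5:
                # W dives are markedly shallower, but deep enough that the
                # mid-dive rise clears the 5 m threshold with a free level
                depth_d = float(np.clip(depth_d * 0.55, 16.0, 60.0))
            depth_d = float(np.clip(depth_d, cfg.min_dive_depth, cfg.max_dive_depth))
            T = 2.0 * depth_d / cfg.vertical_speed + rng.uniform(10.0, 40.0)
            profile, hold = profile_with_hold(arch, depth_d, T, fs_md, rng)

        dive_start = t_cursor
        dive_rows.append({"individual": name, "dive_id": d, "start": dive_start,
                          "end": dive_start + profile.size / fs_md,
                          "max_depth": depth_d, "archetype": arch,
                          "foraging": foraging, "n_prcas": n_e})
        stroke_intervals.append((dive_start, dive_start + profile.size / fs_md))

        # place events inside the bottom hold, at their scheduled depths
        ev_t = []
        t_e = hold[0] + 2.0
        for k in range(n_e):
            ev_t.append(t_e)
            t_e += durs[k] + (gaps[k] if k < len(gaps) else 0.0)
        if n_e:
            profile = _relief_bottom(profile, fs_md, hold, ev_t, chunk)
        for k in range(n_e):
            start = dive_start + ev_t[k]
            i_prof = min(int(round(ev_t[k] * fs_md)), profile.size - 1)
            prca_rows.append(_make_prca(rng, cfg, name, len(prca_rows), d,
                                        start, start + durs[k],
                                        float(profile[i_prof])))

        depth_chunks.append(profile)
        surf = np.zeros(int(rng.uniform(*cfg.surface_interval_range) * fs_md))
        depth_chunks.append(surf)
        t_cursor = dive_start + (profile.size + surf.size) / fs_md

    depth_clean = np.concatenate(depth_chunks) if depth_chunks else np.zeros(0)
    dives = pd.DataFrame(dive_rows, columns=DIVE_COLUMNS)
    prcas = pd.DataFrame(prca_rows, columns=PRCA_COLUMNS)

    bundle = _build_streams(idx, cfg, rng, name, depth_clean, dives, prcas,
                            stroke_intervals)
    return bundle, dives, prcas


def _make_prca(rng, cfg, name, prca_id, dive_id, start, end, depth_at_start):
    benthic = bool(rng.random() < cfg.p_benthic)
    visible = bool(rng.random() < cfg.p_trace_visible)
    reactive = bool(visible and benthic and rng.random() < cfg.p_reactive)
    reaction = "none"
    onset_rel = np.nan
    onset_range = np.nan
    size_cm = np.nan
    school = False
    floor = np.nan
    timing = None
    strokes_before = strokes_during = None
    turn = None
    t_reaction = np.nan
    dur = end - start

    if benthic:
        floor = float(rng.uniform(0.4, 1.5))
    if visible:
        size_cm = float(_truncnorm(rng, *cfg.acoustic_size_mean_sd,
                                   *cfg.acoustic_size_range))
        school = bool(rng.random() < cfg.p_school)
        onset_range = float(_truncnorm(rng, *cfg.reaction_distance_mean_sd,
                                       *cfg.reaction_distance_range))
    if reactive:
        reaction = "leave_seafloor" if rng.random() < cfg.p_leave_seafloor else "escape"
        if reaction == "leave_seafloor":
            floor = onset_range / 100.0
        else:
            clear = rng.uniform(*cfg.escape_clearance_range)
            floor = min(onset_range / 100.0 + clear, cfg.range_max - 0.2)
        timing = ["before", "during", "after"][
            int(rng.choice(3, p=cfg.reaction_timing_probs))]
        mu, sd = cfg.reaction_time_mean_sd
        if timing == "before":
            onset_rel = float(_truncnorm(rng, mu, sd, -4.5, -0.4))
        elif timing == "during":
            onset_rel = float(_truncnorm(rng, mu, sd, 0.2, max(dur - 2.5, 0.5)))
        else:
            onset_rel = float(_truncnorm(rng, mu, sd, dur + 0.3, dur + 4.3))
        t_reaction = start + onset_rel
        strokes_before = bool(rng.random() < cfg.p_strokes_before)
        strokes_during = bool(rng.random() < cfg.p_strokes_continue)
        u = rng.random()
        turn = ("left" if u < cfg.p_turn_left
                else "right" if u < cfg.p_turn_left + cfg.p_turn_right
                else "none")
    elif visible:
        # non-reactive prey: a stationary blob somewhere in the window
        onset_rel = float(rng.uniform(-2.0, dur + 2.0))

    return {
        "individual": name, "prca_id": prca_id, "dive_id": dive_id,
        "start": start, "end": end, "depth_m": depth_at_start,
        "benthic": benthic, "visible": visible, "reactive": reactive,
        "reaction": reaction, "onset_rel_s": onset_rel,
        "onset_range_cm": onset_range, "size_cm": size_cm, "school": school,
        "seafloor_range_m": floor, "timing": timing,
        "strokes_before": strokes_before, "strokes_during": strokes_during,
        "head_turn": turn, "t_reaction": t_reaction,
    }


def _smooth_lowpass(x, fs, cutoff, order=4):
    if x.size < 30:
        return x
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _build_streams(idx, cfg, rng, name, depth_clean, dives, prcas,
                   stroke_intervals):
    fs_md = cfg.mag_depth_fs
    fs_a = float(cfg.accel_fs[idx])
    n_md = depth_clean.size
    duration = n_md / fs_md
    t_md = np.arange(n_md) / fs_md

    if n_md == 0:
        return SensorBundle(
            individual=name, t0_utc=cfg.t0_iso, accel=np.zeros((0, 3)),
            accel_fs=fs_a, mag=np.zeros((0, 3)), depth=np.zeros(0),
            mag_depth_fs=fs_md,
            gps=pd.DataFrame(columns=["t", "lat", "lon"]))

    # pitch from the depth rate at a constant along-path swim speed
    rate = np.gradient(depth_clean) * fs_md
    pitch_md = -np.rad2deg(np.arcsin(np.clip(rate / cfg.swim_speed, -0.95, 0.95)))
    pitch_md = _smooth_lowpass(pitch_md, fs_md, 0.3)

    # heading: per-dive base + slow scanning + scheduled reaction turns
    heading_md = np.zeros(n_md)
    base = rng.uniform(-180, 180)
    prev_end = 0
    for s, e in stroke_intervals:
        i0, i1 = int(s * fs_md), min(int(e * fs_md), n_md)
        heading_md[prev_end:i0] = base
        base = rng.uniform(-180, 180)
        heading_md[i0:i1] = base
        prev_end = i1
    heading_md[prev_end:] = base
    heading_md = heading_md + cfg.scan_amp_deg * np.sin(
        2 * np.pi * t_md / cfg.scan_period_s + rng.uniform(0, 2 * np.pi))
    for _, ev in prcas[prcas["reactive"] == True].iterrows():  # noqa: E712
        if ev["head_turn"] in ("left", "right"):
            delta = -cfg.head_turn_deg if ev["head_turn"] == "left" else cfg.head_turn_deg
            t_r = ev["t_reaction"]
            d2 = cfg.head_turn_duration / 2.0
            ramp = np.clip((t_md - (t_r - d2)) / cfg.head_turn_duration, 0.0, 1.0)
            heading_md = heading_md + delta * 0.5 * (1 - np.cos(np.pi * ramp))

    # magnetometry from the orientation and the local geomagnetic field
    inc = np.deg2rad(cfg.mag_inclination_deg)
    dec = np.deg2rad(cfg.mag_declination_deg)
    b_world = cfg.mag_field_ut * np.array(
        [np.cos(inc) * np.cos(dec), np.cos(inc) * np.sin(dec), -np.sin(inc)])
    mag = body_vector(b_world, heading_md - cfg.mag_declination_deg,
                      pitch_md, np.zeros(n_md))
    mag += rng.normal(0, 0.2, mag.shape)

    # acceleration at the full rate
    n_a = int(round(duration * fs_a))
    t_a = np.arange(n_a) / fs_a
    pitch_a = np.interp(t_a, t_md, pitch_md)
    gate = np.zeros(n_a, dtype=bool)
    for s, e in stroke_intervals:
        gate[int(s * fs_a):int(e * fs_a)] = True
    for _, ev in prcas[prcas["reactive"] == True].iterrows():  # noqa: E712
        if ev["strokes_before"] is False:
            t_r = ev["t_reaction"]
            gate[max(int((t_r - 5.3) * fs_a), 0):max(int(t_r * fs_a), 0)] = False
        if ev["strokes_during"] is False:
            gate[max(int((ev["start"] - 0.2) * fs_a), 0):int((ev["end"] + 0.2) * fs_a)] = False
    accel = simulate_acceleration(
        duration, fs_a,
        prca_schedule=list(zip(prcas["start"], prcas["end"])),
        stroke_gate=gate, pitch_deg=pitch_a,
        stroke_freq=cfg.stroke_freq, stroke_amp=cfg.stroke_amp,
        jerk_noise_rms=cfg.jerk_noise_rms, jerk_event_rms=cfg.jerk_event_rms,
        jerk_event_spread=cfg.jerk_event_spread, gravity=cfg.gravity, rng=rng)

    depth_meas = depth_clean + rng.normal(0, 0.02, n_md)

    gps = _simulate_gps(rng, cfg, duration)
    return SensorBundle(individual=name, t0_utc=cfg.t0_iso, accel=accel,
                        accel_fs=fs_a, mag=mag, depth=depth_meas,
                        mag_depth_fs=fs_md, gps=gps)


def _simulate_gps(rng, cfg, duration):
    n_fix = max(int(duration / 86400.0 * cfg.gps_per_day) + 1, 2)
    t = np.linspace(0.0, max(duration - 1, 1.0), n_fix)
    x = np.zeros(n_fix)
    y = np.zeros(n_fix)
    mean, sd = cfg.gps_step_km_mean_sd
    for k in range(1, n_fix):
        step = max(rng.normal(mean, sd), 0.0)
        bearing = rng.uniform(0, 2 * np.pi)
        xn = x[k - 1] + step * np.cos(bearing)
        yn = y[k - 1] + step * np.sin(bearing)
        r = np.hypot(xn, yn)
        if r > cfg.gps_max_radius_km:  # reflect back toward the colony
            xn, yn = xn * (cfg.gps_max_radius_km / r) ** 2, yn * (cfg.gps_max_radius_km / r) ** 2
        x[k], y[k] = xn, yn
    lat = cfg.colony_lat + y / 111.32
    lon = cfg.colony_lon + x / (111.32 * np.cos(np.deg2rad(cfg.colony_lat)))
    return pd.DataFrame({"t": t, "lat": lat, "lon": lon})


def simulate_deployment(cfg: SimulationConfig):
    """Simulate a full deployment.

    Returns ``(bundles, truth)``: one :class:`SensorBundle` per individual
    and a :class:`GroundTruth` with pooled dive and PrCA tables.  Bit-for-bit
    reproducible under a fixed ``cfg.seed``; individuals use independent
    sub-seeds.
    """
    cfg.validate()
    bundles, dive_frames, prca_frames = [], [], []
    for i in range(cfg.n_individuals):
        bundle, dives, prcas = _simulate_individual(i, cfg)
        bundles.append(bundle)
        dive_frames.append(dives)
        prca_frames.append(prcas)
    dive_frames = [f for f in dive_frames if len(f)]
    prca_frames = [f for f in prca_frames if len(f)]
    truth = GroundTruth(
        dives=pd.concat(dive_frames, ignore_index=True) if dive_frames
        else pd.DataFrame(columns=DIVE_COLUMNS),
        prcas=pd.concat(prca_frames, ignore_index=True) if prca_frames
        else pd.DataFrame(columns=PRCA_COLUMNS),
        config=cfg,
    )
    return bundles, truth


def echogram_for(truth_row, cfg: SimulationConfig, individual_index: int = 0) -> Echogram:
    """Synthesize the echogram for one ground-truth PrCA row, deterministic
    given the configuration seed."""
    rng = np.random.default_rng([cfg.seed, 7001 + individual_index,
                                 int(truth_row["prca_id"])])
    return simulate_echogram(
        float(truth_row["start"]), float(truth_row["end"]),
        truth=truth_row if isinstance(truth_row, dict) else truth_row.to_dict(),
        ping_rate=cfg.ping_rate, range_max=cfg.range_max,
        range_resolution=cfg.range_resolution, noise_enr_db=cfg.noise_enr_db,
        seafloor_enr_db=cfg.seafloor_enr_db, prey_enr_db=cfg.prey_enr_db,
        ridge_halfwidth_bins=cfg.ridge_halfwidth_bins, rng=rng,
        prca_id=int(truth_row["prca_id"]))
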