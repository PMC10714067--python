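"""End-to-end analysis pipeline over one or more sensor bundles.

Chains the stages in the order a deployment is processed: depth cleaning
and 5 Hz downsampling, dive segmentation, jerk-based PrCA detection and
contextualization, per-PrCA echogram analysis (seafloor, prey traces,
reaction, acoustic size), functional dive-shape clustering, approach
behavior, and the summary reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import behavior as bh
from . import dive_shape as ds
from . import echogram as ec
from . import movement as mv
from . import prca as pj
from .config import SimulationConfig
from .report import build_reports
from .simulate.deployment import GroundTruth, SensorBundle, echogram_for

__all__ = ["PipelineResult", "run_pipeline", "analyze_echogram"]

PREY_COLUMNS = ["individual", "event_id", "benthic", "visible", "n_targets",
                "reaction", "onset_time", "onset_range_cm", "size_cm"]
APPROACH_COLUMNS = ["individual", "event_id", "reaction", "timing",
                    "strokes_before", "strokes_during", "head_turn"]


@dataclass
class PipelineResult:
    dives: pd.DataFrame = None
    shallow: pd.DataFrame = None
    events: pd.DataFrame = None
    prey: pd.DataFrame = None
    prey_summary: pd.DataFrame = None
    curves: list = field(default_factory=list)
    fpca: ds.FPCAModel = None
    clusters: ds.ClusterModel = None
    cluster_table: pd.DataFrame = None
    envelopes: dict = field(default_factory=dict)
    approach: pd.DataFrame = None
    approach_summary: pd.DataFrame = None
    reports: dict = field(default_factory=dict)


def analyze_echogram(eg: ec.Echogram, prca_start: float,
                     enr_min: float = ec.ENR_THRESHOLD_DB) -> dict:
    """Run the full echogram chain on one PrCA window.

    Returns benthic flag, trace presence, target count, reaction class,
    onset (time re PrCA start, range in cm) and acoustic size for the
    primary (largest) trace.
    """
    floor = ec.detect_seafloor(eg, enr_min=enr_min)
    traces = ec.extract_prey_traces(eg, floor, enr_min=enr_min)
    out = {"benthic": bool(floor.present), "visible": bool(traces),
           "n_targets": "one", "reaction": "none", "onset_time": np.nan,
           "onset_range_cm": np.nan, "size_cm": np.nan}
    if not traces:
        return out
    primary = max(traces, key=lambda tr: tr.pixels.shape[0])
    if any(tr.n_targets == "several" for tr in traces):
        out["n_targets"] = "several"
    ec.classify_reaction(primary, floor, eg, prca_start)
    ec.measure_acoustic_size(primary, eg, enr_min=enr_min)
    out.update(reaction=primary.reaction, onset_time=primary.onset_time,
               onset_range_cm=primary.onset_range_cm,
               size_cm=primary.acoustic_size_cm)
    return out


def _match_truth(event_row, truth_prcas: pd.DataFrame):
    """Ground-truth PrCA with the largest temporal overlap, or None."""
    s, e = event_row["start"], event_row["end"]
    ov = np.minimum(truth_prcas["end"], e) - np.maximum(truth_prcas["start"], s)
    if len(ov) == 0 or ov.max() <= 0:
        return None
    return truth_prcas.iloc[int(np.argmax(ov.to_numpy()))]


def run_pipeline(
    bundles: Sequence[SensorBundle],
    truth: Optional[GroundTruth] = None,
    config: Optional[SimulationConfig] = None,
    detector: Optional[pj.DetectorConfig] = None,
    echogram_provider: Optional[Callable] = None,
    cluster: bool = True,
    approach: bool = True,
    k_range: Sequence[int] = range(1, 10),
    assign_threshold: float = 0.8,
    enr_min: float = ec.ENR_THRESHOLD_DB,
    random_state: int = 0,
) -> PipelineResult:
    """Run every analysis stage over the given bundles.

    Echograms are taken from ``echogram_provider(individual_index,
    detected_event_row)`` when given; otherwise, when ``truth`` and
    ``config`` are available, they are synthesized from the matched
    ground-truth schedule (the sonar record of a synthetic deployment).
    Without either source the echogram, and hence prey and approach stages,
    are skipped.
    """
    det = detector or pj.DetectorConfig()
    res = PipelineResult()
    all_dives, all_shallow, all_events = [], [], []
    prey_rows, approach_rows = [], []
    curves, curve_keys, curve_inds = [], [], []
    gps = {}
    dive_objects = {}

    for i, bundle in enumerate(bundles):
        ind = bundle.individual
        gps[ind] = bundle.gps
        fs5 = 5.0
        depth5 = mv.downsample(np.clip(bundle.depth, 0.0, None),
                               bundle.mag_depth_fs, fs5)
        if depth5.size == 0:
            continue
        dives, shallow = mv.segment_dives(depth5, fs5, individual=ind)
        dive_objects[ind] = dives
        all_shallow.append(shallow)

        jerk = pj.compute_jerk(bundle.accel, bundle.accel_fs) \
            if bundle.accel.shape[0] >= 2 else np.zeros(0)
        if jerk.size:
            rms = pj.rms_jerk(jerk, bundle.accel_fs, det.rms_window)
            events = pj.detect_events(rms, bundle.accel_fs, det)
            events = pj.contextualize_events(events, dives, depth5, fs5)
        else:
            events = pj.detect_events(np.zeros(1), 1.0, det)
            events["depth_m"] = []
            events["dive_id"] = []
            events["excluded"] = []
        events.insert(0, "individual", ind)
        all_events.append(events)

        # echogram stage
        truth_i = truth.prcas[truth.prcas["individual"] == ind] \
            if truth is not None else None
        for _, ev in events[~events["excluded"].astype(bool)].iterrows():
            eg = None
            if echogram_provider is not None:
                eg = echogram_provider(i, ev)
            elif truth_i is not None and config is not None and len(truth_i):
                match = _match_truth(ev, truth_i)
                if match is not None:
                    eg = echogram_for(match, config, i)
            if eg is None:
                continue
            row = analyze_echogram(eg, ev["start"], enr_min=enr_min)
            row.update(individual=ind, event_id=int(ev["event_id"]))
            prey_rows.append(row)
            if row["benthic"]:
                dives[int(ev["dive_id"])].benthic = True

        # dive curves for shape clustering
        for d in dives:
            if d.profile.size >= 4 and d.profile.std() > 0:
                curves.append(ds.normalize_dive(
                    d.profile, d.end - d.start, dive_id=d.id, individual=ind))
                curve_keys.append((ind, d.id))
                curve_inds.append(ind)

        # approach behavior on reactive PrCAs
        if approach and prey_rows:
            _approach_for_individual(bundle, events, prey_rows, approach_rows,
                                     config)

        lat = bundle.gps["lat"].iloc[0] if len(bundle.gps) else None
        lon = bundle.gps["lon"].iloc[0] if len(bundle.gps) else None
        all_dives.append(mv.dives_to_frame(dives, bundle.t0_utc, lat, lon))

    res.dives = pd.concat(all_dives, ignore_index=True) if all_dives else pd.DataFrame()
    res.shallow = pd.concat(all_shallow, ignore_index=True) if all_shallow else pd.DataFrame()
    res.events = pd.concat(all_events, ignore_index=True) if all_events else pd.DataFrame()
    if prey_rows:
        res.prey = pd.DataFrame(prey_rows)
        res.prey_summary = ec.summarize_prey(res.prey)
    else:
        res.prey = pd.DataFrame(columns=PREY_COLUMNS)

    res.curves = curves
    if cluster and len(curves) >= 2 * max(k_range):
        res.fpca = ds.fit_fpca(curves)
        res.clusters = ds.fit_cluster_model(
            res.fpca.scores, k_range=k_range, threshold=assign_threshold,
            random_state=random_state)
        keys = {key: n for n, key in enumerate(curve_keys)}
        ev_ok = res.events[~res.events["excluded"].astype(bool)]
        prca_curve_idx = [keys.get((r["individual"], r["dive_id"]), -999)
                          for _, r in ev_ok.iterrows()]
        ids = np.arange(len(curves))
        res.cluster_table, res.envelopes = ds.summarize_clusters(
            res.clusters.assignments, curves,
            dive_individuals=curve_inds, prca_dive_ids=prca_curve_idx,
            dive_ids=ids)

    if approach_rows:
        res.approach = pd.DataFrame(approach_rows, columns=APPROACH_COLUMNS)
        res.approach_summary = bh.summarize_approach(res.approach)

    res.reports = build_reports(
        res.dives, res.shallow, res.events, prey=res.prey
        if prey_rows else None, gps=gps, cluster_table=res.cluster_table,
        approach_summary=res.approach_summary)
    return res


def _approach_for_individual(bundle, events, prey_rows, approach_rows, config):
    """Strokes and head turns in the approach window of each reactive PrCA
    of this bundle (appends to ``approach_rows``)."""
    ind = bundle.individual
    mine = [r for r in prey_rows
            if r["individual"] == ind and r["reaction"] in ("escape", "leave_seafloor")]
    done = {r["event_id"] for r in approach_rows if r["individual"] == ind} \
        if approach_rows else set()
    mine = [r for r in mine if r["event_id"] not in done]
    if not mine:
        return
    fs5 = 5.0
    fs_st = 25.0
    accel5 = mv.downsample(bundle.accel, bundle.accel_fs, fs5)
    mag5 = mv.downsample(bundle.mag, bundle.mag_depth_fs, fs5)
    n = min(accel5.shape[0], mag5.shape[0])
    decl = config.mag_declination_deg if config is not None else 0.0
    orient = bh.compute_orientation(accel5[:n], mag5[:n], fs5,
                                    declination_deg=decl)
    lat25 = mv.downsample(bundle.accel[:, 1], bundle.accel_fs, fs_st)
    stroke, residual = bh.filter_strokes(lat25, fs_st)

    ev_by_id = events.set_index("event_id")
    for row in mine:
        ev = ev_by_id.loc[row["event_id"]]
        t_r = ev["start"] + row["onset_time"]
        dur = ev["end"] - ev["start"]
        timing = ("before" if row["onset_time"] < 0
                  else "during" if row["onset_time"] <= dur else "after")
        try:
            sb = bh.count_strokes(stroke, fs_st, window=(t_r - 5.0, t_r),
                                  residual=residual) > 0
            sd_ = bh.count_strokes(stroke, fs_st, window=(ev["start"], ev["end"]),
                                   residual=residual) > 0
            turn = bh.detect_head_turn(orient.heading, fs5, t_r)
        except ValueError:
            continue  # window clipped by the record edge
        approach_rows.append({
            "individual": ind, "event_id": row["event_id"],
            "reaction": row["reaction"], "timing": timing,
            "strokes_before": sb, "strokes_during": sd_, "head_turn": turn,
        })
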