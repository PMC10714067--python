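"""Plain-text deployment and results I/O.

A deployment directory holds one sub-directory per individual with
``accel.csv`` (t, ax, ay, az), ``magdepth.csv`` (t, mx, my, mz, depth),
``gps.csv`` (t, lat, lon) and a shared ``truth.json`` / ``config.yaml`` at
the top level when the deployment is synthetic.  Echograms, when written,
go to ``<individual>/echograms/prca_<id>.csv`` with a JSON sidecar
(prca_id, t0, ping_rate_hz, range_res_m).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .echogram import Echogram
from .simulate.deployment import GroundTruth, SensorBundle

__all__ = ["write_deployment", "read_deployment", "write_echogram",
           "read_echogram", "write_results"]


def write_deployment(path, bundles, truth: GroundTruth | None = None,
                     config: SimulationConfig | None = None) -> Path:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        d = root / b.individual
        d.mkdir(exist_ok=True)
        n_a = b.accel.shape[0]
        pd.DataFrame({"t": np.arange(n_a) / b.accel_fs,
                      "ax": b.accel[:, 0], "ay": b.accel[:, 1],
                      "az": b.accel[:, 2]}).to_csv(d / "accel.csv", index=False)
        n_m = b.depth.size
        pd.DataFrame({"t": np.arange(n_m) / b.mag_depth_fs,
                      "mx": b.mag[:, 0], "my": b.mag[:, 1], "mz": b.mag[:, 2],
                      "depth": b.depth}).to_csv(d / "magdepth.csv", index=False)
        b.gps.to_csv(d / "gps.csv", index=False)
        (d / "meta.json").write_text(json.dumps(
            {"individual": b.individual, "t0_utc": b.t0_utc,
             "accel_fs": b.accel_fs, "mag_depth_fs": b.mag_depth_fs}))
    if truth is not None:
        (root / "truth.json").write_text(json.dumps({
            "dives": truth.dives.to_dict(orient="list"),
            "prcas": truth.prcas.to_dict(orient="list"),
        }))
    if config is not None:
        config.to_yaml(root / "config.yaml")
    return root


def read_deployment(path):
    """Read a deployment directory back into (bundles, truth, config);
    truth/config are None when absent."""
    root = Path(path)
    bundles = []
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        if not (d / "accel.csv").exists():
            continue
        meta = json.loads((d / "meta.json").read_text()) \
            if (d / "meta.json").exists() else {}
        acc = pd.read_csv(d / "accel.csv")
        md = pd.read_csv(d / "magdepth.csv")
        gps = pd.read_csv(d / "gps.csv") if (d / "gps.csv").exists() \
            else pd.DataFrame(columns=["t", "lat", "lon"])
        bundles.append(SensorBundle(
            individual=meta.get("individual", d.name),
            t0_utc=meta.get("t0_utc", "2019-11-12T00:00:00"),
            accel=acc[["ax", "ay", "az"]].to_numpy(),
            accel_fs=float(meta.get("accel_fs", 250.0)),
            mag=md[["mx", "my", "mz"]].to_numpy(),
            depth=md["depth"].to_numpy(),
            mag_depth_fs=float(meta.get("mag_depth_fs", 50.0)),
            gps=gps))
    truth = None
    if (root / "truth.json").exists():
        raw = json.loads((root / "truth.json").read_text())
        truth = GroundTruth(dives=pd.DataFrame(raw["dives"]),
                            prcas=pd.DataFrame(raw["prcas"]))
    config = SimulationConfig.from_yaml(root / "config.yaml") \
        if (root / "config.yaml").exists() else None
    if truth is not None:
        truth.config = config
    return bundles, truth, config


def write_echogram(path, eg: Echogram) -> None:
    path = Path(path)
    np.savetxt(path, eg.enr, delimiter=",", fmt="%.2f")
    path.with_suffix(".json").write_text(json.dumps({
        "prca_id": eg.prca_id, "t0": float(eg.ping_times[0]),
        "ping_rate_hz": float(round(1.0 / (eg.ping_times[1] - eg.ping_times[0]), 6)),
        "range_res_m": eg.range_resolution,
        "window": list(eg.window)}))


def read_echogram(path) -> Echogram:
    path = Path(path)
    enr = np.loadtxt(path, delimiter=",")
    meta = json.loads(path.with_suffix(".json").read_text())
    n_pings, n_bins = enr.shape
    t = meta["t0"] + np.arange(n_pings) / meta["ping_rate_hz"]
    ranges = (np.arange(n_bins) + 0.5) * meta["range_res_m"]
    return Echogram(ping_times=t, ranges=ranges, enr=enr,
                    prca_id=meta.get("prca_id", -1),
                    window=tuple(meta.get("window", (t[0], t[-1]))))


def write_results(path, result) -> Path:
    """Write every stage output of a PipelineResult as CSV plus a JSON run
    manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {}
    tables = {
        "dives.csv": result.dives, "shallow.csv": result.shallow,
        "prca.csv": result.events, "prey.csv": result.prey,
        "prey_summary.csv": result.prey_summary,
        "cluster_summary.csv": result.cluster_table,
        "approach.csv": result.approach,
        "approach_summary.csv": result.approach_summary,
    }
    if result.reports:
        tables["deployment_summary.csv"] = result.reports.get("deployment_summary")
    for name, df in tables.items():
        if df is not None and len(df):
            df.to_csv(root / name, index=False)
            manifest[name] = len(df)
    if result.envelopes:
        rows = []
        for label, env in result.envelopes.items():
            e = env.copy()
            e.insert(0, "cluster", label)
            rows.append(e)
        pd.concat(rows, ignore_index=True).to_csv(root / "envelopes.csv", index=False)
        manifest["envelopes.csv"] = sum(len(e) for e in result.envelopes.values())
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return root
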