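"""Deployment-level summary tables and headline descriptive ratios.

Builds the machine-readable analogues of the standard deployment summary
(per-individual and pooled dive counts and times, PrCA counts and depths,
benthic and prey-trace fractions, GPS statistics), with all printed ratios
recomputable from their numerator/denominator cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["percent", "ratio", "haversine_km", "daily_radius", "build_reports"]


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """``round(100 * numerator / denominator, decimals)`` — the identity all
    printed count-percentage cells must satisfy."""
    if denominator == 0:
        return np.nan
    return round(100.0 * numerator / denominator, decimals)


def ratio(a: float, b: float, decimals: int = 1) -> float:
    if b == 0:
        return np.nan
    return round(a / b, decimals)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km."""
    r = 6371.0
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dp = p2 - p1
    dl = np.deg2rad(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(a))


def daily_radius(gps: pd.DataFrame) -> tuple[float, float, pd.Series]:
    """Per calendar day, the maximum great-circle distance (km) of any fix
    from the day's first fix; returns (mean, sd, per-day series).  ``t`` is
    in seconds; days are floor(t / 86400)."""
    if gps.empty:
        return np.nan, np.nan, pd.Series(dtype=float)
    df = gps.sort_values("t")
    day = np.floor(df["t"].to_numpy() / 86400.0).astype(int)
    radii = {}
    for d in np.unique(day):
        sub = df[day == d]
        lat0, lon0 = sub.iloc[0][["lat", "lon"]]
        radii[d] = float(haversine_km(lat0, lon0, sub["lat"].to_numpy(),
                                      sub["lon"].to_numpy()).max())
    s = pd.Series(radii)
    sd = float(s.std(ddof=1)) if len(s) > 1 else 0.0
    return float(s.mean()), sd, s


def _stats(x: pd.Series) -> dict:
    x = x.dropna()
    if x.empty:
        return {"min": np.nan, "max": np.nan, "mean": np.nan, "sd": np.nan}
    return {"min": float(x.min()), "max": float(x.max()),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0}


def build_reports(
    dives: pd.DataFrame,
    shallow: pd.DataFrame,
    events: pd.DataFrame,
    prey: pd.DataFrame | None = None,
    gps: dict[str, pd.DataFrame] | None = None,
    cluster_table: pd.DataFrame | None = None,
    approach_summary: pd.DataFrame | None = None,
) -> dict:
    """Aggregate stage outputs into a deployment summary plus the prey,
    cluster and approach tables.

    ``dives``/``shallow``/``events`` are the movement and detection outputs
    (events already contextualized, with ``excluded`` flags).  Raises a
    KeyError naming the missing column if an upstream stage was skipped.
    """
    for df, cols, stage in [
        (dives, ["individual", "duration_min", "max_depth_m"], "movement"),
        (events, ["individual", "depth_m", "dive_id", "excluded"], "prca"),
    ]:
        for c in cols:
            if c not in df.columns:
                raise KeyError(f"missing column '{c}' from the {stage} stage")

    rows = []
    individuals = sorted(set(dives["individual"]) | set(events["individual"]))
    groups = [(ind, dives[dives["individual"] == ind],
               events[events["individual"] == ind]) for ind in individuals]
    groups.append(("total", dives, events))

    for label, dv, ev in groups:
        ev_ok = ev[~ev["excluded"].astype(bool)]
        sh = shallow if label == "total" else shallow[shallow["individual"] == label]
        n_dives = len(dv)
        dws = ev_ok.groupby("dive_id").size() if len(ev_ok) else pd.Series(dtype=int)
        n_dives_prca = int(ev_ok.groupby(["individual", "dive_id"]).ngroups) \
            if len(ev_ok) else 0
        depth_stats = _stats(dv["max_depth_m"])
        dur_stats = _stats(dv["duration_min"])
        row = {
            "individual": label,
            "n_dives": n_dives,
            "time_deep_h": float(dv["duration_min"].sum() / 60.0),
            "time_shallow_h": float(sh["duration_s"].sum() / 3600.0)
            if len(sh) else 0.0,
            "depth_max_m": depth_stats["max"], "depth_min_m": depth_stats["min"],
            "depth_mean_m": depth_stats["mean"], "depth_sd_m": depth_stats["sd"],
            "duration_max_min": dur_stats["max"], "duration_min_min": dur_stats["min"],
            "duration_mean_min": dur_stats["mean"], "duration_sd_min": dur_stats["sd"],
            "n_prcas": len(ev_ok),
            "n_dives_with_prcas": n_dives_prca,
            "pct_dives_with_prcas": percent(n_dives_prca, n_dives, 2),
            "prcas_per_dive_mean": float(dws.mean()) if len(dws) else np.nan,
            "prcas_per_dive_sd": float(dws.std(ddof=1)) if len(dws) > 1 else np.nan,
            "prca_depth_mean_m": float(ev_ok["depth_m"].mean()) if len(ev_ok) else np.nan,
            "prca_depth_sd_m": float(ev_ok["depth_m"].std(ddof=1)) if len(ev_ok) > 1 else np.nan,
        }
        if prey is not None and len(prey):
            pr = prey if label == "total" else prey[prey["individual"] == label]
            n_benthic = int(pr["benthic"].astype(bool).sum())
            n_traces = int(pr["visible"].astype(bool).sum())
            row["n_benthic_echograms"] = n_benthic
            row["pct_benthic"] = percent(n_benthic, len(pr)) if len(pr) else np.nan
            row["n_prey_traces"] = n_traces
            row["pct_prey_traces"] = percent(n_traces, len(pr)) if len(pr) else np.nan
        if gps:
            fixes = (pd.concat(gps.values(), ignore_index=True)
                     if label == "total" else gps.get(label))
            if fixes is not None and len(fixes):
                span_days = max((fixes["t"].max() - fixes["t"].min()) / 86400.0, 1e-9)
                steps = haversine_km(fixes["lat"].to_numpy()[:-1],
                                     fixes["lon"].to_numpy()[:-1],
                                     fixes["lat"].to_numpy()[1:],
                                     fixes["lon"].to_numpy()[1:])
                rad_mean, rad_sd, _ = daily_radius(fixes)
                row["gps_fixes_per_day"] = len(fixes) / span_days
                row["gps_step_km_mean"] = float(steps.mean()) if steps.size else np.nan
                row["daily_radius_km_mean"] = rad_mean
                row["daily_radius_km_sd"] = rad_sd
        rows.append(row)

    out = {"deployment_summary": pd.DataFrame(rows)}
    if cluster_table is not None:
        out["cluster_summary"] = cluster_table
    if approach_summary is not None:
        out["approach_summary"] = approach_summary
    return out
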