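"""Echo-to-noise-ratio (ENR) echogram analysis around prey-capture attempts.

An echogram is a pings-by-range-bins image of ENR (echo level minus
background noise, dB, floored at 0) covering the window from 5 s before a
PrCA starts to 5 s after it ends, with a 25 Hz ping rate and a 7 m range.
The analysis extracts, per window:

* a seafloor line (deepest persistent supra-threshold ridge) -> benthic flag,
* prey traces (8-connected supra-threshold components after seafloor
  masking), counted as one target or several (overlapping ping columns),
* the prey reaction class: "leave_seafloor" (straight, negative-slope
  departure from the seafloor ridge), "escape" (curved trace clear of the
  floor whose range decreases then increases) or "none",
* the reaction onset (time relative to the PrCA start, range in cm), and
* the acoustic size: median per-ping supra-threshold pixel extent, in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Echogram",
    "SeafloorLine",
    "PreyTrace",
    "compute_enr",
    "detect_seafloor",
    "extract_prey_traces",
    "classify_reaction",
    "measure_acoustic_size",
    "summarize_prey",
]

ENR_THRESHOLD_DB = 9.0  # pixel-inclusion threshold; reported with results
GUARD_BINS = 2  # masked band above the detected seafloor ridge


@dataclass
class Echogram:
    """ENR image around one PrCA: ``enr`` has shape (n_pings, n_bins)."""

    ping_times: np.ndarray  # s, absolute
    ranges: np.ndarray  # m, bin centers
    enr: np.ndarray  # dB
    prca_id: int = -1
    window: tuple = (0.0, 0.0)  # (t_start - 5 s, t_end + 5 s)

    def __post_init__(self):
        if self.enr.shape != (self.ping_times.size, self.ranges.size):
            raise ValueError("ENR shape must be (n_pings, n_bins)")

    @property
    def range_resolution(self) -> float:
        return float(self.ranges[1] - self.ranges[0])


@dataclass
class SeafloorLine:
    """Per-ping seafloor range (NaN where absent) and its ping coverage."""

    ranges: np.ndarray  # m, NaN where no ridge found
    top_bins: np.ndarray  # shallow edge (bin index) of the ridge per ping
    coverage: float
    present: bool

    def range_at(self, ping: int) -> float:
        if np.isnan(self.ranges[ping]):
            valid = np.flatnonzero(~np.isnan(self.ranges))
            if valid.size == 0:
                return np.nan
            return float(self.ranges[valid[np.argmin(np.abs(valid - ping))]])
        return float(self.ranges[ping])


@dataclass
class PreyTrace:
    """One connected prey echo."""

    pixels: np.ndarray = field(repr=False)  # (k, 2) array of (ping, bin)
    pings: np.ndarray = field(repr=False)  # ping columns with trace pixels
    polyline_min: np.ndarray = field(repr=False)  # per-ping min range, m
    polyline_center: np.ndarray = field(repr=False)  # per-ping run center, m
    n_targets: str = "one"  # or "several"
    reaction: str = "none"
    onset_time: float = np.nan  # s relative to PrCA start (may be negative)
    onset_range_cm: float = np.nan
    acoustic_size_cm: float = np.nan
    isolated: bool = True


def compute_enr(echo_db: np.ndarray, noise_db: np.ndarray, **kwargs) -> Echogram:
    """ENR = echo - noise per range bin, floored at 0 dB.  ``noise_db`` may
    be a per-bin profile or a full matrix."""
    echo = np.asarray(echo_db, dtype=float)
    noise = np.asarray(noise_db, dtype=float)
    if noise.ndim == 1:
        if noise.size != echo.shape[1]:
            raise ValueError("noise profile does not match the bin axis")
        noise = noise[None, :]
    elif noise.shape != echo.shape:
        raise ValueError("echo and noise shapes do not match")
    enr = np.clip(echo - noise, 0.0, None)
    n_pings, n_bins = enr.shape
    ping_times = kwargs.get("ping_times", np.arange(n_pings) / 25.0)
    ranges = kwargs.get("ranges", (np.arange(n_bins) + 0.5) * (7.0 / n_bins))
    return Echogram(ping_times=np.asarray(ping_times, float),
                    ranges=np.asarray(ranges, float), enr=enr,
                    prca_id=kwargs.get("prca_id", -1),
                    window=kwargs.get("window", (0.0, 0.0)))


def _deepest_run(row_mask: np.ndarray, min_len: int = 2):
    """Deepest contiguous True run with at least ``min_len`` bins of a 1-D
    mask -> (lo, hi) or None.  Requiring 2+ contiguous bins rejects isolated
    single-pixel noise exceedances deeper than the true ridge."""
    idx = np.flatnonzero(row_mask)
    while idx.size:
        hi = idx[-1]
        lo = hi
        while lo > 0 and row_mask[lo - 1]:
            lo -= 1
        if hi - lo + 1 >= min_len:
            return lo, hi
        idx = idx[idx < lo]
    return None


def detect_seafloor(
    eg: Echogram,
    enr_min: float = ENR_THRESHOLD_DB,
    min_coverage: float = 0.3,
    max_jump_bins: int = 3,
) -> SeafloorLine:
    """Detect the seafloor ridge: per ping, the deepest-range contiguous
    supra-threshold run; pings are kept when the run center stays within
    ``max_jump_bins`` of the local median ridge.  If fewer than
    ``min_coverage`` of pings carry a consistent ridge, the seafloor is
    declared absent (pelagic window)."""
    mask = eg.enr > enr_min
    n_pings = mask.shape[0]
    centers = np.full(n_pings, np.nan)
    tops = np.full(n_pings, -1, dtype=int)
    for p in range(n_pings):
        run = _deepest_run(mask[p])
        if run is not None:
            centers[p] = 0.5 * (run[0] + run[1])
            tops[p] = run[0]

    valid = ~np.isnan(centers)
    if valid.sum() >= 3:
        # local median over a 9-ping window for range continuity
        series = pd.Series(centers)
        med = series.rolling(9, center=True, min_periods=1).median().to_numpy()
        valid &= np.abs(centers - med) <= max_jump_bins
    coverage = float(valid.mean())
    present = coverage >= min_coverage

    res = eg.range_resolution
    ranges = np.where(valid, (centers + 0.5) * res, np.nan)
    tops = np.where(valid, tops, -1)
    if not present:
        ranges = np.full(n_pings, np.nan)
        tops = np.full(n_pings, -1, dtype=int)
    return SeafloorLine(ranges=ranges, top_bins=tops, coverage=coverage,
                        present=present)


def _seafloor_top_bins(eg: Echogram, seafloor: SeafloorLine) -> np.ndarray:
    """Per-ping shallow edge of the ridge, interpolated over missing pings."""
    tops = seafloor.top_bins.astype(float)
    tops[tops < 0] = np.nan
    if np.all(np.isnan(tops)):
        return np.full(eg.enr.shape[0], eg.enr.shape[1], dtype=int)
    idx = np.arange(tops.size)
    good = ~np.isnan(tops)
    tops = np.interp(idx, idx[good], tops[good])
    return np.floor(tops).astype(int)


def extract_prey_traces(
    eg: Echogram,
    seafloor: SeafloorLine,
    enr_min: float = ENR_THRESHOLD_DB,
    min_pixels: int = 6,
    min_pings: int = 3,
    guard_bins: int = GUARD_BINS,
) -> list[PreyTrace]:
    """Extract prey traces as 8-connected supra-threshold components after
    masking the seafloor ridge plus a guard band above it.

    Components with at least ``min_pixels`` pixels spanning at least
    ``min_pings`` ping columns are kept.  Components that overlap another
    component on 3 or more common ping columns are labelled
    ``n_targets='several'`` (more than one prey echo within the same ping).
    """
    mask = eg.enr > enr_min
    if seafloor.present:
        tops = _seafloor_top_bins(eg, seafloor)
        cols = np.arange(mask.shape[1])[None, :]
        mask &= cols < (tops[:, None] - guard_bins)

    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    res = eg.range_resolution
    comps = []
    for lab in range(1, n_lab + 1):
        pix = np.argwhere(labels == lab)
        pings = np.unique(pix[:, 0])
        if pix.shape[0] < min_pixels or pings.size < min_pings:
            continue
        poly_min = np.full(pings.size, np.nan)
        poly_ctr = np.full(pings.size, np.nan)
        for k, p in enumerate(pings):
            bins = np.sort(pix[pix[:, 0] == p, 1])
            poly_min[k] = (bins.min() + 0.5) * res
            poly_ctr[k] = (bins.mean() + 0.5) * res
        comps.append(PreyTrace(pixels=pix, pings=pings,
                               polyline_min=poly_min, polyline_center=poly_ctr))

    for i, tr in enumerate(comps):
        shared = 0
        for j, other in enumerate(comps):
            if i == j:
                continue
            shared = max(shared, np.intersect1d(tr.pings, other.pings).size)
        if shared >= 3:
            tr.n_targets = "several"
            tr.isolated = False
    return comps


def _smooth(x: np.ndarray, w: int = 5) -> np.ndarray:
    if x.size < 3:
        return x
    return pd.Series(x).rolling(w, center=True, min_periods=1).mean().to_numpy()


def classify_reaction(
    trace: PreyTrace,
    seafloor: SeafloorLine,
    eg: Echogram,
    prca_start: float,
    eps_floor: float = 0.10,
    slope_min: float = 0.03,
    v_min: float = 0.05,
) -> PreyTrace:
    """Classify the prey reaction from the trace geometry and estimate the
    reaction onset.

    * ``leave_seafloor``: the first trace point lies within ``eps_floor``
      (10 cm) of the seafloor range and the linear fit of range over time
      has slope below ``-slope_min`` (a straight departure from the floor).
    * ``escape``: the whole trace stays more than ``eps_floor`` above the
      floor and a quadratic fit opens upward with an interior minimum
      (range decreasing then increasing).
    * otherwise ``none`` (including degenerate traces of < 4 pings).

    When both sets of criteria fire, the departure origin wins and the
    trace is ``leave_seafloor``.  The onset is the first ping where the
    smoothed range rate exceeds ``v_min`` (m/s) over a 3-ping span; the
    onset time is reported relative to ``prca_start`` and the onset range
    in cm from the sonar (for ``leave_seafloor`` the seafloor range at the
    onset ping, i.e. the departure origin).
    """
    if trace.pings.size < 4:
        trace.reaction = "none"
        return trace

    t = eg.ping_times[trace.pings]
    r = _smooth(trace.polyline_center)
    r_min = trace.polyline_min

    floor_r = np.array([seafloor.range_at(p) for p in trace.pings]) \
        if seafloor.present else np.full(trace.pings.size, np.nan)

    span = float(r.max() - r.min())  # a moving prey sweeps a range interval
    lin = np.polyfit(t - t[0], r, 1)
    is_leave = False
    if seafloor.present and np.isfinite(floor_r[0]) and span > 0.06:
        near_floor = (floor_r[0] - r_min[0]) <= eps_floor
        is_leave = near_floor and lin[0] < -slope_min

    is_escape = False
    if not is_leave and t.size >= 5 and span > 0.06:
        clearance_ok = (
            seafloor.present
            and np.all(np.isfinite(floor_r))
            and np.nanmin(floor_r - r_min) > eps_floor
        )
        quad = np.polyfit(t - t[0], r, 2)
        if clearance_ok and quad[0] > 0:
            t_vertex = -quad[1] / (2 * quad[0])
            has_dip = (r[0] - r.min() > 0.04) and (r[-1] - r.min() > 0.04)
            is_escape = (0 < t_vertex < (t[-1] - t[0])) and has_dip

    trace.reaction = "leave_seafloor" if is_leave else ("escape" if is_escape else "none")
    if trace.reaction == "none":
        return trace

    # onset: first ping whose 3-ping-span smoothed range rate exceeds v_min
    vel = np.gradient(r, t)
    moving = np.flatnonzero(np.abs(vel) > v_min)
    k_on = int(moving[0]) if moving.size else 0
    if trace.reaction == "leave_seafloor" and np.isfinite(floor_r[k_on]):
        # the trace only becomes visible after clearing the ridge and guard
        # band; the departure moment is where the fitted line intersects
        # the seafloor range, extrapolated backwards (bounded at 1.5 s)
        t_star = t[0] + (floor_r[0] - lin[1]) / lin[0]
        t_star = float(np.clip(t_star, t[0] - 1.5, t[-1]))
        trace.onset_time = t_star - prca_start
        k_floor = int(np.argmin(np.abs(t - t_star)))
        trace.onset_range_cm = float(floor_r[k_floor] * 100.0)
    else:
        trace.onset_time = float(t[k_on] - prca_start)
        trace.onset_range_cm = float(trace.polyline_center[k_on] * 100.0)
    return trace


def measure_acoustic_size(
    trace: PreyTrace,
    eg: Echogram,
    enr_min: float = ENR_THRESHOLD_DB,
) -> float:
    """Acoustic size: median over ping columns of the contiguous
    supra-threshold pixel extent, times the range-bin width, in cm.

    Only meaningful for clearly isolated traces; a non-isolated trace gets
    NaN (size undefined) and keeps its flag."""
    if not trace.isolated:
        trace.acoustic_size_cm = np.nan
        return np.nan
    res_cm = eg.range_resolution * 100.0
    extents = []
    for p in trace.pings:
        bins = np.sort(trace.pixels[trace.pixels[:, 0] == p, 1])
        # longest contiguous run within this column
        best = run = 1
        for a, b in zip(bins[:-1], bins[1:]):
            run = run + 1 if b == a + 1 else 1
            best = max(best, run)
        extents.append(best)
    size = float(np.median(extents) * res_cm)
    trace.acoustic_size_cm = size
    return size


def summarize_prey(prey: pd.DataFrame) -> pd.DataFrame:
    """Per-individual and pooled prey-interaction summary.

    ``prey`` must carry one row per PrCA with columns ``individual``,
    ``visible``, ``n_targets``, ``reaction``, ``onset_time``,
    ``onset_range_cm`` and ``size_cm``.  The output mirrors the standard
    prey-characteristics table: school/single counts, reaction-type counts
    and min/max/mean+-SD of reaction distance, reaction time and acoustic
    size.
    """
    if prey.empty:
        return pd.DataFrame()

    def _block(df: pd.DataFrame, label: str) -> dict:
        vis = df[df["visible"].astype(bool)]
        reac = vis[vis["reaction"].isin(["escape", "leave_seafloor"])]
        out = {
            "individual": label,
            "n_prcas": len(df),
            "n_with_traces": len(vis),
            "n_school": int((vis["n_targets"] == "several").sum()),
            "n_single": int((vis["n_targets"] == "one").sum()),
            "n_reactive": len(reac),
            "n_leave_seafloor": int((reac["reaction"] == "leave_seafloor").sum()),
            "n_escape": int((reac["reaction"] == "escape").sum()),
        }
        for col, name in [("onset_range_cm", "distance_cm"),
                          ("onset_time", "reaction_time_s"),
                          ("size_cm", "size_cm")]:
            vals = reac[col].dropna() if col != "size_cm" else vis[col].dropna()
            out[f"{name}_min"] = float(vals.min()) if len(vals) else np.nan
            out[f"{name}_max"] = float(vals.max()) if len(vals) else np.nan
            out[f"{name}_mean"] = float(vals.mean()) if len(vals) else np.nan
            out[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        return out

    rows = [_block(g, ind) for ind, g in prey.groupby("individual")]
    rows.append(_block(prey, "total"))
    return pd.DataFrame(rows)
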