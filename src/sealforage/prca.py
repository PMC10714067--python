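"""Prey-capture-attempt (PrCA) detection from triaxial acceleration.

The detection statistic is the RMS-jerk: the norm of the differenced
triaxial acceleration scaled by the sampling rate (m/s^3), smoothed by a
centered sliding root-mean-square.  A PrCA starts when the RMS-jerk
exceeds the 150 m/s^3 threshold and ends when it drops back below; bursts
separated by less than the merge gap (5 s) are consolidated into a single
event before the minimum-duration rule (5 s) is applied, so that one long
capture composed of several peaks is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DetectorConfig",
    "compute_jerk",
    "rms_jerk",
    "detect_events",
    "survival_curve",
    "contextualize_events",
]

EVENT_COLUMNS = ["event_id", "start", "end", "duration_s", "peak_rms"]


@dataclass
class DetectorConfig:
    threshold: float = 150.0  # m/s^3
    min_duration: float = 5.0  # s
    merge_gap: float = 5.0  # s
    rms_window: float = 0.2  # s

    def __post_init__(self):
        if min(self.threshold, self.min_duration, self.merge_gap, self.rms_window) <= 0:
            raise ValueError("all detector parameters must be positive")


def compute_jerk(accel: np.ndarray, fs: float, central: bool = False) -> np.ndarray:
    """Jerk magnitude: ``fs * ||a[k+1] - a[k]||`` (length n-1).

    With ``central=True`` a central difference ``fs/2 * ||a[k+1]-a[k-1]||``
    is used instead (length n-2).
    """
    a = np.asarray(accel, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("accel must have shape (n, 3)")
    if a.shape[0] < (3 if central else 2):
        raise ValueError("too few samples to differentiate")
    if central:
        d = (a[2:] - a[:-2]) * (fs / 2.0)
    else:
        d = np.diff(a, axis=0) * fs
    return np.linalg.norm(d, axis=1)


def rms_jerk(jerk: np.ndarray, fs: float, window: float = 0.2) -> np.ndarray:
    """Centered sliding root-mean-square of the jerk magnitude, hop of one
    sample; edge windows shrink so the output has the input length."""
    j = np.asarray(jerk, dtype=float)
    w = int(round(window * fs))
    if w < 2:
        raise ValueError("RMS window must span at least 2 samples")
    if w > j.size:
        raise ValueError("RMS window longer than the record")
    half = w // 2
    n = j.size
    c = np.concatenate([[0.0], np.cumsum(j**2)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return np.sqrt((c[hi] - c[lo]) / (hi - lo))


def detect_events(
    rms: np.ndarray,
    fs: float,
    config: DetectorConfig | None = None,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Threshold, merge and duration-filter the RMS-jerk series.

    Raw events are maximal supra-threshold runs (strict >).  Runs separated
    by gaps shorter than ``merge_gap`` are merged; merged events shorter
    than ``min_duration`` are discarded.  Events are reported with start and
    end times (s), duration, and the peak RMS-jerk inside the event.
    """
    cfg = config or DetectorConfig()
    r = np.asarray(rms, dtype=float)
    above = r > cfg.threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    starts, ends = edges[::2], edges[1::2]  # half-open sample ranges

    merged: list[list[int]] = []
    for i0, i1 in zip(starts, ends):
        if merged and (i0 - merged[-1][1]) / fs < cfg.merge_gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])

    rows = []
    for i0, i1 in merged:
        dur = (i1 - i0) / fs
        if dur < cfg.min_duration:
            continue
        rows.append(
            {
                "event_id": len(rows),
                "start": t0 + i0 / fs,
                "end": t0 + i1 / fs,
                "duration_s": dur,
                "peak_rms": float(r[i0:i1].max()),
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def survival_curve(gaps, grid: np.ndarray | None = None):
    """Survival function of inter-event gaps and a suggested merge threshold.

    ``S(delta)`` is the fraction of gaps strictly greater than ``delta`` on a
    fixed grid.  The suggested threshold is the knee of S — the grid point
    furthest below the chord from (0, S(0)) to (max, S(max)) — which for a
    bimodal gap distribution falls between the within-burst and
    between-burst modes.  It is reported for inspection only; the default
    5 s merge gap is not changed by it.

    Returns ``(grid, S, suggested_threshold)``; empty input yields empty
    arrays and ``None``.
    """
    g = np.asarray(list(gaps), dtype=float)
    if g.size == 0:
        return np.array([]), np.array([]), None
    if np.any(g < 0):
        raise ValueError("gaps must be non-negative")
    if grid is None:
        grid = np.linspace(0.0, float(g.max()), 201)
    grid = np.asarray(grid, dtype=float)
    s = (g[None, :] > grid[:, None]).mean(axis=1)
    if grid.size < 3 or grid[-1] == grid[0]:
        return grid, s, None
    chord = s[0] + (s[-1] - s[0]) * (grid - grid[0]) / (grid[-1] - grid[0])
    suggested = float(grid[int(np.argmax(chord - s))])
    return grid, s, suggested


def contextualize_events(
    events: pd.DataFrame,
    dives,
    depth: np.ndarray,
    fs: float = 5.0,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Attach depth at event start and the containing dive to each event.

    Events whose start lies outside any dive (i.e. at <= 5 m) are flagged
    ``excluded`` and carry ``dive_id = -1``; downstream counts ignore them.
    """
    depth = np.asarray(depth, dtype=float)
    out = events.copy()
    depths, dive_ids, excluded = [], [], []
    intervals = [(d.start, d.end, d.id) for d in dives]
    for start in out["start"].to_numpy():
        idx = int(round((start - t0) * fs))
        if idx < 0 or idx >= depth.size:
            raise ValueError("event outside the depth record")
        depths.append(float(depth[idx]))
        hit = next((i for (s, e, i) in intervals if s <= start < e), None)
        dive_ids.append(-1 if hit is None else hit)
        excluded.append(hit is None)
    out["depth_m"] = depths
    out["dive_id"] = dive_ids
    out["excluded"] = excluded
    return out
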