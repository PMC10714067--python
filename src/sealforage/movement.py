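"""Sensor calibration, dive segmentation and dive-level labelling.

Depth is positive downward with the surface at 0 m; raw negative readings
are clamped to 0 before segmentation.  A dive is a maximal run of samples
strictly deeper than the 5 m threshold; runs in (0, 5] m are kept
separately as shallow under-ice activity.  Day period is classified from
the solar elevation at the dive start (day > 0 deg, twilight in [-12, 0],
night below -12).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .solar import solar_elevation, to_epoch_seconds

__all__ = [
    "CalibrationSpec",
    "Dive",
    "calibrate",
    "downsample",
    "segment_dives",
    "solar_angle",
    "classify_day_period",
    "bin_dives_by_depth",
    "dives_to_frame",
]

DIVE_THRESHOLD_M = 5.0


@dataclass
class CalibrationSpec:
    """Per-axis affine calibration, with an optional fixed mounting rotation
    applied after the affine map (``out = rotation @ (gain * (raw - offset))``
    per sample)."""

    offset: Sequence[float] = (0.0, 0.0, 0.0)
    gain: Sequence[float] = (1.0, 1.0, 1.0)
    rotation: Optional[np.ndarray] = None

    def __post_init__(self):
        self.offset = np.asarray(self.offset, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        if np.any(self.gain == 0):
            raise ValueError("calibration gains must be non-zero")
        if self.rotation is not None:
            self.rotation = np.asarray(self.rotation, dtype=float)
            if self.rotation.shape != (3, 3):
                raise ValueError("rotation must be a 3x3 matrix")


def calibrate(raw: np.ndarray, spec: CalibrationSpec) -> np.ndarray:
    """Apply an affine (offset, gain) calibration and optional rotation to a
    triaxial stream of shape (n, 3)."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != spec.offset.size:
        raise ValueError("stream axes do not match calibration spec")
    out = spec.gain * (raw - spec.offset)
    if spec.rotation is not None:
        out = out @ spec.rotation.T
    return out


def downsample(x: np.ndarray, native_fs: float, target_fs: float) -> np.ndarray:
    """Anti-aliased decimation: moving average over each decimation window,
    then one sample per window.  ``target_fs`` must divide ``native_fs``."""
    ratio = native_fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("target_fs must be an integer divisor of native_fs")
    k = int(round(ratio))
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    m = int(np.ceil(n / k))
    pad = m * k - n
    if pad:
        x = np.concatenate([x, np.repeat(x[-1:], pad, axis=0)], axis=0)
    shape = (m, k) + x.shape[1:]
    return x.reshape(shape).mean(axis=1)


@dataclass
class Dive:
    """One submergence deeper than the dive threshold."""

    id: int
    start: float  # s, time of first sample below threshold
    end: float  # s, time of last sample below threshold
    max_depth: float  # m
    profile: np.ndarray = field(repr=False)  # depth samples at analysis fs
    t: np.ndarray = field(repr=False)  # sample times, s
    individual: str = ""
    period: Optional[str] = None
    depth_bin: Optional[int] = None
    benthic: Optional[bool] = None

    @property
    def duration_min(self) -> float:
        return (self.end - self.start) / 60.0


def segment_dives(
    depth: np.ndarray,
    fs: float = 5.0,
    threshold: float = DIVE_THRESHOLD_M,
    t0: float = 0.0,
    individual: str = "",
):
    """Segment a cleaned depth series into dives and shallow-activity bouts.

    Returns ``(dives, shallow)`` where ``dives`` is a list of :class:`Dive`
    (maximal runs strictly deeper than ``threshold``) and ``shallow`` is a
    DataFrame of runs with depth in (0, threshold].  Boundaries are the
    first/last samples of each run; times are ``t0 + index / fs``.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.size == 0:
        raise ValueError("empty depth series")
    depth = np.clip(depth, 0.0, None)

    dives: list[Dive] = []
    for i0, i1 in _runs(depth > threshold):
        t = t0 + np.arange(i0, i1) / fs
        prof = depth[i0:i1]
        dives.append(
            Dive(
                id=len(dives),
                start=float(t[0]),
                end=float(t[-1] + 1.0 / fs),
                max_depth=float(prof.max()),
                profile=prof,
                t=t,
                individual=individual,
            )
        )
    shallow_rows = [
        {
            "start": t0 + i0 / fs,
            "end": t0 + i1 / fs,
            "duration_s": (i1 - i0) / fs,
            "max_depth_m": float(depth[i0:i1].max()),
            "individual": individual,
        }
        for i0, i1 in _runs((depth > 0) & (depth <= threshold))
    ]
    shallow = pd.DataFrame(
        shallow_rows,
        columns=["start", "end", "duration_s", "max_depth_m", "individual"],
    )
    return dives, shallow


def _runs(mask: np.ndarray):
    """Half-open index ranges [i0, i1) of the True runs of a boolean mask."""
    m = np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], m, [False]))))
    return list(zip(edges[::2], edges[1::2]))


def solar_angle(lat: float, lon: float, t):
    """Solar elevation in degrees at (lat, lon) and UTC time(s) ``t``."""
    return solar_elevation(lat, lon, t)


def classify_day_period(elevation) -> np.ndarray:
    """Map solar elevation (deg) to 'day' (> 0), 'twilight' ([-12, 0]) or
    'night' (< -12); the twilight interval is closed at both ends."""
    e = np.asarray(elevation, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("elevation must be finite")
    out = np.where(e > 0, "day", np.where(e >= -12.0, "twilight", "night"))
    return out.item() if np.ndim(elevation) == 0 else out


def bin_dives_by_depth(dives, bin_width: float = 40.0) -> dict[int, int]:
    """Count dives per maximum-depth bin ``[k*w, (k+1)*w)``.  Accepts a list
    of :class:`Dive` or an array of maximum depths."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(dives) and isinstance(dives[0], Dive):
        depths = np.asarray([d.max_depth for d in dives], dtype=float)
    else:
        depths = np.asarray(dives, dtype=float)
    if depths.size == 0:
        return {}
    idx = np.floor(depths / bin_width).astype(int)
    keys, counts = np.unique(idx, return_counts=True)
    return dict(zip(keys.tolist(), counts.tolist()))


def dives_to_frame(
    dives: list[Dive],
    t0_utc=None,
    lat: Optional[float] = None,
    lon: Optional[float] = None,
    bin_width: float = 40.0,
) -> pd.DataFrame:
    """Tabulate dives; when a UTC start time and location are given, also
    label each dive with its day period at the dive start."""
    rows = []
    epoch0 = to_epoch_seconds(t0_utc) if t0_utc is not None else None
    for d in dives:
        period = d.period
        if period is None and epoch0 is not None and lat is not None:
            elev = solar_elevation(lat, lon, float(epoch0) + d.start)
            period = classify_day_period(elev)
            d.period = period
        d.depth_bin = int(d.max_depth // bin_width)
        rows.append(
            {
                "dive_id": d.id,
                "individual": d.individual,
                "start": d.start,
                "end": d.end,
                "duration_min": d.duration_min,
                "max_depth_m": d.max_depth,
                "period": period,
                "depth_bin": d.depth_bin,
                "benthic": d.benthic,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["dive_id", "individual", "start", "end", "duration_min",
                 "max_depth_m", "period", "depth_bin", "benthic"],
    )
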