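"""Body orientation, dead-reckoned tracks, strokes and head turns.

Conventions (documented once, used consistently by the generator and the
estimators): the world frame is north/east/up; heading is in (-180, 180]
degrees with 0 at magnetic north and negative values a leftward rotation;
pitch is positive nose-up; roll positive right-side-down.  At rest the
accelerometer reads ``g * (sin(pitch), cos(pitch) sin(roll),
cos(pitch) cos(roll))``, so pitch = asin(ax/g) and roll = atan2(ay, az).
Heading comes from the tilt-compensated magnetic field and is corrected by
the local declination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "OrientationSeries",
    "LocalTrack",
    "euler_to_matrix",
    "body_vector",
    "compute_orientation",
    "dead_reckon",
    "filter_strokes",
    "count_strokes",
    "detect_head_turn",
    "summarize_approach",
    "wrap_angle",
]


def wrap_angle(deg) -> np.ndarray:
    """Wrap angles to (-180, 180] degrees."""
    d = np.asarray(deg, dtype=float)
    return -(np.mod(-d + 180.0, 360.0) - 180.0)


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_to_matrix(heading_deg: float, pitch_deg: float, roll_deg: float) -> np.ndarray:
    """Body-to-world rotation matrix for the conventions above (world axes
    north/east/up)."""
    psi, th, ph = np.deg2rad([heading_deg, pitch_deg, roll_deg])
    return _rot_z(psi) @ _rot_y(-th) @ _rot_x(ph)


def body_vector(world_vec, heading_deg, pitch_deg, roll_deg) -> np.ndarray:
    """Express a world-frame vector in body coordinates for the given Euler
    angles (vectorized over angle arrays)."""
    psi = np.deg2rad(np.asarray(heading_deg, dtype=float))
    th = np.deg2rad(np.asarray(pitch_deg, dtype=float))
    ph = np.deg2rad(np.asarray(roll_deg, dtype=float))
    v = np.asarray(world_vec, dtype=float)
    # Rz(psi)^T
    x = np.cos(psi) * v[0] + np.sin(psi) * v[1]
    y = -np.sin(psi) * v[0] + np.cos(psi) * v[1]
    z = np.broadcast_to(v[2], x.shape).astype(float)
    # Ry(-th)^T
    x2 = np.cos(th) * x + np.sin(th) * z
    z2 = -np.sin(th) * x + np.cos(th) * z
    # Rx(ph)^T
    y2 = np.cos(ph) * y + np.sin(ph) * z2
    z3 = -np.sin(ph) * y + np.cos(ph) * z2
    return np.stack([x2, y2, z3], axis=-1)


@dataclass
class OrientationSeries:
    t: np.ndarray = field(repr=False)
    pitch: np.ndarray = field(repr=False)  # deg, positive nose-up
    roll: np.ndarray = field(repr=False)  # deg
    heading: np.ndarray = field(repr=False)  # deg in (-180, 180]
    reliable: np.ndarray = field(repr=False)  # False where |a| far from g


@dataclass
class LocalTrack:
    t: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)  # m north of the dive start
    y: np.ndarray = field(repr=False)  # m east of the dive start
    z: np.ndarray = field(repr=False)  # m, positive down
    speed: np.ndarray = field(repr=False)
    speed_model: np.ndarray = field(repr=False)  # 'pitch' or 'fallback'


def _lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def compute_orientation(
    accel: np.ndarray,
    mag: np.ndarray,
    fs: float = 5.0,
    g: float = 9.81,
    declination_deg: float = 0.0,
    lowpass_hz: float = 0.5,
    t0: float = 0.0,
) -> OrientationSeries:
    """Pitch, roll and heading from calibrated acceleration and magnetometry
    on a common time base.

    The static (gravitational) acceleration is isolated by a zero-phase
    low-pass filter; samples whose static magnitude departs from g by more
    than 30 % are flagged unreliable.  Heading is tilt-compensated and
    declination-corrected.
    """
    a = np.asarray(accel, dtype=float)
    m = np.asarray(mag, dtype=float)
    if a.shape != m.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("accel and mag must share an (n, 3) shape")
    if lowpass_hz and lowpass_hz < fs / 2 and a.shape[0] > 12:
        a_static = _lowpass(a, fs, lowpass_hz)
    else:
        a_static = a.copy()

    norm = np.linalg.norm(a_static, axis=1)
    reliable = np.abs(norm - g) <= 0.3 * g
    pitch = np.rad2deg(np.arcsin(np.clip(a_static[:, 0] / g, -1.0, 1.0)))
    roll = np.rad2deg(np.arctan2(a_static[:, 1], a_static[:, 2]))

    # de-tilt the magnetic field: w = Ry(-pitch) Rx(roll) m_body
    th = np.deg2rad(pitch)
    ph = np.deg2rad(roll)
    my2 = np.cos(ph) * m[:, 1] - np.sin(ph) * m[:, 2]
    mz2 = np.sin(ph) * m[:, 1] + np.cos(ph) * m[:, 2]
    mx3 = np.cos(th) * m[:, 0] - np.sin(th) * mz2
    heading = np.rad2deg(np.arctan2(-my2, mx3)) + declination_deg
    heading = wrap_angle(heading)

    t = t0 + np.arange(a.shape[0]) / fs
    return OrientationSeries(t=t, pitch=pitch, roll=roll, heading=heading,
                             reliable=reliable)


def dead_reckon(
    orient: OrientationSeries,
    depth: np.ndarray,
    fs: float = 5.0,
    pitch_min_deg: float = 20.0,
    speed_clamp: tuple = (0.2, 3.0),
    fallback_speed: float = 1.0,
) -> LocalTrack:
    """Dead-reckon a local 3-D track from orientation and depth.

    Per-sample speed is |depth rate| / |sin(pitch)| where |pitch| exceeds
    ``pitch_min_deg`` (clamped to ``speed_clamp``), otherwise a constant
    fallback.  Steps are ``s dt (cos(pitch) cos(heading),
    cos(pitch) sin(heading), -sin(pitch))`` with x north, y east and z down;
    z starts at the measured depth.
    """
    depth = np.asarray(depth, dtype=float)
    n = depth.size
    if orient.pitch.size != n:
        raise ValueError("orientation and depth must be aligned")
    dt = 1.0 / fs
    depth_rate = np.gradient(depth) * fs  # m/s, positive when descending
    th = np.deg2rad(orient.pitch)
    psi = np.deg2rad(orient.heading)

    use_pitch = np.abs(orient.pitch) > pitch_min_deg
    with np.errstate(divide="ignore", invalid="ignore"):
        s_pitch = np.abs(depth_rate) / np.abs(np.sin(th))
    speed = np.where(use_pitch,
                     np.clip(s_pitch, speed_clamp[0], speed_clamp[1]),
                     fallback_speed)
    model = np.where(use_pitch, "pitch", "fallback")

    dx = speed * dt * np.cos(th) * np.cos(psi)
    dy = speed * dt * np.cos(th) * np.sin(psi)
    dz = -speed * dt * np.sin(th)  # nose-down pitch (<0) increases depth
    x = np.concatenate([[0.0], np.cumsum(dx[:-1])])
    y = np.concatenate([[0.0], np.cumsum(dy[:-1])])
    z = depth[0] + np.concatenate([[0.0], np.cumsum(dz[:-1])])
    return LocalTrack(t=orient.t, x=x, y=y, z=z, speed=speed, speed_model=model)


def filter_strokes(
    lateral: np.ndarray,
    fs: float,
    band: tuple = (0.4, 2.5),
    trend_hz: float = 0.05,
):
    """Split lateral acceleration into a stroke component (zero-phase
    band-pass over the stroking band), a slow gravity/posture trend, and a
    residual attributed to other lateral movements such as head turns.

    Returns ``(stroke, residual)`` with ``residual = raw - trend - stroke``.
    """
    x = np.asarray(lateral, dtype=float)
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError("band must satisfy 0 < low < high < fs/2")
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    stroke = signal.sosfiltfilt(sos, x)
    trend = _lowpass(x, fs, trend_hz, order=2) if trend_hz else np.zeros_like(x)
    residual = x - trend - stroke
    return stroke, residual


def count_strokes(
    stroke: np.ndarray,
    fs: float,
    window: Optional[tuple] = None,
    t0: float = 0.0,
    amp_min: float = 0.3,
    min_spacing: float = 0.3,
    residual: Optional[np.ndarray] = None,
    snr_min: float = 1.5,
) -> int:
    """Count stroke peaks: local maxima of the filtered lateral acceleration
    with prominence >= ``amp_min`` (m/s^2) and spacing >= ``min_spacing`` s,
    optionally restricted to a time window.

    When the ``residual`` channel from :func:`filter_strokes` is supplied,
    peaks whose local stroke-band RMS does not exceed ``snr_min`` times the
    local residual RMS are rejected: broadband transients (capture lunges,
    head movements) and filter edge-ringing leak some energy into the stroke
    band but are desynchronized from it, whereas genuine stroking dominates
    the residual by an order of magnitude.
    """
    x = np.asarray(stroke, dtype=float)
    res = None if residual is None else np.asarray(residual, dtype=float)
    if window is not None:
        i0 = int(round((window[0] - t0) * fs))
        i1 = int(round((window[1] - t0) * fs))
        if i0 < 0 or i1 > x.size or i1 <= i0:
            raise ValueError("window outside the record")
        x = x[i0:i1]
        if res is not None:
            res = res[i0:i1]
    peaks, _ = signal.find_peaks(x, prominence=amp_min,
                                 distance=max(1, int(round(min_spacing * fs))))
    if res is None or peaks.size == 0:
        return int(peaks.size)
    half = max(int(round(0.6 * fs)), 1)
    kept = 0
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        if np.sqrt(np.mean(x[lo:hi] ** 2)) > snr_min * np.sqrt(np.mean(res[lo:hi] ** 2)):
            kept += 1
    return kept


def detect_head_turn(
    heading: np.ndarray,
    fs: float,
    t_reaction: float,
    t0: float = 0.0,
    half_window: float = 1.0,
    angle_min: float = 10.0,
) -> str:
    """Classify the net heading change within +-``half_window`` s of the
    prey-reaction time: 'left' for a wrapped change <= -``angle_min`` deg,
    'right' for >= +``angle_min``, else 'none'."""
    h = np.asarray(heading, dtype=float)
    i0 = int(round((t_reaction - half_window - t0) * fs))
    i1 = int(round((t_reaction + half_window - t0) * fs))
    if i0 < 0 or i1 >= h.size:
        raise ValueError("window outside the heading record")
    dpsi = wrap_angle(h[i1] - h[i0])
    if dpsi <= -angle_min:
        return "left"
    if dpsi >= angle_min:
        return "right"
    return "none"


def summarize_approach(windows: pd.DataFrame) -> pd.DataFrame:
    """Approach-behavior summary over reactive-prey PrCAs.

    ``windows`` carries one row per reactive PrCA with columns
    ``individual``, ``reaction`` ('escape' / 'leave_seafloor'),
    ``timing`` ('before' / 'during' / 'after'), ``strokes_before`` (bool),
    ``strokes_during`` (bool) and ``head_turn`` ('left'/'right'/'none').
    Percentages are reported per reaction type and pooled.
    """
    if windows.empty:
        return pd.DataFrame()

    def _row(df: pd.DataFrame, label: str) -> dict:
        n = len(df)
        pct = lambda mask: 100.0 * mask.sum() / n if n else np.nan
        return {
            "group": label,
            "n_prcas": n,
            "pct_before": pct(df["timing"] == "before"),
            "pct_during": pct(df["timing"] == "during"),
            "pct_after": pct(df["timing"] == "after"),
            "pct_strokes_before": pct(df["strokes_before"].astype(bool)),
            "pct_strokes_during": pct(df["strokes_during"].astype(bool)),
            "pct_turn_left": pct(df["head_turn"] == "left"),
            "pct_turn_right": pct(df["head_turn"] == "right"),
        }

    rows = []
    for ind, g in windows.groupby("individual"):
        for reaction, gg in g.groupby("reaction"):
            rows.append(_row(gg, f"{ind}:{reaction}"))
    for reaction, g in windows.groupby("reaction"):
        rows.append(_row(g, f"total:{reaction}"))
    rows.append(_row(windows, "total"))
    return pd.DataFrame(rows)
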