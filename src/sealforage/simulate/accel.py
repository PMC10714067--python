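"""Triaxial acceleration with stroke-and-capture structure.

The signal model is: a slowly varying gravitational (static) component set
by the posture, sinusoidal lateral flipper strokes during dives, broadband
sensor noise whose RMS-jerk sits well below the 150 m/s^3 detection
threshold, and, during each scheduled prey-capture attempt, a broadband
burst on all three axes whose RMS-jerk sits well above it.  The two noise
regimes realize the bimodal RMS-jerk distribution the detector threshold
relies on; per-event amplitudes are log-normally spread.
"""

from __future__ import annotations

import numpy as np

from ..behavior import body_vector

__all__ = ["simulate_acceleration", "jerk_noise_sigma"]


def jerk_noise_sigma(jerk_rms: float, fs: float) -> float:
    """Per-axis white-noise standard deviation (m/s^2) that produces a given
    RMS-jerk (m/s^3): differencing white noise of variance s^2 on 3 axes
    gives E[j^2] = 6 fs^2 s^2."""
    return jerk_rms / (fs * np.sqrt(6.0))


def simulate_acceleration(
    duration_s: float,
    fs: float,
    prca_schedule=(),
    dive_intervals=(),
    pitch_deg=0.0,
    roll_deg=0.0,
    stroke_gate: np.ndarray | None = None,
    stroke_freq: float = 1.2,
    stroke_amp: float = 0.6,
    jerk_noise_rms: float = 30.0,
    jerk_event_rms: float = 400.0,
    jerk_event_spread: float = 0.15,
    gravity: float = 9.81,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate an (n, 3) acceleration record in m/s^2.

    Parameters
    ----------
    prca_schedule
        Iterable of (start, end) times in seconds for capture attempts.
    dive_intervals
        Iterable of (start, end) times during which strokes occur (ignored
        when ``stroke_gate`` is given).
    pitch_deg, roll_deg
        Posture schedule: scalars or arrays of length n.
    stroke_gate
        Optional boolean array of length n gating the stroke component.
    """
    if int(fs) not in (200, 250):
        raise ValueError("accelerometer sampling rate must be 200 or 250 Hz")
    n = int(round(duration_s * fs))
    rng = rng if rng is not None else np.random.default_rng(0)
    t = np.arange(n) / fs

    pitch = np.broadcast_to(np.asarray(pitch_deg, dtype=float), (n,))
    roll = np.broadcast_to(np.asarray(roll_deg, dtype=float), (n,))
    a = body_vector([0.0, 0.0, gravity], np.zeros(n), pitch, roll)

    if stroke_gate is None:
        gate = np.zeros(n, dtype=bool)
        for s, e in dive_intervals:
            gate[int(round(s * fs)):int(round(e * fs))] = True
    else:
        gate = np.asarray(stroke_gate, dtype=bool)
        if gate.size != n:
            raise ValueError("stroke_gate length must match the record")
    if stroke_amp > 0:
        a[:, 1] += gate * stroke_amp * np.sin(2 * np.pi * stroke_freq * t
                                              + rng.uniform(0, 2 * np.pi))

    sigma = jerk_noise_sigma(jerk_noise_rms, fs)
    if sigma > 0:
        a += rng.normal(0.0, sigma, size=(n, 3))

    for s, e in prca_schedule:
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        if i1 <= i0 or i0 >= n:
            continue
        i1 = min(i1, n)
        amp = jerk_event_rms * rng.lognormal(0.0, jerk_event_spread)
        amp = max(amp, 1.7 * 150.0)  # keep every event clearly supra-threshold
        burst = rng.normal(0.0, jerk_noise_sigma(amp, fs), size=(i1 - i0, 3))
        # short cosine taper so the RMS-jerk crosses near the scheduled edges
        m = i1 - i0
        ramp = min(int(0.1 * fs), m // 4)
        env = np.ones(m)
        if ramp > 0:
            env[:ramp] = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
            env[-ramp:] = env[:ramp][::-1]
        a[i0:i1] += burst * env[:, None]
    return a
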