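"""Synthetic ENR echograms around prey-capture attempts.

The window spans from 5 s before the PrCA starts to 5 s after it ends at a
25 Hz ping rate, with 1 cm range bins over 0-7 m by default (so acoustic
sizes in cm map directly to pixel counts).  Background ENR is exponential
speckle below the 9 dB detection threshold; benthic windows carry a bright
seafloor ridge; visible prey are painted as supra-threshold traces whose
geometry encodes the scheduled reaction:

* ``leave_seafloor``: a straight negative-slope line departing from the
  seafloor ridge at the scheduled onset time and range,
* ``escape``: a curved trace (range decreasing then increasing) staying
  clear of the floor, preceded by a short stationary segment,
* ``none``: a range-stationary blob,
* schools: a second parallel trace sharing ping columns.
"""

from __future__ import annotations

import numpy as np

from ..echogram import Echogram

__all__ = ["simulate_echogram", "PreyScheduleEntry"]


def _paint(enr, p, center_bin, size_bins, level, n_bins, rng):
    half = (size_bins - 1) / 2.0
    lo = int(round(center_bin - half))
    hi = lo + size_bins
    lo, hi = max(lo, 0), min(hi, n_bins)
    if hi > lo:
        enr[p, lo:hi] = level + rng.normal(0, 0.8, hi - lo)


def simulate_echogram(
    prca_start: float,
    prca_end: float,
    truth: dict,
    ping_rate: float = 25.0,
    range_max: float = 7.0,
    range_resolution: float = 0.01,
    noise_enr_db: float = 1.2,
    seafloor_enr_db: float = 25.0,
    prey_enr_db: float = 18.0,
    ridge_halfwidth_bins: int = 2,
    rng: np.random.Generator | None = None,
    prca_id: int = -1,
) -> Echogram:
    """Simulate the ENR echogram for one PrCA window.

    ``truth`` is a mapping with keys ``benthic``, ``visible``, ``reaction``
    ('none' / 'escape' / 'leave_seafloor'), ``onset_rel_s`` (reaction onset
    relative to the PrCA start), ``onset_range_cm`` (distance from the
    sonar at the onset), ``size_cm``, ``school`` and ``seafloor_range_m``.
    """
    if range_resolution <= 0:
        raise ValueError("range_resolution must be positive")
    rng = rng if rng is not None else np.random.default_rng(0)
    t_lo, t_hi = prca_start - 5.0, prca_end + 5.0
    n_pings = int(round((t_hi - t_lo) * ping_rate))
    n_bins = int(round(range_max / range_resolution))
    ping_times = t_lo + np.arange(n_pings) / ping_rate

    enr = rng.exponential(noise_enr_db, size=(n_pings, n_bins))

    floor_bin = None
    if truth.get("benthic", False) and np.isfinite(truth.get("seafloor_range_m", np.nan)):
        floor_bin = truth["seafloor_range_m"] / range_resolution - 0.5
        jitter = (0.8 * np.sin(2 * np.pi * ping_times / 7.0 + rng.uniform(0, 6))
                  + rng.normal(0, 0.3, n_pings))
        for p in range(n_pings):
            c = int(round(floor_bin + jitter[p]))
            lo = max(c - ridge_halfwidth_bins, 0)
            hi = min(c + ridge_halfwidth_bins + 1, n_bins)
            enr[p, lo:hi] = seafloor_enr_db + rng.normal(0, 1.0, hi - lo)

    if truth.get("visible", False):
        _paint_prey(enr, ping_times, prca_start, truth, range_resolution,
                    n_bins, prey_enr_db, rng)

    ranges = (np.arange(n_bins) + 0.5) * range_resolution
    return Echogram(ping_times=ping_times, ranges=ranges, enr=enr,
                    prca_id=prca_id, window=(t_lo, t_hi))


def _paint_prey(enr, ping_times, prca_start, truth, res, n_bins, level, rng):
    size_bins = max(int(round(truth.get("size_cm", 5.0) / (res * 100.0))), 1)
    reaction = truth.get("reaction", "none")
    onset_t = prca_start + truth.get("onset_rel_s", 0.0)
    r0 = truth.get("onset_range_cm", 60.0) / 100.0  # m from the sonar

    offsets = [0.0]
    if truth.get("school", False):
        offsets.append(-0.18 if r0 > 0.30 else 0.18)

    t_rel = ping_times - onset_t
    if reaction == "leave_seafloor":
        v = rng.uniform(0.08, 0.20)  # m/s toward the sonar
        dur = rng.uniform(2.5, 4.5)
        sel = (t_rel >= 0) & (t_rel <= dur)
        r = r0 - v * t_rel
    elif reaction == "escape":
        v = rng.uniform(0.10, 0.22)
        tau = rng.uniform(1.0, 1.8)  # time to minimum range
        v = min(v, 2.0 * (r0 - 0.06) / tau)  # keep min range positive
        pre = 1.0
        dur = 2.0 * tau
        sel = (t_rel >= -pre) & (t_rel <= dur)
        r = np.where(t_rel < 0, r0, r0 - v * t_rel + (v / (2 * tau)) * t_rel**2)
    else:  # stationary blob
        dur = rng.uniform(1.5, 3.0)
        sel = (t_rel >= -dur / 2) & (t_rel <= dur / 2)
        r = np.full_like(t_rel, r0)

    idx = np.flatnonzero(sel & (ping_times >= ping_times[0]))
    for off in offsets:
        for p in idx:
            rp = r[p] + off + rng.normal(0, 0.002)
            if rp <= 0.03:
                continue
            center = rp / res - 0.5
            _paint(enr, p, center, size_bins, level, n_bins, rng)
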