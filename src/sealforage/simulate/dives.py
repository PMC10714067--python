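"""Dive-profile archetypes.

Five stereotyped dive shapes, mirroring the clusters that functional
dive-shape analysis recovers for a central-place benthic forager:

1. square (U): direct descent/ascent with a flat bottom >= 30 % of the dive
2. symmetric V with vertical sinuosity throughout
3. left-skewed: sinuous descent, straight ascent (bottom late in the dive)
4. right-skewed: straight descent, sinuous ascent (bottom early)
5. W: two bottom excursions, typically shallow

Profiles are positive-down depth series that start and end at the surface
and reach the requested maximum depth exactly (the curve is rescaled after
shape construction).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["simulate_dive_profile", "profile_with_hold", "ARCHETYPES"]

ARCHETYPES = (1, 2, 3, 4, 5)

# relative wiggle amplitude and where it applies (u-range of the envelope)
_WIGGLE = {1: (0.02, (0.0, 1.0)), 2: (0.06, (0.0, 1.0)),
           3: (0.07, (0.0, None)), 4: (0.07, (None, 1.0)),
           5: (0.02, (0.0, 1.0))}


def _keypoints(archetype: int, hold: float, rng: np.random.Generator,
               min_rel: float = 0.0):
    """Normalized-time keypoints (u, relative depth) plus the bottom-hold
    interval in normalized time.

    Within-archetype variability is Gaussian keypoint jitter (clipped to
    stay geometrically valid), so each archetype forms a coherent,
    roughly Gaussian cloud in shape space.
    """

    def j(mu, sd, lo, hi):
        return float(np.clip(rng.normal(mu, sd), lo, hi))

    if archetype == 1:
        d = j(0.11, 0.015, 0.07, 0.15)
        h = max(hold, j(0.47, 0.03, 0.38, 0.57))
        a = min(d + h, 0.88)
        pts = [(0.0, 0.0), (d, 1.0), (a, 1.0), (1.0, 0.0)]
        return pts, (d, a)
    if archetype == 2:
        m = j(0.50, 0.02, 0.44, 0.56)
    elif archetype == 3:
        m = j(0.65, 0.02, 0.59, 0.71)
    elif archetype == 4:
        m = j(0.35, 0.02, 0.29, 0.41)
    elif archetype == 5:
        p1 = j(0.26, 0.015, 0.21, 0.31)
        mid = j(0.50, 0.015, 0.45, 0.55)
        p2 = j(0.72, 0.015, 0.67, 0.77)
        h = max(hold, 0.04)
        lo = max(p1 - h / 2, 0.06)
        hi = min(p1 + h / 2, mid - 0.08)
        # the mid-dive rise must stay deeper than the dive threshold so
        # a shallow W remains a single dive (min_rel encodes 5 m / depth)
        mid_level = max(j(0.42, 0.03, 0.34, 0.51), min_rel)
        pts = [(0.0, 0.0), (lo, 1.0), (hi, 1.0), (mid, mid_level),
               (p2, j(0.92, 0.015, 0.87, 0.97)), (1.0, 0.0)]
        return pts, (lo, hi)
    else:
        raise ValueError(f"unknown dive archetype: {archetype}")
    h = max(hold, 0.03)
    lo = max(m - h / 2, 0.05)
    hi = min(m + h / 2, 0.95)
    pts = [(0.0, 0.0), (lo, 1.0), (hi, 1.0), (1.0, 0.0)]
    return pts, (lo, hi)


def profile_with_hold(
    archetype: int,
    max_depth: float,
    duration: float,
    fs: float = 50.0,
    rng: np.random.Generator | None = None,
    bottom_hold_frac: float = 0.0,
    wiggle_scale: float = 1.0,
):
    """Like :func:`simulate_dive_profile` but also returns the bottom-hold
    interval in seconds, used to place capture attempts at depth."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown dive archetype: {archetype}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if max_depth <= 5.0:
        raise ValueError("max_depth must exceed the 5 m dive threshold")
    rng = rng if rng is not None else np.random.default_rng(0)

    min_rel = min(6.0 / max_depth, 0.85)
    pts, hold_u = _keypoints(archetype, bottom_hold_frac, rng, min_rel)
    uk = np.array([p[0] for p in pts])
    dk = np.array([p[1] for p in pts])
    n = max(int(round(duration * fs)), 8)
    u = np.linspace(0.0, 1.0, n)
    base = PchipInterpolator(uk, dk)(u)

    amp = _WIGGLE[archetype][0] * wiggle_scale
    # region mask: archetype 3 wiggles only on the descent, 4 on the ascent
    if archetype == 3:
        mask = (u <= hold_u[0]).astype(float)
    elif archetype == 4:
        mask = (u >= hold_u[1]).astype(float)
    else:
        mask = np.ones_like(u)
    if amp > 0:
        # fixed wiggle frequencies with Gaussian coefficients: the vertical
        # sinuosity is then a (near-)Gaussian deformation in shape space
        w = np.zeros_like(u)
        for f in (3.0, 4.5, 6.0):
            w += rng.normal(0.0, 1.0) * np.sin(2 * np.pi * f * u) \
                + rng.normal(0.0, 1.0) * np.cos(2 * np.pi * f * u)
        w *= amp / 2.45  # sum of 6 unit-variance terms -> ~unit amplitude
        # keep the bottom hold flat so scheduled events stay at depth
        damp = np.ones_like(u)
        in_hold = (u >= hold_u[0]) & (u <= hold_u[1])
        damp[in_hold] = 0.15
        # fade the wiggle out near the surface so the profile crosses the
        # 5 m dive threshold exactly once on each limb
        surface_fade = np.clip((base - 6.5 / max_depth) / 0.05, 0.0, 1.0)
        base = base + w * np.sin(np.pi * u) * mask * damp * surface_fade

    # clip at the bottom level so wiggles never exceed the maximum depth
    # (the bottom hold must sit exactly at max_depth for scheduled events)
    base = np.clip(base, 0.0, 1.0)
    profile = base / base.max() * max_depth
    profile[0] = 0.0
    profile[-1] = 0.0
    return profile, (hold_u[0] * duration, hold_u[1] * duration)


def simulate_dive_profile(
    archetype: int,
    max_depth: float,
    duration: float,
    fs: float = 50.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Depth series (m, positive down) for one dive of the given archetype.

    The profile starts and ends at the surface, reaches ``max_depth``
    exactly, and honors the archetype geometry (flat bottom, V, skewed V,
    or W with two bottom excursions).
    """
    profile, _ = profile_with_hold(archetype, max_depth, duration, fs, rng)
    return profile
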