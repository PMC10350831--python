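"""Shared fixtures: analytically constructed cell masks and trajectories.

Masks are rasterised directly from the analytic silhouette (independent of
the geometry module under test) so they can serve as oracles.
"""

from __future__ import annotations

import numpy as np
import pytest


def rasterize_spherocylinder(length, width, pixel_size, angle=0.0, pad=12):
    """Binary mask of a spherocylinder silhouette, rasterised analytically.

    The silhouette is the set of points within ``width/2`` of the axis
    segment; pixel centres are tested directly.
    """
    half_axis = (length - width) / 2.0
    r = width / 2.0
    diag = length + 2 * pad * pixel_size
    n = int(np.ceil(diag / pixel_size))
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    x = (xx - c) * pixel_size
    y = (yy - c) * pixel_size
    ca, sa = np.cos(angle), np.sin(angle)
    u = x * ca + y * sa
    v = -x * sa + y * ca
    du = np.clip(np.abs(u) - half_axis, 0.0, None)
    return du**2 + v**2 <= r**2


def rasterize_bent_rod(arc_length, width, radius, pixel_size, pad=12):
    """Mask of a rod bent along a circular arc of given centerline radius."""
    half_angle = arc_length / radius / 2.0
    r_half = width / 2.0
    extent = 2 * (radius + r_half) + 2 * pad * pixel_size
    n = int(np.ceil(extent / pixel_size))
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    x = (xx - c) * pixel_size
    y = (yy - c) * pixel_size
    rr = np.hypot(x, y)
    ang = np.arctan2(y, x)
    mask = (np.abs(rr - radius) <= r_half) & (np.abs(ang) <= half_angle)
    for s in (-1.0, 1.0):
        ex = radius * np.cos(s * half_angle)
        ey = radius * np.sin(s * half_angle)
        mask |= np.hypot(x - ex, y - ey) <= r_half
    return mask


@pytest.fixture
def spherocylinder_mask():
    return rasterize_spherocylinder


@pytest.fixture
def bent_rod_mask():
    return rasterize_bent_rod
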