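"""Morphometry of rod-shaped cells.

Converts cell contours or binary masks into the scalar shape quantities used
throughout the pipeline — length ``L``, width ``W``, surface area ``S``,
volume ``V`` and centerline curvature ``kappa`` — under a spherocylinder
shape model (a cylinder of length ``L - W`` capped by two hemispheres of
diameter ``W``).  All coordinates are in micrometres, with the origin at the
centre of the upper-left pixel of the source image.

The centerline is extracted as the ridge of the Euclidean distance transform
of the cell mask (a skeleton pruned to its longest path and extended to the
cell poles), and the width is twice the median distance-transform value along
the central 60% of that centerline.  Cells whose skeleton branches (i.e. that
are not rod-like) are rejected with :class:`BranchedSkeletonError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw, measure, morphology

__all__ = [
    "CellFrame",
    "BranchedSkeletonError",
    "spherocylinder_surface",
    "spherocylinder_volume",
    "spherocylinder_length_from_surface",
    "spherocylinder_projected_area",
    "contour_from_mask",
    "mask_from_contour",
    "measure_cell",
    "measure_mask",
    "centerline_curvature",
    "resample_polyline",
    "polyline_length",
]


class BranchedSkeletonError(ValueError):
    """Raised when a cell mask yields a branched (non-rod-like) skeleton."""


@dataclass
class CellFrame:
    """Morphometry of one cell at one time point.

    Attributes
    ----------
    time : float
        Acquisition time in minutes.
    contour : (n, 2) ndarray
        Closed polyline of the cell outline, ``(x, y)`` in micrometres.
    centerline : (m, 2) ndarray
        Open polyline along the cell axis, pole to pole, in micrometres.
    length : float
        Pole-to-pole arc length ``L`` (μm).
    width : float
        Cell diameter ``W`` (μm).
    projected_area : float
        Area enclosed by the contour (μm²).
    """

    time: float
    contour: np.ndarray
    centerline: np.ndarray
    length: float
    width: float
    projected_area: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# closed-form spherocylinder geometry
# ---------------------------------------------------------------------------

def _check_lw(length: float, width: float) -> None:
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(width <= 0):
        raise ValueError("width must be positive")
    if np.any(length < width):
        raise ValueError("spherocylinder requires L >= W (cell longer than wide)")


def spherocylinder_surface(length, width):
    """Surface area ``S = pi * W * L`` of a spherocylinder (μm²).

    The lateral cylinder ``pi*W*(L - W)`` plus two hemispherical caps
    ``pi*W**2`` sum to ``pi*W*L``; at ``L == W`` this is the sphere surface.
    """
    _check_lw(length, width)
    return np.pi * np.asarray(width, dtype=float) * np.asarray(length, dtype=float)


def spherocylinder_volume(length, width):
    """Volume ``V = pi*W**2*L/4 - pi*W**3/12`` of a spherocylinder (μm³)."""
    _check_lw(length, width)
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    return np.pi * width**2 * length / 4.0 - np.pi * width**3 / 12.0


def spherocylinder_length_from_surface(surface, width):
    """Invert ``S = pi*W*L`` for the length; rejects ``L < W``."""
    width = np.asarray(width, dtype=float)
    length = np.asarray(surface, dtype=float) / (np.pi * width)
    _check_lw(length, width)
    return length


def spherocylinder_projected_area(length, width):
    """2D projected (silhouette) area ``W*(L - W) + pi*(W/2)**2`` (μm²)."""
    _check_lw(length, width)
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    return width * (length - width) + np.pi * (width / 2.0) ** 2


# ---------------------------------------------------------------------------
# polyline helpers
# ---------------------------------------------------------------------------

def polyline_length(points: np.ndarray) -> float:
    """Arc length of an open polyline (same units as the coordinates)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample an open polyline to uniform arc-length spacing."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) polyline")
    n = max(int(round(total / spacing)) + 1, 2)
    si = np.linspace(0.0, total, n)
    return np.column_stack(
        [np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])]
    )


# ---------------------------------------------------------------------------
# mask <-> contour conversion
# ---------------------------------------------------------------------------

def contour_from_mask(mask: np.ndarray, pixel_size: float = 1.0) -> np.ndarray:
    """Extract the cell outline from a binary mask by marching squares.

    Returns the longest closed iso-contour at level 0.5 as ``(x, y)``
    micrometre coordinates (origin at the centre of pixel ``[0, 0]``).
    """
    mask = np.asarray(mask).astype(float)
    contours = measure.find_contours(mask, 0.5)
    if not contours:
        raise ValueError("mask contains no foreground object")
    rc = max(contours, key=len)  # (row, col)
    return np.column_stack([rc[:, 1], rc[:, 0]]) * pixel_size


def mask_from_contour(
    contour: np.ndarray, pixel_size: float, pad: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise a closed contour (μm coordinates) onto a pixel grid.

    Returns ``(mask, origin_um)`` where ``origin_um`` is the μm coordinate of
    pixel ``[0, 0]`` so results can be mapped back to the input frame.
    """
    contour = np.asarray(contour, dtype=float)
    lo = contour.min(axis=0) - pad * pixel_size
    px = (contour - lo) / pixel_size
    shape = tuple(int(np.ceil(v)) + pad for v in px.max(axis=0)[::-1])
    rr, cc = draw.polygon(px[:, 1], px[:, 0], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask, lo


# ---------------------------------------------------------------------------
# centerline extraction
# ---------------------------------------------------------------------------

def _skeleton_longest_path(skel: np.ndarray) -> list[tuple[int, int]]:
    """Order skeleton pixels into the longest endpoint-to-endpoint path.

    Raises :class:`BranchedSkeletonError` if pixels stray from that path by
    more than a small spur tolerance (the cell is then not rod-like).
    """
    pts = list(zip(*np.nonzero(skel)))
    if not pts:
        raise ValueError("empty skeleton")
    pset = set(pts)

    def neighbors(p):
        r, c = p
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in pset:
                    out.append(q)
        return out

    def bfs(start):
        dist = {start: 0.0}
        prev = {}
        queue = [start]
        far, far_d = start, 0.0
        while queue:
            nxt = []
            for p in queue:
                for q in neighbors(p):
                    if q not in dist:
                        dist[q] = dist[p] + float(np.hypot(q[0] - p[0], q[1] - p[1]))
                        prev[q] = p
                        nxt.append(q)
                        if dist[q] > far_d:
                            far, far_d = q, dist[q]
            queue = nxt
        return far, prev, dist

    a, _, _ = bfs(pts[0])
    b, prev, dist = bfs(a)
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    path.reverse()

    # branch check: every skeleton pixel must sit near the longest path
    on_path = set(path)
    spur_tol = 3  # px; marching artefacts at the caps are shorter than this
    for p in pts:
        if p in on_path:
            continue
        d = min(max(abs(p[0] - q[0]), abs(p[1] - q[1])) for q in on_path)
        if d > spur_tol:
            raise BranchedSkeletonError(
                "skeleton has side branches; cell is not rod-like"
            )
    return path


def _ray_to_polyline(origin: np.ndarray, direction: np.ndarray, poly: np.ndarray) -> float:
    """Distance from ``origin`` along ``direction`` to the nearest crossing of
    a closed polyline; NaN if the ray never crosses."""
    p, d = origin, direction
    a = poly
    b = np.roll(poly, -1, axis=0)
    e = b - a
    denom = d[0] * (-e[:, 1]) - d[1] * (-e[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        rhs = a - p
        t = (rhs[:, 0] * (-e[:, 1]) - rhs[:, 1] * (-e[:, 0])) / denom
        u = (d[0] * rhs[:, 1] - d[1] * rhs[:, 0]) / denom
    ok = np.isfinite(t) & np.isfinite(u) & (t > 0) & (u >= 0) & (u <= 1)
    return float(t[ok].min()) if ok.any() else float("nan")


def measure_mask(
    mask: np.ndarray, pixel_size: float, time: float = 0.0
) -> CellFrame:
    """Measure centerline, length and width of a single-cell binary mask.

    The centerline is the ridge of the distance transform (the skeleton of
    the mask pruned to its longest path and smoothed); each end is extended
    along the local tangent to the subpixel 0.5-level contour so the
    polyline reaches the cell poles.  Width is twice the median distance
    from the central 60% of the centerline to that contour.  For nearly
    round cells (no usable axial ridge) the sphere limit ``L = W`` is
    returned from the centroid-to-contour distance.
    """
    from scipy.spatial import cKDTree

    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    edt = ndimage.distance_transform_edt(mask) * pixel_size
    contour = contour_from_mask(mask, pixel_size)
    tree = cKDTree(contour)
    area = float(mask.sum()) * pixel_size**2

    rmax = float(edt.max())
    skel = morphology.skeletonize(mask)
    try:
        path = _skeleton_longest_path(skel)
    except BranchedSkeletonError:
        raise
    except ValueError:
        path = []

    skel_pts = np.array([(c * pixel_size, r * pixel_size) for r, c in path])
    if len(skel_pts) < 2 or polyline_length(skel_pts) < rmax:
        # sphere limit: no usable axial ridge
        com = ndimage.center_of_mass(mask)
        center = np.array([com[1], com[0]]) * pixel_size
        centerline = np.vstack([center, center + [1e-6, 0.0]])
        width = 2.0 * float(np.median(tree.query(center[None, :])[0]))
        return CellFrame(time, contour, centerline, width, width, area)

    # light smoothing of the pixel staircase before tangent estimation
    line = resample_polyline(skel_pts, pixel_size)
    if len(line) >= 7:
        from scipy.signal import savgol_filter

        win = min(len(line) - (1 - len(line) % 2), 11)
        if win >= 5:
            line = np.column_stack(
                [savgol_filter(line[:, i], win, 2) for i in (0, 1)]
            )

    # extend both ends to the poles: ray-cast along the end tangent to the
    # subpixel contour
    k = min(5, len(line) - 1)
    ends = []
    for idx, sgn in ((0, -1), (len(line) - 1, +1)):
        tangent = line[idx] - line[idx - sgn * k]
        tangent = tangent / np.linalg.norm(tangent)
        reach = _ray_to_polyline(line[idx], tangent, contour)
        if not np.isfinite(reach):
            reach = float(tree.query(line[idx][None, :])[0][0])
        ends.append(line[idx] + tangent * reach)
    centerline = np.vstack([ends[0], line, ends[1]])

    length = polyline_length(centerline)

    # width along the central 60% of the (unextended) ridge, measured as the
    # full chord normal to the local tangent (robust to the ridge sitting a
    # fraction of a pixel off-centre)
    s = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(line, axis=0), axis=1))]
    )
    keep_idx = np.nonzero((s >= 0.2 * s[-1]) & (s <= 0.8 * s[-1]))[0]
    chords = []
    for i in keep_idx:
        j0, j1 = max(i - 2, 0), min(i + 2, len(line) - 1)
        tangent = line[j1] - line[j0]
        tangent = tangent / np.linalg.norm(tangent)
        normal = np.array([-tangent[1], tangent[0]])
        d_plus = _ray_to_polyline(line[i], normal, contour)
        d_minus = _ray_to_polyline(line[i], -normal, contour)
        if np.isfinite(d_plus) and np.isfinite(d_minus):
            chords.append(d_plus + d_minus)
    if chords:
        width = float(np.median(chords))
    else:
        width = 2.0 * float(np.median(tree.query(line[keep_idx])[0]))
    width = min(width, length)
    return CellFrame(time, contour, centerline, length, width, area)


def measure_cell(
    contour: np.ndarray, pixel_size: float = 0.05, time: float = 0.0
) -> CellFrame:
    """Measure a cell given its closed outline in micrometre coordinates.

    The contour is rasterised at ``pixel_size`` and measured with
    :func:`measure_mask`; the returned centerline is mapped back to the
    contour's coordinate frame.
    """
    contour = np.asarray(contour, dtype=float)
    if len(contour) < 20:
        raise ValueError("contour must have at least 20 vertices")
    mask, origin = mask_from_contour(contour, pixel_size)
    frame = measure_mask(mask, pixel_size, time=time)
    frame.centerline = frame.centerline + origin
    frame.contour = contour
    return frame


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def centerline_curvature(
    centerline: np.ndarray,
    spacing: float = 0.1,
    smooth_sigma: float = 2.0,
) -> float:
    """Mean unsigned curvature ``kappa = <|d theta / d s|>`` of a centerline (μm⁻¹).

    The polyline is resampled to uniform arc-length ``spacing`` (μm), the
    tangent angle is unwrapped and smoothed with a Gaussian of ``smooth_sigma``
    samples, and the mean absolute angular derivative is returned.  A straight
    line gives 0; a circular arc of radius ``R`` gives ``1/R``.
    """
    centerline = np.asarray(centerline, dtype=float)
    if len(centerline) < 5:
        raise ValueError("centerline needs at least 5 points")
    if polyline_length(centerline) < 1.0:
        raise ValueError("centerline arc length below 1 um")
    line = resample_polyline(centerline, spacing)
    d = np.diff(line, axis=0)
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    ds = polyline_length(line) / (len(line) - 1)
    dtheta = np.diff(theta)
    # smooth the angular increments: a circular arc has constant dtheta, so
    # symmetric filtering is bias-free in both the arc and straight limits
    if smooth_sigma > 0 and len(dtheta) > 4:
        dtheta = ndimage.gaussian_filter1d(dtheta, smooth_sigma, mode="nearest")
    return float(np.mean(np.abs(dtheta)) / ds)
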