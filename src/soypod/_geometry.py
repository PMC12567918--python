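"""Shared low-level geometry on binary masks.

Masks are 2D boolean numpy arrays indexed ``[row, col]``; points are
``(x, y)`` = ``(col, row)`` with the origin at the top-left pixel centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure


@dataclass(frozen=True)
class RotatedRect:
    """Minimum-area rotated rectangle of a pixel set.

    ``angle_deg`` is the direction of the *long* side in (-90, 90],
    measured in image coordinates (x right, y down).
    """

    center: tuple[float, float]
    length: float
    width: float
    angle_deg: float

    @property
    def long_axis(self) -> tuple[float, float]:
        t = np.deg2rad(self.angle_deg)
        return (float(np.cos(t)), float(np.sin(t)))


#: orientations whose bounding-rectangle area is within this relative
#: margin of the true minimum are treated as ties (see min_area_rect_points)
_AREA_TIE_FRAC = 0.05


def min_area_rect_points(points: np.ndarray) -> RotatedRect:
    """Minimum-area rotated rectangle of an (n, 2) array of (x, y) points.

    Rotating calipers over the convex hull. For near-circular shapes the
    minimizing orientation is ill-conditioned (many orientations are
    within discretization noise of the minimum area), which makes the
    reported long side unstable under re-rasterization; among orientations
    within 5% of the minimal area, the one whose long axis is closest to
    the principal (second-moment) axis of the points is reported. That
    choice is stable under rotation and coincides with the unique minimum
    for elongated shapes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        d = np.ptp(pts, axis=0)
        ang = float(np.rad2deg(np.arctan2(d[1], d[0]))) if np.hypot(*d) > 0 else 0.0
        if ang <= -90.0:
            ang += 180.0
        elif ang > 90.0:
            ang -= 180.0
        c = pts.mean(axis=0)
        return RotatedRect((float(c[0]), float(c[1])), max(float(np.hypot(*d)), 1.0), 1.0, ang)
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:  # collinear points
        d = np.ptp(pts, axis=0)
        ang = float(np.rad2deg(np.arctan2(d[1], d[0])))
        if ang <= -90.0:
            ang += 180.0
        elif ang > 90.0:
            ang -= 180.0
        c = pts.mean(axis=0)
        return RotatedRect((float(c[0]), float(c[1])), float(np.hypot(*d)), 1.0, ang)

    # principal axis of the point cloud, from second central moments
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred
    pca_angle = 0.5 * np.arctan2(2.0 * cov[0, 1], cov[0, 0] - cov[1, 1])

    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    # hull-edge orientations (caliper candidates) plus the PCA axis: a
    # coarse hull may lack an edge along the true symmetry axis
    angles = np.unique(
        np.concatenate(
            [
                np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi / 2),
                [np.mod(pca_angle, np.pi / 2)],
            ]
        )
    )
    cos, sin = np.cos(angles), np.sin(angles)
    # project hull points onto each candidate frame
    u = hull @ np.vstack([cos, sin])    # (n_pts, n_angles)
    v = hull @ np.vstack([-sin, cos])
    du = u.max(axis=0) - u.min(axis=0)
    dv = v.max(axis=0) - v.min(axis=0)
    areas = du * dv
    best = float(areas.min())
    tied = np.flatnonzero(areas <= best * (1.0 + _AREA_TIE_FRAC))
    long_angles = np.where(du[tied] >= dv[tied], angles[tied], angles[tied] + np.pi / 2)
    mis = np.abs(np.remainder(long_angles - pca_angle + np.pi / 2, np.pi) - np.pi / 2)
    k = tied[int(np.argmin(mis))]
    long_len, short_len = float(max(du[k], dv[k])), float(min(du[k], dv[k]))
    ang = float(np.rad2deg(angles[k] if du[k] >= dv[k] else angles[k] + np.pi / 2))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    cu = (u[:, k].max() + u[:, k].min()) / 2.0
    cv = (v[:, k].max() + v[:, k].min()) / 2.0
    cx = cu * cos[k] - cv * sin[k]
    cy = cu * sin[k] + cv * cos[k]
    return RotatedRect((float(cx), float(cy)), long_len, short_len, ang)


def mask_contour_points(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel 0.5-level contour points of a binary mask, as (x, y)."""
    contours = measure.find_contours(np.pad(mask, 1).astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask has no contour")
    # each loop closes on its first point; drop the duplicate so point
    # statistics (e.g. the PCA axis) are unbiased
    pts_rc = np.vstack([c[:-1] if len(c) > 1 else c for c in contours]) - 1.0
    return pts_rc[:, ::-1]


def min_area_rect(mask: np.ndarray) -> RotatedRect:
    """Minimum-area rotated rectangle around the foreground of ``mask``.

    The rectangle is fitted to the sub-pixel 0.5-level contour of the
    mask, so an axis-aligned w x h block reports sides (w, h) exactly and
    warped (interpolated) masks measure consistently with crisp ones.
    """
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask has no bounding rectangle")
    if xs.size == 1:
        return RotatedRect((float(xs[0]), float(ys[0])), 1.0, 1.0, 0.0)
    return min_area_rect_points(mask_contour_points(mask))


@dataclass(frozen=True)
class MaskTransform:
    """Affine point map associated with a mask rotation (x, y convention)."""

    matrix: np.ndarray  # 2x2, maps source direction to destination direction
    offset: np.ndarray  # length-2

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.offset


def rotate_mask(mask: np.ndarray, angle_deg: float) -> tuple[np.ndarray, MaskTransform]:
    """Rotate a binary mask by ``angle_deg`` (counter-clockwise in the x-right,
    y-down frame), expanding the canvas so nothing is clipped.

    Returns the rotated mask and the exact point transform, so geometry
    attached to the source mask (seed centres, tip vertices) can be carried
    along without re-detection.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    t = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
    rc = (corners - center) @ rot.T + center
    lo = np.floor(rc.min(axis=0))
    hi = np.ceil(rc.max(axis=0))
    out_w = int(hi[0] - lo[0]) + 1
    out_h = int(hi[1] - lo[1]) + 1
    offset = center - lo
    # output[y', x'] = input at p = R^-1 @ (p' - offset - 0) ... inverse map
    inv = rot.T
    # ndimage.affine_transform works in (row, col); build the (y, x) inverse
    m_yx = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    # source (y,x) = m_yx @ (out (y,x) - offset_yx) + center_yx
    offset_yx = np.array([offset[1], offset[0]])
    center_yx = np.array([center[1], center[0]])
    shift = center_yx - m_yx @ offset_yx
    # bilinear warp + 0.5 threshold keeps the boundary sub-pixel accurate;
    # nearest-neighbour warping roughens it enough to bias inscribed-circle
    # widths by 1-2 px
    rotated = (
        ndimage.affine_transform(
            mask.astype(np.float32),
            m_yx,
            offset=shift,
            output_shape=(out_h, out_w),
            order=1,
            mode="constant",
            cval=0.0,
        )
        > 0.5
    )
    # forward map: p' = rot @ (p - center) + center - lo = rot @ p + (offset - rot @ center)
    tform = MaskTransform(matrix=rot, offset=offset - rot @ center)
    return rotated, tform


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest 8-connected foreground component."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("empty mask")
    if n == 1:
        return labels == 1
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels adjacent to background (1-px boundary)."""
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    return mask & ~eroded


def disk_overlap_area(distance: float, radius: float) -> float:
    """Area of intersection of two equal disks with centres ``distance`` apart."""
    d, r = float(distance), float(radius)
    if d >= 2.0 * r:
        return 0.0
    if d <= 0.0:
        return float(np.pi * r * r)
    x = d / (2.0 * r)
    return float(2.0 * r * r * np.arccos(x) - 0.5 * d * np.sqrt(4.0 * r * r - d * d))
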