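"""On-branch pod placement: growth points, tip vertices, and mounting.

Pods on a real soybean branch cluster near stem nodes and hang downward.
The simulator emulates this by partitioning the branch silhouette's
vertical extent into 7 bands, jittering the band lines, sampling candidate
growth points where the lines cross the branch foreground, and mounting
each pod by its tip vertex — the boundary point at the pod's narrow
terminal end — with a downward-pointing orientation. Occlusion-ratio
control is identical to the excised-pod simulator: the branch itself is
rendered below all pods and never occludes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._geometry import MaskTransform, RotatedRect, boundary_pixels, min_area_rect, rotate_mask
from .compositing import ATTEMPT_BUDGET, SceneAnnotation, try_place

__all__ = [
    "GrowthPointSet",
    "TipVertex",
    "growth_points",
    "tip_vertex",
    "mount_pod",
    "synthesize_branch_scene",
    "N_BANDS",
]

logger = logging.getLogger(__name__)

#: number of even growth bands over the branch's vertical extent
N_BANDS = 7
#: half-angle (degrees) of the downward orientation cone for mounted pods
DOWNWARD_CONE_DEG = 60.0


@dataclass
class GrowthPointSet:
    branch_mask: np.ndarray
    h_min: int
    h_max: int
    band_lines: list[float]
    points: list[tuple[int, int]]


@dataclass
class TipVertex:
    point: tuple[float, float]
    tip_side: str  # "A" (smaller x after normalization) or "B"
    rect: RotatedRect


def growth_points(
    branch_mask: np.ndarray,
    jitter_frac: float = 0.15,
    per_band: int = 3,
    rng: np.random.Generator | None = None,
) -> GrowthPointSet:
    """Jittered band lines over the branch extent and on-branch candidates.

    Band ordinates are ``y_i = h_min + i*(h_max-h_min)/7`` for i=1..7 plus
    a uniform jitter of +/- ``jitter_frac`` band heights; on each line up
    to ``per_band`` x-positions are sampled from columns where the line
    crosses branch foreground.
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = np.flatnonzero(branch_mask.any(axis=1))
    if rows.size == 0:
        raise ValueError("branch mask is empty")
    h_min, h_max = int(rows[0]), int(rows[-1])
    band_h = (h_max - h_min) / N_BANDS
    lines: list[float] = []
    points: list[tuple[int, int]] = []
    for i in range(1, N_BANDS + 1):
        y = h_min + i * band_h + float(rng.uniform(-jitter_frac, jitter_frac)) * band_h
        y = float(np.clip(y, h_min, h_max))
        lines.append(y)
        row = int(round(y))
        cols = np.flatnonzero(branch_mask[row])
        if cols.size == 0:
            logger.info("band line y=%.1f crosses no branch foreground", y)
            continue
        k = min(per_band, cols.size)
        chosen = rng.choice(cols, size=k, replace=False)
        points.extend((int(c), row) for c in sorted(chosen))
    return GrowthPointSet(branch_mask, h_min, h_max, lines, points)


def tip_vertex(pod_mask: np.ndarray) -> TipVertex:
    """Locate the pod's tip: the narrow terminal end of its long axis.

    The minimum-area rotated rectangle is split into four equal strips
    along the long axis; the terminal strip with the smaller mask overlap
    is the tip side. The tip vertex is the centroid of mask boundary
    points within 1 px of that strip's outer short edge. Terminal-overlap
    ties resolve to end A (smaller x after axis normalization).
    """
    rect = min_area_rect(pod_mask)
    if rect.width <= 2.0:
        raise ValueError("degenerate (line-like) mask has no tip")
    ux, uy = rect.long_axis  # normalized: ux >= 0
    cx, cy = rect.center
    ys, xs = np.nonzero(pod_mask)
    s = (xs - cx) * ux + (ys - cy) * uy  # projection onto the long axis
    half = rect.length / 2.0
    quarter = rect.length / 4.0
    area_a = int(np.count_nonzero(s <= -half + quarter))
    area_b = int(np.count_nonzero(s >= half - quarter))
    tip_side = "A" if area_a <= area_b else "B"

    bys, bxs = np.nonzero(boundary_pixels(pod_mask))
    bs = (bxs - cx) * ux + (bys - cy) * uy
    if tip_side == "A":
        edge = bs.min()
        sel = bs <= edge + 1.0
    else:
        edge = bs.max()
        sel = bs >= edge - 1.0
    point = (float(bxs[sel].mean()), float(bys[sel].mean()))
    return TipVertex(point=point, tip_side=tip_side, rect=rect)


def _oriented_pod(
    pod_mask: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotate a cutout so its tip-to-centroid axis points downward.

    Returns the rotated cutout, the tip coordinates in the rotated frame,
    and the applied rotation angle. The tip-to-centroid direction lands
    uniformly within +/- DOWNWARD_CONE_DEG of straight down.
    """
    tip = tip_vertex(pod_mask)
    ys, xs = np.nonzero(pod_mask)
    centroid = np.array([xs.mean(), ys.mean()])
    tp = np.array(tip.point)
    current = np.rad2deg(np.arctan2(*(centroid - tp)[::-1]))
    target = 90.0 + float(rng.uniform(-DOWNWARD_CONE_DEG, DOWNWARD_CONE_DEG))
    angle = target - current
    rotated, tform = rotate_mask(pod_mask, angle)
    tip_rot = tform.apply(tp)[0]
    return rotated, tip_rot, angle


def mount_pod(
    scene: SceneAnnotation,
    pod_cutout: np.ndarray,
    growth_point: tuple[int, int],
    rng: np.random.Generator,
    source_index: int | None = None,
) -> bool:
    """Attach a pod by its tip to a growth point; accept under alpha control.

    The pod is rotated so its tip-to-centroid axis points within the
    downward cone, translated so the tip vertex coincides with the growth
    point, and then submitted to the same occlusion-ratio acceptance as
    the excised-pod simulator.
    """
    gx, gy = growth_point
    H, W = scene.canvas_size
    if not (0 <= gx < W and 0 <= gy < H):
        raise ValueError("growth point outside canvas")
    rotated, tip_rot, angle = _oriented_pod(pod_cutout, rng)
    dx = int(round(gx - tip_rot[0]))
    dy = int(round(gy - tip_rot[1]))
    h, w = rotated.shape
    if dx < 0 or dy < 0 or dx + w > W or dy + h > H:
        return False
    full = np.zeros(scene.canvas_size, dtype=bool)
    full[dy : dy + h, dx : dx + w] = rotated
    ok = try_place(
        scene,
        pod_cutout,
        rng,
        full_mask=full,
        rotation_deg=angle,
        translation=(dx, dy),
        source_index=source_index,
    )
    if ok:
        scene.instances[-1].tip_vertex = (float(gx), float(gy))
    return ok


def synthesize_branch_scene(
    branch_library: list[np.ndarray],
    pod_library: list[np.ndarray],
    alpha: float,
    canvas: tuple[int, int],
    rng_seed: int,
    jitter_frac: float = 0.15,
    per_band: int = 3,
    attempt_budget: int = ATTEMPT_BUDGET,
) -> SceneAnnotation:
    """Compose one on-branch scene.

    A branch silhouette is centred on the canvas (z-order 0, not a counted
    instance and never an occluder), growth points are derived, and pods
    are mounted at growth points consumed without replacement until points
    are exhausted. All pod-vs-pod invariants of the excised-pod simulator
    hold unchanged.
    """
    if not branch_library or not pod_library:
        raise ValueError("branch and pod libraries must be nonempty")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    H, W = canvas

    branch = np.asarray(branch_library[int(rng.integers(0, len(branch_library)))], dtype=bool)
    bh, bw = branch.shape
    if bh > H or bw > W:
        raise ValueError("branch silhouette larger than canvas")
    branch_full = np.zeros((H, W), dtype=bool)
    oy, ox = (H - bh) // 2, (W - bw) // 2
    branch_full[oy : oy + bh, ox : ox + bw] = branch

    gset = growth_points(branch_full, jitter_frac=jitter_frac, per_band=per_band, rng=rng)
    scene = SceneAnnotation(
        canvas_size=(H, W),
        alpha=alpha,
        rng_seed=rng_seed,
        branch_mask=branch_full,
        growth_points=list(gset.points),
    )
    order = rng.permutation(len(gset.points))
    for pi in order:
        point = gset.points[pi]
        idx = int(rng.integers(0, len(pod_library)))
        cutout = np.asarray(pod_library[idx], dtype=bool)
        for _ in range(attempt_budget):
            if mount_pod(scene, cutout, point, rng, source_index=idx):
                break
        else:
            logger.info("growth point %s: pod skipped (budget exhausted)", point)
    if not scene.instances:
        raise ValueError("no pod could be mounted on the branch")
    return scene
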