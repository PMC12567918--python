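"""Excised-pod overlap simulation with explicit occlusion-ratio control.

Pod cutouts are placed on a black canvas with a random in-plane rotation
and translation. A placement is accepted only if no pod's occlusion ratio
— the fraction of its complete (amodal) mask hidden by pods placed on top
of it — exceeds the user threshold ``alpha``. Every accepted scene carries
exact dual masks: the amodal mask of each pod and its visible mask under
the z-order, which tile the composite foreground.

Occlusion semantics are z-ordered: only pods placed later (on top) occlude
a pod. This keeps visible masks pairwise disjoint and their union equal to
the union of the amodal masks, matching physical compositing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._geometry import rotate_mask

__all__ = [
    "PodInstance",
    "SceneAnnotation",
    "occluded_region",
    "occlusion_ratio",
    "try_place",
    "synthesize_scene",
    "ATTEMPT_BUDGET",
]

logger = logging.getLogger(__name__)

#: resampling budget per pod before it is skipped
ATTEMPT_BUDGET = 100


@dataclass
class PodInstance:
    """One composited pod: amodal + visible mask and placement parameters."""

    instance_id: int
    full_mask: np.ndarray
    visible_mask: np.ndarray
    z_index: int
    rotation_deg: float = 0.0
    translation: tuple[int, int] = (0, 0)
    occlusion_ratio: float = 0.0
    tip_vertex: tuple[float, float] | None = None
    source_index: int | None = None


@dataclass
class SceneAnnotation:
    """A synthetic scene: canvas, ordered pod instances, occlusion threshold."""

    canvas_size: tuple[int, int]  # (H, W)
    instances: list[PodInstance] = field(default_factory=list)
    alpha: float = 1.0
    rng_seed: int | None = None
    branch_mask: np.ndarray | None = None
    growth_points: list[tuple[int, int]] | None = None

    def validate(self) -> None:
        union_vis = np.zeros(self.canvas_size, dtype=bool)
        union_full = np.zeros(self.canvas_size, dtype=bool)
        for inst in self.instances:
            if inst.full_mask.shape != self.canvas_size:
                raise ValueError(f"instance {inst.instance_id}: mask/canvas size mismatch")
            if np.any(inst.visible_mask & ~inst.full_mask):
                raise ValueError(f"instance {inst.instance_id}: visible not within amodal mask")
            if inst.occlusion_ratio > self.alpha + 1e-9:
                raise ValueError(
                    f"instance {inst.instance_id}: occlusion ratio "
                    f"{inst.occlusion_ratio:.3f} exceeds alpha={self.alpha}"
                )
            if np.any(union_vis & inst.visible_mask):
                raise ValueError(f"instance {inst.instance_id}: visible masks overlap")
            union_vis |= inst.visible_mask
            union_full |= inst.full_mask
        if not np.array_equal(union_vis, union_full):
            raise ValueError("union of visible masks differs from union of amodal masks")


def occluded_region(instance: PodInstance, others: list[PodInstance]) -> np.ndarray:
    """Pixels of ``instance`` hidden by pods with a larger z-index."""
    occ = np.zeros_like(instance.full_mask)
    for other in others:
        if other is instance:
            continue
        if other.full_mask.shape != instance.full_mask.shape:
            raise ValueError("mismatched canvas sizes")
        if other.z_index > instance.z_index:
            occ |= other.full_mask
    return occ & instance.full_mask


def occlusion_ratio(instance: PodInstance, others: list[PodInstance]) -> float:
    """Occluded area of the instance divided by its amodal-mask area."""
    full_area = int(instance.full_mask.sum())
    if full_area == 0:
        raise ValueError("empty amodal mask")
    return float(occluded_region(instance, others).sum()) / full_area


def _refresh_visibility(instances: list[PodInstance]) -> None:
    """Recompute every visible mask and occlusion ratio under the z-order."""
    order = sorted(instances, key=lambda p: p.z_index)
    above = np.zeros_like(order[0].full_mask) if order else None
    for inst in reversed(order):
        inst.visible_mask = inst.full_mask & ~above
        full_area = int(inst.full_mask.sum())
        inst.occlusion_ratio = 1.0 - float(inst.visible_mask.sum()) / full_area
        above = above | inst.full_mask


def _random_placement(
    cutout: np.ndarray, canvas: tuple[int, int], rng: np.random.Generator
) -> tuple[np.ndarray, float, tuple[int, int]] | None:
    """Rotate uniformly and translate uniformly over in-canvas positions."""
    angle = float(rng.uniform(0.0, 360.0))
    rotated, _ = rotate_mask(cutout, angle)
    ys, xs = np.nonzero(rotated)
    if ys.size == 0:
        return None
    rotated = rotated[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    h, w = rotated.shape
    H, W = canvas
    if h > H or w > W:
        return None
    dy = int(rng.integers(0, H - h + 1))
    dx = int(rng.integers(0, W - w + 1))
    full = np.zeros(canvas, dtype=bool)
    full[dy : dy + h, dx : dx + w] = rotated
    return full, angle, (dx, dy)


def try_place(
    scene: SceneAnnotation,
    pod_cutout: np.ndarray,
    rng: np.random.Generator,
    full_mask: np.ndarray | None = None,
    rotation_deg: float = 0.0,
    translation: tuple[int, int] = (0, 0),
    source_index: int | None = None,
) -> bool:
    """Attempt one placement; accept only if all occlusion ratios stay <= alpha.

    By default the cutout is given a uniform random rotation and an in-canvas
    uniform random translation; callers (e.g. the on-branch simulator) can
    pass a pre-transformed ``full_mask`` instead. On accept the scene is
    updated in place (all visible masks refreshed) and True is returned; on
    reject the scene is left unchanged.
    """
    if full_mask is None:
        placed = _random_placement(pod_cutout, scene.canvas_size, rng)
        if placed is None:
            return False
        full_mask, rotation_deg, translation = placed
    new_area = int(full_mask.sum())
    if new_area == 0:
        return False
    # the new pod goes on top: it occludes others, and is itself unoccluded
    for inst in scene.instances:
        full_area = int(inst.full_mask.sum())
        still_visible = int((inst.visible_mask & ~full_mask).sum())
        if 1.0 - still_visible / full_area > scene.alpha + 1e-12:
            return False
    z = max((p.z_index for p in scene.instances), default=-1) + 1
    inst = PodInstance(
        instance_id=len(scene.instances),
        full_mask=full_mask,
        visible_mask=full_mask.copy(),
        z_index=z,
        rotation_deg=rotation_deg,
        translation=translation,
        source_index=source_index,
    )
    scene.instances.append(inst)
    _refresh_visibility(scene.instances)
    return True


def synthesize_scene(
    library: list[np.ndarray],
    alpha: float,
    target_pods: int,
    canvas: tuple[int, int],
    rng_seed: int,
    attempt_budget: int = ATTEMPT_BUDGET,
) -> SceneAnnotation:
    """Compose one scene by repeated sample -> rotate -> try_place.

    Each pod slot draws a cutout from the library and retries placement up
    to ``attempt_budget`` times before being skipped. Raises if no pod can
    be placed at all.
    """
    if not library:
        raise ValueError("pod library is empty")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    scene = SceneAnnotation(canvas_size=tuple(canvas), alpha=alpha, rng_seed=rng_seed)
    for slot in range(target_pods):
        idx = int(rng.integers(0, len(library)))
        cutout = np.asarray(library[idx], dtype=bool)
        for _ in range(attempt_budget):
            if try_place(scene, cutout, rng, source_index=idx):
                break
        else:
            logger.info("scene seed=%s: pod slot %d skipped (budget exhausted)", rng_seed, slot)
    if not scene.instances:
        raise ValueError("no pod could be placed on the canvas")
    return scene
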