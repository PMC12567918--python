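"""Procedural soybean-pod and branch fixtures with known ground truth.

Real pod phenotyping pipelines start from libraries of excised-pod cutouts
and branch silhouettes. This module generates morphologically equivalent
binary shapes — elongated pods built from overlapping seed lobes with a
pinched waist between seeds, and roughly vertical branch silhouettes — so
that every downstream stage (compositing, counting, trait extraction) can
be exercised against exact, constructed ground truth.

Conventions: 0-based pixel coordinates, ``x`` = column, ``y`` = row,
origin top-left. Masks are rendered on a canvas padded by twice the lobe
radius on all sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SyntheticPodSpec",
    "SyntheticPodTruth",
    "generate_pod",
    "generate_branch",
    "pod_library",
    "save_pod_library",
]


@dataclass(frozen=True)
class SyntheticPodSpec:
    """Parameters of one procedurally generated pod.

    num_seeds
        Number of seed lobes (1-4 typical).
    seed_radius
        Nominal lobe radius in pixels (along-chain semi-axis).
    radius_jitter
        Half-width of the uniform per-lobe radius perturbation, pixels.
    center_spacing
        Distance between adjacent lobe centres along the chain, pixels.
        Must be < 2 * seed_radius so adjacent lobes overlap.
    curvature
        Total bend of the lobe-centre chain in radians (0 = straight;
        the chain is a circular arc subtending this angle).
    rng_seed
        Seed for the per-pod random stream; identical spec + seed gives a
        bit-identical mask.
    """

    num_seeds: int
    seed_radius: float
    center_spacing: float
    radius_jitter: float = 0.0
    curvature: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.num_seeds < 1:
            raise ValueError("num_seeds must be >= 1")
        if self.seed_radius <= 0:
            raise ValueError("seed_radius must be > 0")
        if self.center_spacing <= 0:
            raise ValueError("center_spacing must be > 0")
        if self.num_seeds > 1 and self.center_spacing >= 2.0 * self.seed_radius:
            raise ValueError(
                "disconnected pod: center_spacing must be < 2*seed_radius "
                "so adjacent lobes overlap"
            )
        if self.radius_jitter < 0:
            raise ValueError("radius_jitter must be >= 0")


@dataclass
class SyntheticPodTruth:
    """A generated pod mask together with its constructed ground truth."""

    mask: np.ndarray
    seed_centers: list[tuple[float, float]]
    true_length: float
    true_width: float
    spec: SyntheticPodSpec = field(repr=False, default=None)

    @property
    def num_seeds(self) -> int:
        return len(self.seed_centers)


# lobes are ellipses slightly flattened across the chain; the minor/major
# ratio is sampled per lobe in this band to avoid perfectly circular art
_AXIS_RATIO_RANGE = (0.85, 1.0)
# a junction between lobes is pinched to at most this fraction of the
# narrower neighbouring lobe's width, guaranteeing a valley in the width
# profile between every pair of seeds
_PINCH_FACTOR = 0.85


def _chain_geometry(spec: SyntheticPodSpec) -> tuple[np.ndarray, np.ndarray]:
    """Lobe centres and tangent angles along a circular-arc chain.

    Returns centres (n, 2) in a local frame centred on the chain midpoint,
    and tangent angles (radians) at each centre.
    """
    n = spec.num_seeds
    if n == 1:
        return np.zeros((1, 2)), np.zeros(1)
    total = (n - 1) * spec.center_spacing
    s = np.linspace(-total / 2.0, total / 2.0, n)  # arc-length positions
    if abs(spec.curvature) < 1e-9:
        centers = np.column_stack([s, np.zeros(n)])
        tangents = np.zeros(n)
        return centers, tangents
    radius = total / spec.curvature
    phi = s / radius  # angle along the arc, centred on 0
    xs = radius * np.sin(phi)
    ys = radius * (1.0 - np.cos(phi))
    tangents = phi
    return np.column_stack([xs, ys]), tangents


def generate_pod(spec: SyntheticPodSpec) -> SyntheticPodTruth:
    """Render one pod mask as a union of overlapping elliptical seed lobes.

    The constructed truth is exact: seed centres are the lobe centres,
    ``true_length`` is the chain extent plus the two terminal semi-axes
    (for a straight chain: ``(n-1)*spacing + r_first + r_last``), and
    ``true_width`` is twice the largest lobe minor semi-axis, i.e. the
    maximal-inscribed-circle diameter of the constructed shape.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.num_seeds

    radii = spec.seed_radius + rng.uniform(-spec.radius_jitter, spec.radius_jitter, size=n)
    radii = np.maximum(radii, 1.0)
    ratios = rng.uniform(*_AXIS_RATIO_RANGE, size=n)
    minor = radii * ratios  # across-chain semi-axes

    centers, tangents = _chain_geometry(spec)

    # canvas padded by 2*radius beyond the lobe extents
    pad = 2.0 * spec.seed_radius
    ext = np.max(radii)
    lo = centers.min(axis=0) - ext - pad
    hi = centers.max(axis=0) + ext + pad
    origin = np.floor(lo)
    w = int(np.ceil(hi[0] - origin[0])) + 1
    h = int(np.ceil(hi[1] - origin[1])) + 1
    centers_px = centers - origin  # lobe centres in canvas coordinates

    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for i in range(n):
        cx, cy = centers_px[i]
        ct, st = np.cos(tangents[i]), np.sin(tangents[i])
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask |= (u / radii[i]) ** 2 + (v / minor[i]) ** 2 <= 1.0

    # pinch each junction so the waist is at most _PINCH_FACTOR of the
    # narrower neighbouring lobe
    for i in range(n - 1):
        mid = 0.5 * (centers_px[i] + centers_px[i + 1])
        tang = 0.5 * (tangents[i] + tangents[i + 1])
        ct, st = np.cos(tang), np.sin(tang)
        u = (xx - mid[0]) * ct + (yy - mid[1]) * st
        v = -(xx - mid[0]) * st + (yy - mid[1]) * ct
        cap = _PINCH_FACTOR * min(minor[i], minor[i + 1])
        notch_half = max(1.5, 0.15 * spec.center_spacing)
        mask &= ~((np.abs(u) <= notch_half) & (np.abs(v) > cap))

    if n == 1:
        true_length = 2.0 * radii[0]
    else:
        chord = float(np.hypot(*(centers[-1] - centers[0])))
        true_length = chord + radii[0] + radii[-1]
    true_width = float(2.0 * minor.max())

    return SyntheticPodTruth(
        mask=mask,
        seed_centers=[(float(c[0]), float(c[1])) for c in centers_px],
        true_length=float(true_length),
        true_width=true_width,
        spec=spec,
    )


def generate_branch(
    height: int,
    width: int,
    trunk_thickness: int,
    rng_seed: int = 0,
    n_side_branches: int = 2,
) -> np.ndarray:
    """Render a roughly vertical branch silhouette on a height x width canvas.

    The trunk is a smooth random walk spanning the full canvas height;
    short slanted side branches add realism. Deterministic given the seed.
    """
    if height <= 0 or width <= 0:
        raise ValueError("canvas dimensions must be positive")
    if trunk_thickness >= width:
        raise ValueError("trunk_thickness must be smaller than the canvas width")
    if trunk_thickness < 1:
        raise ValueError("trunk_thickness must be >= 1")
    rng = np.random.default_rng(rng_seed)

    half = trunk_thickness / 2.0
    # smooth lateral wander: cumulative steps, low-pass filtered
    steps = rng.uniform(-0.6, 0.6, size=height)
    path = np.cumsum(steps)
    path = ndimage.uniform_filter1d(path, size=max(5, height // 20))
    path = path - path.mean() + width / 2.0
    path = np.clip(path, half + 1, width - half - 2)

    mask = np.zeros((height, width), dtype=bool)
    cols = np.arange(width)
    for y in range(height):
        mask[y, np.abs(cols - path[y]) <= half] = True

    thin = max(1, trunk_thickness // 2)
    for _ in range(n_side_branches):
        y0 = int(rng.integers(height // 6, 5 * height // 6))
        direction = -1 if rng.random() < 0.5 else 1
        length = int(rng.integers(height // 12, height // 6))
        slope = rng.uniform(0.4, 1.2)
        for t in range(length):
            y = y0 - t
            if y < 0:
                break
            x = path[y0] + direction * slope * t
            if x < 0 or x >= width:
                break
            sel = np.abs(cols - x) <= thin / 2.0
            mask[y, sel] = True
    return mask


def pod_library(
    n: int,
    spec_ranges: dict | None = None,
    rng_seed: int = 0,
) -> list[SyntheticPodTruth]:
    """Sample ``n`` pods with specs drawn uniformly from ``spec_ranges``.

    Default ranges reflect the fixture study conditions: 1-4 seeds per
    pod, nominal lobe radius 18 +/- 3 px, centre spacing 1.5x the lobe
    radius, straight chains.

    ``spec_ranges`` keys (each an inclusive (lo, hi) pair):
    ``num_seeds``, ``seed_radius``, ``spacing_factor``, ``radius_jitter``,
    ``curvature``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = {
        "num_seeds": (1, 4),
        "seed_radius": (15.0, 21.0),
        "spacing_factor": (1.5, 1.5),
        "radius_jitter": (0.0, 0.0),
        "curvature": (0.0, 0.0),
    }
    if spec_ranges:
        ranges.update(spec_ranges)
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {key!r}: {(lo, hi)}")

    rng = np.random.default_rng(rng_seed)
    pods = []
    for i in range(n):
        num = int(rng.integers(ranges["num_seeds"][0], ranges["num_seeds"][1] + 1))
        radius = float(rng.uniform(*ranges["seed_radius"]))
        factor = float(rng.uniform(*ranges["spacing_factor"]))
        jitter = float(rng.uniform(*ranges["radius_jitter"]))
        curv = float(rng.uniform(*ranges["curvature"]))
        spec = SyntheticPodSpec(
            num_seeds=num,
            seed_radius=radius,
            center_spacing=factor * radius,
            radius_jitter=jitter,
            curvature=curv,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        pods.append(generate_pod(spec))
    return pods


def save_pod_library(pods: list[SyntheticPodTruth], out_dir: str | Path) -> list[Path]:
    """Write each pod as a 0/255 PNG plus a JSON truth sidecar."""
    from .dualmask_io import write_mask_png

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, pod in enumerate(pods):
        mask_path = out / f"pod_{i:04d}.png"
        write_mask_png(pod.mask, mask_path)
        sidecar = {
            "mask_path": mask_path.name,
            "seed_centers": pod.seed_centers,
            "true_length": pod.true_length,
            "true_width": pod.true_width,
            "spec": asdict(pod.spec) if pod.spec is not None else None,
        }
        json_path = out / f"pod_{i:04d}.json"
        json_path.write_text(json.dumps(sidecar, indent=1))
        paths.append(mask_path)
    return paths
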