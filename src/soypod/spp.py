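"""Seeds-per-pod (SPP) counting from complete (amodal) pod masks.

The chain is: pose normalization (principal axis horizontal) -> axial
width modelling from the Euclidean distance transform -> a fused density
map combining the normalized distance field, a multi-scale smoothed
response and an inverted boundary-gradient cue -> non-maximum-suppressed
density peaks -> marker-controlled watershed -> morphological filtering of
regions -> dynamic-programming selection of an ordered, regularly spaced
subset of seed centres -> fusion of the DP count with an auxiliary count
from valleys of the axial width profile.

All stage parameters live in :class:`PipelineConfig`; the defaults are the
pipeline's operating point: kappa=0.4 (standard radius as a fraction of
the median column width), rho=0.8 (peak separation in standard radii),
tau_abs=0.15 (density floor), density weights (0.45, 0.40, 0.15),
eta=1.0, lambda1=0.8, lambda2=0.6 (DP spacing / crowding penalties) and
e_max=0.98 (eccentricity cap for seed regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage import filters, measure, segmentation

from ._geometry import disk_overlap_area, largest_component, min_area_rect, rotate_mask

__all__ = [
    "PipelineConfig",
    "NormalizedPod",
    "WidthProfile",
    "DensityMap",
    "CandidateSet",
    "SegmentationResult",
    "AuxCount",
    "CountResult",
    "SppError",
    "pose_normalize",
    "width_profile",
    "fused_density",
    "nms_peaks",
    "marker_watershed",
    "morphology_filter",
    "dp_refine",
    "aux_count",
    "fuse_counts",
    "count_spp",
]


class SppError(ValueError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    kappa: float = 0.4            # standard radius = kappa * median column width
    rho: float = 0.8              # peak separation d_min = rho * r
    tau_abs: float = 0.15         # absolute density floor for peaks
    weights: tuple[float, float, float] = (0.45, 0.40, 0.15)  # (N_D, N_M, N_E)
    scales: tuple[float, ...] = (0.5, 0.75, 1.0)  # Gaussian sigmas in units of r
    eta: float = 1.0              # expected-spacing scale factor
    lambda1: float = 0.8          # spacing-deviation penalty
    lambda2: float = 0.6          # crowding (disk-overlap) penalty
    e_max: float = 0.98           # eccentricity cap for seed regions
    # Seed-region area gates in units of r. The axial width profile of a
    # single convex lobe is tent-shaped (the column max of the distance
    # field decays linearly from the lobe centre), so the median width
    # underestimates the true seed width by about a factor of two; the
    # upper gate must leave room for that, hence 3r rather than 2r.
    r_min_factor: float = 0.5     # min seed radius in units of r
    r_max_factor: float = 3.0     # max seed radius in units of r
    boundary_band: int = 2        # background-marker band width, px
    aux_prominence: float = 0.1   # valley prominence floor, fraction of max(w)
    fuse_prominence: float = 0.2  # profile-confidence floor for count fusion


@dataclass
class NormalizedPod:
    mask_rot: np.ndarray
    theta_deg: float
    crop_offset: tuple[int, int]
    removed_components: int


@dataclass
class WidthProfile:
    w: np.ndarray          # per-column width, px
    w_bar: float           # median of nonzero widths
    r: float               # standard radius = kappa * w_bar
    kappa: float


@dataclass
class DensityMap:
    F: np.ndarray
    N_D: np.ndarray
    N_M: np.ndarray
    N_E: np.ndarray
    weights: tuple[float, float, float]


@dataclass
class CandidateSet:
    peaks: list[tuple[int, int, float]]  # (x, y, score)
    d_min: float
    rho: float
    tau_abs: float


@dataclass
class SegmentationResult:
    label_map: np.ndarray
    regions: list[dict]   # id, area, eccentricity, marker (x, y, score), [reject reason]
    kept: list[tuple[int, int, float]]
    rejected: list[dict]


@dataclass
class AuxCount:
    count: int
    mean_prominence: float
    valley_columns: list[int]


@dataclass
class CountResult:
    c_main: int
    c_aux: int
    spp: int
    selected_centers: list[tuple[int, int]]
    dp_scores: list[float]
    delta_bar: float
    config: PipelineConfig = field(repr=False, default_factory=PipelineConfig)
    intermediates: dict = field(repr=False, default_factory=dict)


def _default_a_min(mask: np.ndarray) -> float:
    return max(20.0, 0.005 * float(np.count_nonzero(mask)))


def pose_normalize(mask: np.ndarray, a_min: float | None = None) -> NormalizedPod:
    """Rotate the principal axis horizontal and crop to the bounding box.

    Components smaller than ``a_min`` (default: max(20 px^2, 0.5% of the
    foreground)) are removed first; of the remainder, the largest
    component is kept, so exactly one component survives.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SppError("pose_normalize: empty mask")
    if a_min is None:
        a_min = _default_a_min(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    counts = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(counts)) + 1
    removed = n - 1
    mask = labels == keep

    rect = min_area_rect(mask)
    theta = rect.angle_deg
    rotated, _ = rotate_mask(mask, -theta)
    rotated = largest_component(rotated)  # guard against warp speckle
    # one fine-adjust pass if discretization left the axis off-horizontal
    rect2 = min_area_rect(rotated)
    if abs(rect2.angle_deg) > 1.0:
        rotated, _ = rotate_mask(rotated, -rect2.angle_deg)
        rotated = largest_component(rotated)
        theta = theta + rect2.angle_deg
    ys, xs = np.nonzero(rotated)
    y0, x0 = int(ys.min()), int(xs.min())
    cropped = rotated[y0 : ys.max() + 1, x0 : xs.max() + 1]
    return NormalizedPod(
        mask_rot=cropped, theta_deg=float(theta), crop_offset=(x0, y0), removed_components=removed
    )


def _distance_field(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(mask, 1)
    return ndimage.distance_transform_edt(padded)[1:-1, 1:-1]


def width_profile(pod: NormalizedPod, kappa: float = PipelineConfig.kappa) -> WidthProfile:
    """Axial width w(x) = 2 * column max of the distance transform."""
    D = _distance_field(pod.mask_rot)
    w = 2.0 * D.max(axis=0)
    nonzero = w[w > 0]
    if nonzero.size == 0:
        raise SppError("width_profile: mask has no interior")
    w_bar = float(np.median(nonzero))
    return WidthProfile(w=w, w_bar=w_bar, r=kappa * w_bar, kappa=kappa)


def _minmax_in_mask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(values, dtype=float)
    inside = values[mask]
    lo, hi = float(inside.min()), float(inside.max())
    if hi - lo < 1e-12:
        return out
    out[mask] = (inside - lo) / (hi - lo)
    return out


def fused_density(
    pod: NormalizedPod, profile: WidthProfile, config: PipelineConfig = PipelineConfig()
) -> DensityMap:
    """Weighted fusion of distance, multi-scale and boundary cues.

    ``N_D`` is the min-max-normalized distance field; ``N_M`` the pixelwise
    maximum of the distance field smoothed at sigmas {0.5r, 0.75r, 1.0r};
    ``N_E`` one minus the normalized boundary-gradient magnitude. All
    normalizations are within the mask; F is zero outside it.
    """
    mask = pod.mask_rot
    if profile.r <= 0:
        raise SppError("fused_density: non-positive standard radius")
    D = _distance_field(mask)
    n_d = _minmax_in_mask(D, mask)
    multi = np.max(
        [ndimage.gaussian_filter(D, sigma=s * profile.r) for s in config.scales], axis=0
    )
    n_m = _minmax_in_mask(multi, mask)
    soft = ndimage.gaussian_filter(mask.astype(float), sigma=1.0)
    grad = filters.sobel(soft)
    n_e = np.zeros_like(grad)
    n_e[mask] = 1.0 - _minmax_in_mask(grad, mask)[mask]
    a, b, c = config.weights
    F = a * n_d + b * n_m + c * n_e
    F[~mask] = 0.0
    np.clip(F, 0.0, 1.0, out=F)
    return DensityMap(F=F, N_D=n_d, N_M=n_m, N_E=n_e, weights=config.weights)


def nms_peaks(
    density: DensityMap | np.ndarray,
    r: float,
    mask: np.ndarray | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> CandidateSet:
    """Seed-centre candidates: density local maxima above the floor.

    A candidate must be the strongest response within a disk of radius
    ``d_min = rho * r`` and exceed ``tau_abs``. Plateaus of equal response
    yield one candidate each (lexicographic (y, x) tie-break), and the
    final set is greedily thinned in descending response so pairwise
    distances are >= d_min.
    """
    F = density.F if isinstance(density, DensityMap) else density
    if mask is None:
        mask = F > 0
    d_min = max(1.0, config.rho * r)
    size = int(np.ceil(d_min))
    yy, xx = np.mgrid[-size : size + 1, -size : size + 1]
    footprint = (yy**2 + xx**2) <= d_min**2
    local_max = (F >= ndimage.maximum_filter(F, footprint=footprint)) & mask & (F >= config.tau_abs)

    # collapse plateaus: one representative per connected run of candidates
    labels, n = ndimage.label(local_max, structure=np.ones((3, 3), dtype=int))
    reps: list[tuple[int, int, float]] = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        order = np.lexsort((xs, ys))
        y, x = int(ys[order[0]]), int(xs[order[0]])
        reps.append((x, y, float(F[y, x])))

    reps.sort(key=lambda p: (-p[2], p[1], p[0]))
    accepted: list[tuple[int, int, float]] = []
    for x, y, s in reps:
        if all((x - ax) ** 2 + (y - ay) ** 2 >= d_min**2 for ax, ay, _ in accepted):
            accepted.append((x, y, s))
    return CandidateSet(peaks=accepted, d_min=float(d_min), rho=config.rho, tau_abs=config.tau_abs)


def marker_watershed(
    pod: NormalizedPod,
    density: DensityMap,
    candidates: CandidateSet,
    config: PipelineConfig = PipelineConfig(),
) -> SegmentationResult:
    """Flood the inverted fused density from the candidate markers.

    Candidates are foreground markers; everything outside the mask plus a
    thin inner boundary band is the background marker, so each candidate
    seeds exactly one region and regions partition the mask interior.
    """
    if not candidates.peaks:
        raise SppError("marker_watershed: no seeds detected")
    mask = pod.mask_rot
    band = mask & ~ndimage.binary_erosion(mask, iterations=config.boundary_band)
    markers = np.zeros(mask.shape, dtype=np.int32)
    background = ~mask | band
    for x, y, _ in candidates.peaks:
        background[y, x] = False  # a marker never sits in the background set
    markers[background] = 1
    for i, (x, y, _) in enumerate(candidates.peaks, start=2):
        markers[y, x] = i
    labels = segmentation.watershed(-density.F, markers=markers, mask=None)
    labels[~mask] = 0
    labels[labels == 1] = 0  # background basin
    label_map = np.where(labels >= 2, labels - 1, 0)  # regions numbered 1..k

    regions = []
    props = {p.label: p for p in measure.regionprops(label_map)}
    for i, peak in enumerate(candidates.peaks, start=1):
        p = props.get(i)
        regions.append(
            {
                "id": i,
                "area": int(p.area) if p else 0,
                "eccentricity": float(p.eccentricity) if p else 1.0,
                "marker": peak,
            }
        )
    return SegmentationResult(label_map=label_map, regions=regions, kept=list(candidates.peaks), rejected=[])


def morphology_filter(
    seg: SegmentationResult, r: float, config: PipelineConfig = PipelineConfig()
) -> SegmentationResult:
    """Reject regions outside the plausible seed-area band or too elongated.

    Area bounds are pi*(r_min_factor*r)^2 .. pi*(r_max_factor*r)^2;
    eccentricity must not exceed ``e_max``. Surviving markers form the
    refined candidate set.
    """
    a_min = np.pi * (config.r_min_factor * r) ** 2
    a_max = np.pi * (config.r_max_factor * r) ** 2
    kept, rejected = [], []
    for region in seg.regions:
        if region["area"] < a_min:
            rejected.append({**region, "reason": "too_small"})
        elif region["area"] > a_max:
            rejected.append({**region, "reason": "too_large"})
        elif region["eccentricity"] > config.e_max:
            rejected.append({**region, "reason": "elongated"})
        else:
            kept.append(region["marker"])
    if not kept:
        raise SppError("morphology_filter: no valid seed regions")
    kept_regions = [reg for reg in seg.regions if reg["marker"] in kept]
    return SegmentationResult(
        label_map=seg.label_map, regions=kept_regions, kept=kept, rejected=rejected
    )


def dp_refine(
    candidates: list[tuple[int, int, float]],
    profile: WidthProfile,
    config: PipelineConfig = PipelineConfig(),
) -> CountResult:
    """Select the ordered seed-centre subset maximizing the total DP score.

    Candidates are sorted by x. The expected spacing is ``delta_bar =
    eta * mean(w(x_i))``. A candidate scores its density response minus a
    spacing penalty ``lambda1 * ((gap - delta_bar)/delta_bar)^2`` against
    its selected predecessor (no penalty for the first of a chain) and a
    crowding penalty ``lambda2 * o_i`` where ``o_i`` is the largest
    fractional disk overlap with any other candidate. The recursion
    ``cost[i] = max(start_i, max_{j<i} cost[j] + S_i(j))`` with backtracking
    yields the optimal ordered subset; its size is the main count.
    """
    if not candidates:
        raise SppError("dp_refine: empty candidate set")
    pts = sorted(candidates, key=lambda p: (p[0], p[1]))
    n = len(pts)
    xs = np.array([p[0] for p in pts], dtype=float)
    ys = np.array([p[1] for p in pts], dtype=float)
    ss = np.array([p[2] for p in pts], dtype=float)

    w = profile.w
    cols = np.clip(np.round(xs).astype(int), 0, len(w) - 1)
    delta_bar = config.eta * float(np.mean(w[cols]))
    if delta_bar <= 0:
        delta_bar = max(2.0 * profile.r, 1.0)

    r = profile.r
    disk_area = np.pi * r * r
    overlap = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                d = float(np.hypot(xs[i] - xs[j], ys[i] - ys[j]))
                overlap[i] = max(overlap[i], disk_overlap_area(d, r) / disk_area)

    base = ss - config.lambda2 * overlap
    cost = np.full(n, -np.inf)
    prev = np.full(n, -1, dtype=int)
    for i in range(n):
        cost[i] = base[i]  # start of a chain: no spacing penalty
        for j in range(i):
            if xs[j] >= xs[i]:
                continue  # selected centres must be strictly increasing in x
            gap = xs[i] - xs[j]
            s_ij = base[i] - config.lambda1 * ((gap - delta_bar) / delta_bar) ** 2
            c = cost[j] + s_ij
            if c > cost[i]:
                cost[i] = c
                prev[i] = j
    end = int(np.argmax(cost))
    chain = []
    i = end
    while i != -1:
        chain.append(i)
        i = prev[i]
    chain.reverse()
    selected = [(int(xs[i]), int(ys[i])) for i in chain]
    return CountResult(
        c_main=len(selected),
        c_aux=0,
        spp=len(selected),
        selected_centers=selected,
        dp_scores=[float(cost[i]) for i in chain],
        delta_bar=float(delta_bar),
        config=config,
    )


def aux_count(profile: WidthProfile, r: float, config: PipelineConfig = PipelineConfig()) -> AuxCount:
    """Count seeds from the axial width profile.

    Valleys of ``1 - w(x)`` (equivalently bulges of ``w``) with prominence
    at least ``aux_prominence * max(w)`` and pairwise separation >= 0.8r
    are counted; a nonempty profile always yields at least one (a flat
    plateau counts once).
    """
    w = profile.w
    if not np.any(w > 0):
        raise SppError("aux_count: empty width profile")
    wmax = float(w.max())
    distance = max(1, int(round(config.rho * r)))
    peaks, props = signal.find_peaks(w, prominence=config.aux_prominence * wmax, distance=distance)
    if peaks.size == 0:
        # single-bulge or flat profile: one seed's worth of evidence
        return AuxCount(count=1, mean_prominence=wmax, valley_columns=[int(np.argmax(w))])
    return AuxCount(
        count=int(peaks.size),
        mean_prominence=float(np.mean(props["prominences"])),
        valley_columns=[int(p) for p in peaks],
    )


def fuse_counts(
    c_main: int,
    aux: AuxCount,
    w_max: float,
    config: PipelineConfig = PipelineConfig(),
) -> int:
    """Prefer consistent, confident profile evidence; else keep the DP count."""
    if aux.count == c_main:
        return c_main
    if abs(aux.count - c_main) <= 1 and aux.mean_prominence >= config.fuse_prominence * w_max:
        return aux.count
    return c_main


def count_spp(
    mask: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    a_min: float | None = None,
) -> CountResult:
    """Run the full counting chain on one amodal pod mask.

    Returns the fused count plus all intermediates (normalized pod, width
    profile, density map, candidates, watershed segmentation) for
    inspection. Deterministic.
    """
    pod = pose_normalize(mask, a_min=a_min)
    profile = width_profile(pod, kappa=config.kappa)
    density = fused_density(pod, profile, config)
    candidates = nms_peaks(density, profile.r, mask=pod.mask_rot, config=config)
    if not candidates.peaks:
        raise SppError("nms_peaks: no density peaks above the floor")
    seg = marker_watershed(pod, density, candidates, config)
    seg = morphology_filter(seg, profile.r, config)
    result = dp_refine(seg.kept, profile, config)
    aux = aux_count(profile, profile.r, config)
    spp = fuse_counts(result.c_main, aux, float(profile.w.max()), config)
    result.c_aux = aux.count
    result.spp = spp
    result.intermediates = {
        "normalized": pod,
        "profile": profile,
        "density": density,
        "candidates": candidates,
        "segmentation": seg,
        "aux": aux,
    }
    return result
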