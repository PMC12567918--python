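"""The SPP counting chain, stage by stage, against constructed oracles."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from conftest import make_disk, make_rect
from soypod._geometry import disk_overlap_area, rotate_mask
from soypod.fixtures import SyntheticPodSpec, generate_pod
from soypod.spp import (
    PipelineConfig,
    SppError,
    WidthProfile,
    aux_count,
    count_spp,
    dp_refine,
    fuse_counts,
    fused_density,
    marker_watershed,
    morphology_filter,
    nms_peaks,
    pose_normalize,
    width_profile,
)


def brute_force_distance(mask):
    """O(n^2) Euclidean distance-to-background oracle for tiny masks."""
    ys, xs = np.nonzero(mask)
    bys, bxs = np.nonzero(~np.pad(mask, 1))
    out = np.zeros(mask.shape)
    for y, x in zip(ys, xs):
        out[y, x] = np.min(np.hypot(bxs - 1 - x, bys - 1 - y))
    return out


class TestPoseNormalize:
    def test_horizontal_ellipse_unchanged_up_to_crop(self):
        yy, xx = np.mgrid[0:41, 0:81]
        ellipse = (xx - 40) ** 2 / 30**2 + (yy - 20) ** 2 / 12**2 <= 1
        pod = pose_normalize(ellipse)
        assert abs(pod.theta_deg) <= 1.0
        assert pod.mask_rot.sum() == ellipse.sum()

    def test_rotated_ellipse_recovered(self):
        yy, xx = np.mgrid[0:41, 0:81]
        ellipse = (xx - 40) ** 2 / 30**2 + (yy - 20) ** 2 / 12**2 <= 1
        rotated, _ = rotate_mask(ellipse, 30.0)
        pod = pose_normalize(rotated)
        ref = pose_normalize(ellipse)
        # align by bounding boxes and compare IoU
        a, b = pod.mask_rot, ref.mask_rot
        h = min(a.shape[0], b.shape[0])
        w = min(a.shape[1], b.shape[1])
        inter = (a[:h, :w] & b[:h, :w]).sum()
        union = (a[:h, :w] | b[:h, :w]).sum() + abs(a.sum() - b.sum())
        assert inter / union >= 0.95

    def test_speck_removed(self):
        mask = make_rect(12, 50)
        mask[1, 1] = True  # 1-px speck far from the pod
        pod = pose_normalize(mask)
        assert pod.removed_components == 1
        assert pod.mask_rot.sum() == 12 * 50

    def test_empty_mask_rejected(self):
        with pytest.raises(SppError, match="empty"):
            pose_normalize(np.zeros((10, 10), dtype=bool))


class TestWidthProfile:
    def test_rectangle_interior_width_matches_distance_oracle(self):
        mask = make_rect(10, 50)
        pod = pose_normalize(mask)
        profile = width_profile(pod)
        oracle = brute_force_distance(pod.mask_rot)
        assert np.allclose(profile.w, 2 * oracle.max(axis=0))
        interior = profile.w[10:40]
        assert np.all(np.abs(interior - 10) <= 1.0)
        assert profile.w_bar == pytest.approx(10.0, abs=1.0)
        assert profile.r == pytest.approx(0.4 * profile.w_bar)

    def test_disk_peak_width_is_diameter(self):
        pod = pose_normalize(make_disk(10))
        profile = width_profile(pod)
        assert abs(profile.w.max() - 20) <= 1.0

    def test_three_lobe_profile_has_three_maxima(self, three_lobe_pod):
        pod = pose_normalize(three_lobe_pod.mask)
        profile = width_profile(pod)
        w = profile.w[profile.w > 0]
        keep = np.concatenate([[True], np.diff(w) != 0])
        c = w[keep]
        n_max = sum(
            1 for i in range(1, len(c) - 1) if c[i] > c[i - 1] and c[i] > c[i + 1]
        )
        n_min = sum(
            1 for i in range(1, len(c) - 1) if c[i] < c[i - 1] and c[i] < c[i + 1]
        )
        assert n_max == 3 and n_min == 2


class TestFusedDensity:
    def test_disk_density_peaks_at_center(self):
        mask = make_disk(12)
        pod = pose_normalize(mask)
        profile = width_profile(pod)
        density = fused_density(pod, profile)
        y, x = np.unravel_index(np.argmax(density.F), density.F.shape)
        cy, cx = (np.array(pod.mask_rot.shape) - 1) / 2.0
        assert np.hypot(x - cx, y - cy) <= 2.0
        assert density.F.max() <= 1.0 + 1e-9

    def test_density_is_weighted_sum_inside_mask(self, three_lobe_pod):
        pod = pose_normalize(three_lobe_pod.mask)
        profile = width_profile(pod)
        d = fused_density(pod, profile)
        recomposed = 0.45 * d.N_D + 0.40 * d.N_M + 0.15 * d.N_E
        assert np.allclose(d.F[pod.mask_rot], recomposed[pod.mask_rot], atol=1e-9)
        assert np.all(d.F[~pod.mask_rot] == 0)

    def test_three_lobes_give_three_separated_maxima(self, three_lobe_pod):
        pod = pose_normalize(three_lobe_pod.mask)
        profile = width_profile(pod)
        density = fused_density(pod, profile)
        peaks = nms_peaks(density, profile.r, mask=pod.mask_rot).peaks
        strong = [p for p in peaks if p[2] >= 0.15]
        assert len(strong) == 3
        for a, b in itertools.combinations(strong, 2):
            assert np.hypot(a[0] - b[0], a[1] - b[1]) >= 0.8 * profile.r


class TestNmsPeaks:
    @staticmethod
    def gaussian_bump(shape, cx, cy, amp, sigma):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))

    def test_two_distant_bumps_two_peaks(self):
        r = 6.0
        F = self.gaussian_bump((40, 80), 20, 20, 0.9, 4) + self.gaussian_bump((40, 80), 56, 20, 0.9, 4)
        peaks = nms_peaks(F, r, mask=np.ones_like(F, dtype=bool)).peaks
        assert len(peaks) == 2

    def test_two_close_bumps_merge_to_strongest(self):
        r = 10.0  # d_min = 8; bumps 4 px apart
        F = self.gaussian_bump((40, 60), 28, 20, 0.9, 3) + self.gaussian_bump((40, 60), 32, 20, 0.7, 3)
        peaks = nms_peaks(F, r, mask=np.ones_like(F, dtype=bool)).peaks
        assert len(peaks) == 1
        # exhaustive scan oracle for the global max
        y, x = np.unravel_index(np.argmax(F), F.shape)
        assert peaks[0][:2] == (x, y)

    def test_subthreshold_field_yields_no_peaks(self):
        F = np.full((20, 20), 0.1)
        assert nms_peaks(F, 5.0, mask=np.ones_like(F, dtype=bool)).peaks == []


class TestWatershedAndMorphology:
    def test_single_candidate_single_region(self):
        mask = make_disk(12)
        pod = pose_normalize(mask)
        profile = width_profile(pod)
        density = fused_density(pod, profile)
        cands = nms_peaks(density, profile.r, mask=pod.mask_rot)
        seg = marker_watershed(pod, density, cands)
        assert len(seg.regions) == 1
        assert seg.regions[0]["area"] >= 0.5 * pod.mask_rot.sum()

    def test_dumbbell_cut_falls_at_neck(self):
        truth = generate_pod(SyntheticPodSpec(num_seeds=2, seed_radius=15, center_spacing=24, rng_seed=2))
        pod = pose_normalize(truth.mask)
        profile = width_profile(pod)
        density = fused_density(pod, profile)
        cands = nms_peaks(density, profile.r, mask=pod.mask_rot)
        assert len(cands.peaks) == 2
        seg = marker_watershed(pod, density, cands)
        labels = seg.label_map
        # neck: midpoint between the two lobe centres (normalized frame keeps x-order)
        neck_x = pod.mask_rot.shape[1] / 2.0
        border = (labels[:, :-1] != labels[:, 1:]) & (labels[:, :-1] > 0) & (labels[:, 1:] > 0)
        xs = np.nonzero(border)[1]
        assert xs.size > 0
        assert abs(np.median(xs) - neck_x) <= 3.0

    def test_each_marker_seeds_own_region(self, three_lobe_pod):
        pod = pose_normalize(three_lobe_pod.mask)
        profile = width_profile(pod)
        density = fused_density(pod, profile)
        cands = nms_peaks(density, profile.r, mask=pod.mask_rot)
        seg = marker_watershed(pod, density, cands)
        assert len(seg.regions) == len(cands.peaks)
        for i, region in enumerate(seg.regions, start=1):
            x, y, _ = region["marker"]
            assert seg.label_map[y, x] == i

    def test_empty_candidates_rejected(self):
        pod = pose_normalize(make_disk(10))
        profile = width_profile(pod)
        density = fused_density(pod, profile)
        from soypod.spp import CandidateSet

        with pytest.raises(SppError, match="no seeds"):
            marker_watershed(pod, density, CandidateSet([], 1.0, 0.8, 0.15))

    def test_morphology_rejects_small_large_elongated(self):
        from soypod.spp import SegmentationResult

        r = 10.0
        regions = [
            {"id": 1, "area": int(np.pi * (0.1 * r) ** 2), "eccentricity": 0.1, "marker": (5, 5, 0.9)},
            {"id": 2, "area": int(np.pi * r**2), "eccentricity": 0.1, "marker": (30, 5, 0.9)},
            {"id": 3, "area": int(np.pi * r**2), "eccentricity": 0.995, "marker": (60, 5, 0.9)},
            {"id": 4, "area": int(np.pi * (5 * r) ** 2), "eccentricity": 0.2, "marker": (90, 5, 0.9)},
        ]
        seg = SegmentationResult(label_map=np.zeros((1, 1), int), regions=regions, kept=[], rejected=[])
        out = morphology_filter(seg, r)
        assert out.kept == [(30, 5, 0.9)]
        reasons = {r["id"]: r["reason"] for r in out.rejected}
        assert reasons == {1: "too_small", 3: "elongated", 4: "too_large"}

    def test_all_rejected_raises(self):
        from soypod.spp import SegmentationResult

        seg = SegmentationResult(
            label_map=np.zeros((1, 1), int),
            regions=[{"id": 1, "area": 1, "eccentricity": 0.0, "marker": (0, 0, 0.5)}],
            kept=[],
            rejected=[],
        )
        with pytest.raises(SppError, match="no valid seed regions"):
            morphology_filter(seg, 10.0)


def dp_oracle(candidates, profile, config=PipelineConfig()):
    """Exhaustive maximization over all ordered candidate subsets."""
    pts = sorted(candidates, key=lambda p: (p[0], p[1]))
    n = len(pts)
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    ss = [p[2] for p in pts]
    w = profile.w
    cols = [min(max(int(round(x)), 0), len(w) - 1) for x in xs]
    delta_bar = config.eta * float(np.mean([w[c] for c in cols]))
    if delta_bar <= 0:
        delta_bar = max(2.0 * profile.r, 1.0)
    r = profile.r
    disk_area = np.pi * r * r
    o = [
        max(
            (disk_overlap_area(np.hypot(xs[i] - xs[j], ys[i] - ys[j]), r) / disk_area
             for j in range(n) if j != i),
            default=0.0,
        )
        for i in range(n)
    ]
    best_score, best_chain = -np.inf, None
    for size in range(1, n + 1):
        for chain in itertools.combinations(range(n), size):
            if any(xs[chain[k]] >= xs[chain[k + 1]] for k in range(size - 1)):
                continue
            score = 0.0
            for k, i in enumerate(chain):
                s = ss[i] - config.lambda2 * o[i]
                if k > 0:
                    gap = xs[i] - xs[chain[k - 1]]
                    s -= config.lambda1 * ((gap - delta_bar) / delta_bar) ** 2
                score += s
            if score > best_score:
                best_score, best_chain = score, chain
    return best_score, best_chain


class TestDpRefine:
    def flat_profile(self, length=200, width=20.0, kappa=0.4):
        w = np.full(length, width)
        return WidthProfile(w=w, w_bar=width, r=kappa * width, kappa=kappa)

    def test_single_candidate_selected(self):
        profile = self.flat_profile()
        result = dp_refine([(50, 10, 0.9)], profile)
        assert result.c_main == 1
        assert result.selected_centers == [(50, 10)]

    def test_evenly_spaced_candidates_all_selected(self):
        profile = self.flat_profile(width=20.0)
        cands = [(20 + 20 * k, 10, 0.9) for k in range(4)]  # spacing = delta_bar
        result = dp_refine(cands, profile)
        oracle_score, oracle_chain = dp_oracle(cands, profile)
        assert result.c_main == len(oracle_chain) == 4
        assert result.dp_scores[-1] == pytest.approx(oracle_score)

    def test_weak_crowded_midpoint_excluded(self):
        # two strong candidates one expected spacing apart; a weak candidate
        # (s = 0.16) at their midpoint whose disk overlaps both by ~50%
        w = np.full(200, 40.0)
        w[[50, 63, 76]] = 26.0  # delta_bar = mean w at candidates = 26
        profile = WidthProfile(w=w, w_bar=40.0, r=16.0, kappa=0.4)
        cands = [(50, 10, 0.9), (63, 10, 0.16), (76, 10, 0.9)]
        result = dp_refine(cands, profile)
        oracle_score, _ = dp_oracle(cands, profile)
        assert result.dp_scores[-1] == pytest.approx(oracle_score)
        assert result.c_main == 2
        assert (63, 10) not in result.selected_centers

    def test_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = int(rng.integers(1, 9))
            xs = np.sort(rng.choice(np.arange(0, 180, 3), size=n, replace=False))
            cands = [
                (int(x), int(rng.integers(5, 15)), float(rng.uniform(0.15, 1.0))) for x in xs
            ]
            w = rng.uniform(8.0, 30.0, size=200)
            profile = WidthProfile(w=w, w_bar=float(np.median(w)), r=0.4 * float(np.median(w)), kappa=0.4)
            result = dp_refine(cands, profile)
            oracle_score, _ = dp_oracle(cands, profile)
            assert result.dp_scores[-1] == pytest.approx(oracle_score, abs=1e-9)

    def test_empty_candidates_rejected(self):
        with pytest.raises(SppError, match="empty"):
            dp_refine([], self.flat_profile())


class TestAuxAndFusion:
    def test_single_bulge_counts_one(self):
        pod = pose_normalize(make_disk(12))
        profile = width_profile(pod)
        assert aux_count(profile, profile.r).count == 1

    def test_three_lobe_profile_counts_three(self, three_lobe_pod):
        pod = pose_normalize(three_lobe_pod.mask)
        profile = width_profile(pod)
        assert aux_count(profile, profile.r).count == 3

    def test_flat_rectangle_counts_one(self):
        pod = pose_normalize(make_rect(10, 60))
        profile = width_profile(pod)
        assert aux_count(profile, profile.r).count == 1

    def test_fusion_rules(self):
        from soypod.spp import AuxCount

        strong = AuxCount(count=3, mean_prominence=10.0, valley_columns=[])
        weak = AuxCount(count=3, mean_prominence=0.5, valley_columns=[])
        far = AuxCount(count=5, mean_prominence=10.0, valley_columns=[])
        w_max = 20.0
        assert fuse_counts(3, strong, w_max) == 3          # agreement
        assert fuse_counts(2, strong, w_max) == 3          # adjacent + confident
        assert fuse_counts(2, weak, w_max) == 2            # adjacent but weak
        assert fuse_counts(2, far, w_max) == 2             # inconsistent profile ignored


class TestCountSpp:
    @pytest.mark.parametrize("num_seeds", [1, 2, 3, 4])
    def test_fixture_pod_counts_match_construction(self, num_seeds):
        truth = generate_pod(
            SyntheticPodSpec(num_seeds=num_seeds, seed_radius=18, center_spacing=27, rng_seed=13)
        )
        result = count_spp(truth.mask)
        assert result.spp == num_seeds
        assert 1 <= result.spp <= len(result.intermediates["candidates"].peaks)
        xs = [c[0] for c in result.selected_centers]
        assert xs == sorted(xs)

    def test_rotation_invariant_counts(self):
        truth = generate_pod(
            SyntheticPodSpec(num_seeds=3, seed_radius=16, center_spacing=24, rng_seed=21)
        )
        base = count_spp(truth.mask).spp
        for phi in (15, 30, 45, 60, 75):
            rotated, _ = rotate_mask(truth.mask, phi)
            assert count_spp(rotated).spp == base

    def test_deterministic(self, three_lobe_pod):
        a = count_spp(three_lobe_pod.mask)
        b = count_spp(three_lobe_pod.mask)
        assert a.spp == b.spp
        assert a.selected_centers == b.selected_centers
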