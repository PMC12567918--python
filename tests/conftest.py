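import numpy as np
import pytest

from soypod import spp, traits
from soypod.fixtures import SyntheticPodSpec, generate_pod, pod_library


@pytest.fixture(scope="session")
def three_lobe_pod():
    """A straight 3-seed pod with spacing 1.5x radius."""
    return generate_pod(SyntheticPodSpec(num_seeds=3, seed_radius=15, center_spacing=22.5, rng_seed=7))


@pytest.fixture(scope="session")
def small_library():
    return pod_library(12, rng_seed=1)


@pytest.fixture(scope="session")
def small_library_masks(small_library):
    return [p.mask for p in small_library]


def make_disk(radius: int, pad: int = 4) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = radius + pad
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


def make_rect(height: int, width: int, pad: int = 5) -> np.ndarray:
    mask = np.zeros((height + 2 * pad, width + 2 * pad), dtype=bool)
    mask[pad : pad + height, pad : pad + width] = True
    return mask


@pytest.fixture(scope="session")
def benchmark_batch():
    """The reference 200-pod counting/trait run shared by accuracy checks.

    Conditions: 1-4 seeds per pod, lobe radius 18 +/- 3 px, spacing 1.5x
    radius, straight chains, no occlusion, master seed 42.
    """
    pods = pod_library(
        200,
        spec_ranges={"num_seeds": (1, 4), "seed_radius": (15.0, 21.0), "spacing_factor": (1.5, 1.5)},
        rng_seed=42,
    )
    rows = []
    for pod in pods:
        result = spp.count_spp(pod.mask)
        record = traits.measure_traits(pod.mask)
        rows.append(
            {
                "true_count": pod.num_seeds,
                "pred_count": result.spp,
                "true_length": pod.true_length,
                "pred_length": record.length_px,
                "true_width": pod.true_width,
                "pred_width": record.width_px,
            }
        )
    return rows
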