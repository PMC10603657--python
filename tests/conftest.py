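import numpy as np
import pytest

from clickseg.synthetic import SynthConfig, generate_instance


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def overfit_set():
    """Eight small synthetic instances shared by the training tests."""
    cfg = SynthConfig(
        image_size=64,
        n_samples=8,
        blob_area_fraction_range=(0.08, 0.3),
        boundary_roughness=0.12,
        seed=7,
    )
    root = np.random.default_rng(7)
    samples = []
    for _ in range(8):
        s = generate_instance(cfg, np.random.default_rng(int(root.integers(2**31))))
        samples.append((s.image, s.mask))
    return samples


def disk_mask(size: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (((yy - cy) ** 2 + (xx - cx) ** 2) <= radius**2).astype(np.uint8)


@pytest.fixture
def disk():
    return disk_mask
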