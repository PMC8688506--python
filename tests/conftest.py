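import numpy as np
import pytest

import segscale as ss


@pytest.fixture(scope="session")
def small_phantom() -> ss.PhantomSample:
    """64^3 phantom at 15 um used across tests (all four classes present)."""
    spec = ss.PhantomSpec(grid_shape=(64, 64, 64), voxel_size_um=15.0, seed=0)
    return ss.generate_phantom(spec)


@pytest.fixture(scope="session")
def crisp_phantom() -> ss.PhantomSample:
    """Noise-free phantom: gray values equal the class means exactly."""
    spec = ss.PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size_um=15.0,
        intensity_sigmas={c: 0.0 for c in range(4)},
        seed=3,
    )
    return ss.generate_phantom(spec)


@pytest.fixture(scope="session")
def smooth_volume() -> ss.Volume:
    """A smooth (band-limited) Gaussian-blob field for interpolation tests."""
    n = 64
    z, y, x = np.meshgrid(*[np.linspace(-1, 1, n)] * 3, indexing="ij")
    rng = np.random.default_rng(42)
    data = np.zeros((n, n, n), dtype=np.float32)
    for _ in range(6):
        c = rng.uniform(-0.5, 0.5, size=3)
        w = rng.uniform(0.5, 0.8)
        a = rng.uniform(0.2, 1.0)
        data += a * np.exp(-(((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2) / w**2))
    data /= data.max()
    return ss.Volume(data.astype(np.float32), ss.VoxelGeometry(5.0))


class IntensityOraclePredictor:
    """Maps phantom gray levels back to their class by nearest intensity mean.

    Acts as a perfect slice predictor for phantoms rendered with zero noise;
    emits (almost) one-hot probability maps.
    """

    divisor = 1
    n_classes = 4

    def __init__(self, means: dict[int, float], sharp: float = 60.0):
        order = sorted(means)
        self.means = np.array([means[c] for c in order], dtype=np.float32)
        self.sharp = sharp

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        # x: (N, 1, H, W) -> (N, k, H, W)
        d = -self.sharp * np.abs(x - self.means[None, :, None, None])
        e = np.exp(d - d.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


@pytest.fixture(scope="session")
def oracle_predictor() -> IntensityOraclePredictor:
    return IntensityOraclePredictor(ss.phantom.DEFAULT_INTENSITY_MEANS)
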