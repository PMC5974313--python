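import numpy as np
import pytest

from nichestat import SpatialWindow, make_window


@pytest.fixture
def plain_window() -> SpatialWindow:
    """Standard 150×150 μm analysis window, no exclusions."""
    return SpatialWindow(width=150.0, height=150.0)


@pytest.fixture
def follicle_window() -> SpatialWindow:
    """150×150 μm window with one central 30 μm-radius follicle."""
    return make_window(150.0, 150.0, [(75.0, 75.0, 30.0)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def brute_force_nearest(targets: np.ndarray, references: np.ndarray) -> np.ndarray:
    """O(n²) all-pairs nearest-reference distances (oracle)."""
    diff = targets[:, None, :] - references[None, :, :]
    return np.sqrt((diff ** 2).sum(-1)).min(axis=1)


def brute_force_hopkins(points: np.ndarray, origins: np.ndarray,
                        data_indices: np.ndarray, exponent: int) -> float:
    """All-pairs-distance Hopkins computation (oracle).

    u_i: origin i to its nearest data point; w_i: data point
    data_indices[i] to its nearest *other* data point (by index, so a
    coincident duplicate yields distance 0).
    """
    u = brute_force_nearest(origins, points)
    w = np.empty(len(data_indices))
    for k, idx in enumerate(np.asarray(data_indices)):
        others = np.delete(points, idx, axis=0)
        w[k] = np.sqrt(((points[idx] - others) ** 2).sum(-1)).min()
    su = float((u ** exponent).sum())
    sw = float((w ** exponent).sum())
    return 0.5 if su + sw == 0 else su / (su + sw)
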