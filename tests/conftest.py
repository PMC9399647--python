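import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ladgcn.synthetic_tiles import generate_dataset
from ladgcn.train_eval import load_samples


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """10 tiles per class with ground-truth masks, written once per session."""
    root = tmp_path_factory.mktemp("tiles")
    manifest = generate_dataset(10, 500, root)
    return manifest, root


@pytest.fixture(scope="session")
def small_samples(small_dataset):
    manifest, root = small_dataset
    samples, labels, class_names = load_samples(manifest, root)
    return samples, labels, class_names


def numerical_gradient(loss_fn, tensor, eps=1e-6):
    """Central finite differences of a scalar loss w.r.t. one tensor."""
    grad = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = tensor.data[idx]
        tensor.data[idx] = orig + eps
        f_plus = loss_fn()
        tensor.data[idx] = orig - eps
        f_minus = loss_fn()
        tensor.data[idx] = orig
        grad[idx] = (f_plus - f_minus) / (2 * eps)
    return grad


def raster_ellipse(a, b, theta=0.0, shape=(64, 64)):
    """Binary ellipse rasterized about a half-integer center (symmetric grid)."""
    cr = (shape[0] - 1) / 2
    cc = (shape[1] - 1) / 2
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    y = (yy - cr) * np.cos(theta) + (xx - cc) * np.sin(theta)
    x = -(yy - cr) * np.sin(theta) + (xx - cc) * np.cos(theta)
    return (y / a) ** 2 + (x / b) ** 2 <= 1.0
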