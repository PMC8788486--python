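import numpy as np
import pytest
from scipy import ndimage

from snicseg import init_seeds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_image():
    return np.full((16, 16), 128, dtype=np.uint8)


@pytest.fixture
def step_image():
    """Left half 0, right half 255 on an 8x8 grid."""
    img = np.zeros((8, 8), dtype=np.uint8)
    img[:, 4:] = 255
    return img


@pytest.fixture
def blurred_disk_image():
    """Bright disk on dark background, blurred with mild noise; 16x16."""
    rr, cc = np.mgrid[:16, :16]
    img = np.where((rr - 8) ** 2 + (cc - 8) ** 2 <= 25, 200.0, 40.0)
    img = ndimage.gaussian_filter(img, 1.0)
    img += np.random.default_rng(1).normal(0, 5, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def voronoi_partition(shape, n_segments):
    """Brute-force nearest-seed partition of a uniform image.

    Per-pixel argmin of Euclidean distance over all grid seeds; midline ties
    go to the larger label, matching the queue engine where border-limited
    clusters drift toward each other so the later seed claims the midline.
    """
    h, w = shape
    seeds = np.asarray(init_seeds(shape, n_segments), dtype=float)
    rr, cc = np.mgrid[:h, :w]
    d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
    k = d2.shape[-1]
    return (k - 1 - d2[..., ::-1].argmin(axis=-1)).astype(np.int32)


def brute_force_lbp(image):
    """Per-pixel loop LBP with edge replication; oracle for the vectorised map."""
    img = np.pad(np.asarray(image, dtype=float), 1, mode="edge")
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    h, w = np.asarray(image).shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            code = 0
            for p, (dr, dc) in enumerate(offsets):
                if img[1 + r + dr, 1 + c + dc] >= img[1 + r, 1 + c]:
                    code += 2**p
            out[r, c] = code
    return out


def assert_valid_partition(labels, n_segments, connectivity=4):
    """Label-map invariants: full coverage, all labels present, connected."""
    labels = np.asarray(labels)
    assert labels.min() >= 0, "unlabeled pixels remain"
    assert labels.max() < n_segments
    counts = np.bincount(labels.ravel(), minlength=n_segments)
    assert (counts > 0).all(), "some labels have no pixels"
    structure = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        if connectivity == 4
        else np.ones((3, 3))
    )
    for k in range(n_segments):
        _, n_comp = ndimage.label(labels == k, structure=structure)
        assert n_comp == 1, f"label {k} has {n_comp} components"
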