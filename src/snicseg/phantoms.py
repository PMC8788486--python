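"""Synthetic phantoms with exact ground truth.

Real vertebral/liver CT slices come with expert masks that cannot be
redistributed, so the test surface is built on phantoms: piecewise-constant
images whose label maps are known exactly, degraded by Gaussian edge blur
and additive Gaussian noise to emulate the blurred boundaries and uneven
gray levels of soft-tissue CT. The ground truth is always the *pre-blur*
region map, so every metric has an exact reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "make_blob_phantom", "make_grid_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a blob phantom.

    ``intensity_levels[0]`` is the background level; each further level is
    one elliptical "bone" blob. Levels must be pairwise at least 20 apart so
    the ground truth is meaningful against the noise floor. Defaults render
    one bright blob (level 200) on a dark background (level 30) with 1 px
    edge blur and sigma-5 noise on a 512x512 grid, the size of the CT slices
    the tool targets.
    """

    shape: tuple[int, int] = (512, 512)
    n_regions: int = 2
    intensity_levels: tuple[float, ...] = (30.0, 200.0)
    edge_blur_sigma: float = 1.0
    noise_sigma: float = 5.0
    seed: int = 42

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions (background + 1 blob)")
        if len(self.intensity_levels) != self.n_regions:
            raise ValueError("one intensity level per region required")
        lv = np.asarray(self.intensity_levels, dtype=float)
        if lv.min() < 0 or lv.max() > 255:
            raise ValueError("intensity levels must lie in [0, 255]")
        diffs = np.abs(lv[:, None] - lv[None, :])
        if (diffs[np.triu_indices(len(lv), 1)] < 20).any():
            raise ValueError("intensity levels must be pairwise >= 20 apart")
        if self.shape[0] < 16 or self.shape[1] < 16:
            raise ValueError("phantom shape must be at least 16x16")
        if self.edge_blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur and noise sigmas must be >= 0")


def _draw_ellipse(shape, center, axes, theta) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def make_blob_phantom(spec: PhantomSpec = PhantomSpec()):
    """Render a blob phantom and its exact ground truth.

    Blobs are random non-touching ellipses (a 2 px clearance keeps regions
    separated and the background connected); they never touch the image
    border. The image is the piecewise-constant level map blurred by
    ``edge_blur_sigma`` and corrupted with N(0, noise_sigma) noise, clipped
    to [0, 255] and quantised to uint8. Fully reproducible from ``seed``.

    Returns
    -------
    image : ndarray of uint8
    gt_labels : ndarray of int32
        0 = background, 1..n_regions-1 = blobs (the pre-blur region map).
    mask : ndarray of bool
        Foreground mask, i.e. ``gt_labels > 0``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    gt = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)  # blobs + clearance margin
    n_blobs = spec.n_regions - 1
    lo, hi = 0.10 * min(h, w), 0.20 * min(h, w)
    for label in range(1, n_blobs + 1):
        placed = False
        for _ in range(200):
            a, b = rng.uniform(lo, hi, size=2)
            margin = max(a, b) + 3
            if 2 * margin >= min(h, w):
                continue
            center = rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)
            theta = rng.uniform(0, np.pi)
            blob = _draw_ellipse((h, w), center, (a, b), theta)
            if not blob.any() or (blob & occupied).any():
                continue
            gt[blob] = label
            occupied |= ndimage.binary_dilation(blob, iterations=2)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place blob {label}: spec {spec.shape} with "
                f"{n_blobs} blobs is infeasible"
            )
    levels = np.asarray(spec.intensity_levels, dtype=np.float64)
    image = levels[gt]
    if spec.edge_blur_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.edge_blur_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, gt, gt > 0


def make_grid_phantom(shape: tuple[int, int], cell: int, intensities=(80.0, 180.0)):
    """Checkerboard phantom with one ground-truth label per cell.

    Cells alternate between two intensity levels so every cell border is a
    true intensity edge; ``cell`` must divide both dimensions. Used for
    boundary-metric and seed-recovery oracle tests.

    Returns ``(image uint8, gt_labels int32)``; labels are row-major cell
    indices.
    """
    h, w = shape
    if cell <= 0 or h % cell or w % cell:
        raise ValueError(f"cell size {cell} must divide shape {shape}")
    ci = np.arange(h) // cell
    cj = np.arange(w) // cell
    labels = (ci[:, None] * (w // cell) + cj[None, :]).astype(np.int32)
    parity = (ci[:, None] + cj[None, :]) % 2
    image = np.where(parity == 0, intensities[0], intensities[1]).astype(np.uint8)
    return image, labels
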