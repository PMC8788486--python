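"""Input checking shared across the package."""

from __future__ import annotations

import numpy as np

#: Sentinel for pixels not yet assigned to any superpixel.
UNLABELED = -1

# Rec. 601 luma weights, used to collapse RGB(A) input to one channel.
_LUMA = np.array([0.299, 0.587, 0.114])


def as_gray_image(image) -> np.ndarray:
    """Coerce input to a validated 2-D float64 grayscale image in [0, 255].

    Accepts 2-D arrays directly and RGB(A) arrays, which are collapsed to
    luminance. Raises ``ValueError`` for degenerate shapes or out-of-range
    intensities.
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"image must be at least 2x2, got shape {arr.shape}")
    arr = arr.astype(np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite values")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]; rescale 16-bit input first")
    return arr


def check_connectivity(connectivity: int) -> int:
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity!r}")
    return int(connectivity)


def check_same_shape(a, b, what: str = "arrays") -> None:
    if np.shape(a) != np.shape(b):
        raise ValueError(f"{what} must have equal shapes: {np.shape(a)} vs {np.shape(b)}")
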