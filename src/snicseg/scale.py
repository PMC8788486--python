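"""Scale transform: 2x decimation and nearest-neighbour label restoration.

Segmentation cost scales with pixel count, so the pipeline deletes every odd
row and column (keeping 0-based even indices), segments the quarter-size
image, and maps the label image back by assigning each original pixel the
label of its nearest retained pixel. For this decimation pattern the nearest
retained pixel is simply ``(i // 2, j // 2)``, so restoration is an exact
closed-form index map with no search structure and no possible ties.
"""

from __future__ import annotations

import numpy as np


def downscale(arr) -> np.ndarray:
    """Keep even-indexed rows and columns of a 2-D array.

    Output shape is ``(ceil(h/2), ceil(w/2))``; for even dimensions exactly
    one quarter of the pixels survive. No interpolation or smoothing is
    applied — this is pure pixel deletion.
    """
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {a.shape}")
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError(f"cannot downscale a degenerate dimension: shape {a.shape}")
    return a[::2, ::2]


def downscaled_shape(shape: tuple[int, int]) -> tuple[int, int]:
    h, w = shape
    return ((h + 1) // 2, (w + 1) // 2)


def upscale_labels(small, target_shape: tuple[int, int]) -> np.ndarray:
    """Restore a decimated label image to ``target_shape``.

    Each pixel ``(i, j)`` of the output receives ``small[i // 2, j // 2]``,
    the label of its nearest retained pixel. Restricting the result to even
    rows/columns reproduces ``small`` exactly, so coarse and restored
    segmentations are consistent by construction.
    """
    small = np.asarray(small)
    if small.ndim != 2:
        raise ValueError(f"expected a 2-D label array, got shape {small.shape}")
    h, w = target_shape
    if small.shape != downscaled_shape((h, w)):
        raise ValueError(
            f"label shape {small.shape} does not match downscale of {target_shape}"
        )
    return small[np.arange(h) // 2][:, np.arange(w) // 2]
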