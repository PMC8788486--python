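"""Local binary pattern (LBP) texture maps.

The basic 8-neighbour LBP thresholds each pixel's ring of neighbours against
the centre intensity and packs the comparison bits into an 8-bit code. The
code is invariant to additive intensity shifts (and to any monotone gain,
barring clipping), which is what makes it useful as a texture channel for CT
slices whose absolute gray levels vary between scans.
"""

from __future__ import annotations

import numpy as np

from ._validation import as_gray_image

#: Bit-position -> neighbour offset. P runs clockwise from the top-left
#: neighbour; bit P carries weight 2**P. Any fixed order is internally
#: consistent because only absolute code differences enter the clustering
#: distance, but it is pinned here so code values are reproducible.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def lbp_map(image) -> np.ndarray:
    """Compute the per-pixel 8-neighbour LBP code image.

    A neighbour contributes a 1-bit when its intensity is greater than or
    *equal* to the centre (ties count as 1), so a constant image maps to
    all-255 codes and a strict local maximum maps to 0. Borders are handled
    by edge replication so the output covers every pixel.

    Parameters
    ----------
    image : array-like
        2-D grayscale image with intensities in [0, 255].

    Returns
    -------
    ndarray of uint8
        LBP code per pixel, same shape as ``image``.
    """
    img = as_gray_image(image)
    padded = np.pad(img, 1, mode="edge")
    h, w = img.shape
    codes = np.zeros((h, w), dtype=np.uint8)
    for p, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        nbr = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        codes |= (nbr >= img).astype(np.uint8) << p
    return codes
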