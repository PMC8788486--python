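"""Segmentation quality metrics.

Two families are provided. Boundary-based scores compare a segmentation's
boundary image B against a reference boundary image G with a pixel tolerance
d (Chebyshev neighbourhoods, default d = 2):

* boundary recall        BR  = TP / (TP + FN)
* under-segmentation err USE = FP / (TP + FP)
* achievable seg. acc.   ASA = TP / sum(G_i)

All three are computed on boundary pixels. With sum(G_i) read as the count
of reference boundary pixels, ASA coincides numerically with BR; both are
exposed for fidelity to the definitions.

Region-based scores compare binary masks (after majority-vote conversion of
superpixels against the reference mask):

* Dice    = 2|SEG ∩ GT| / (|SEG| + |GT|)
* Jaccard = |SEG ∩ GT| / |SEG ∪ GT|
* CCR     = (pixels whose class matches GT, both classes) / N
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from ._validation import check_same_shape

__all__ = [
    "MatchCounts",
    "MetricsReport",
    "UndefinedMetricError",
    "boundary_map",
    "match_counts",
    "boundary_recall",
    "under_segmentation_error",
    "achievable_segmentation_accuracy",
    "superpixels_to_mask",
    "dice",
    "jaccard",
    "ccr",
    "evaluate",
]


class UndefinedMetricError(ValueError):
    """Raised when a ratio metric has an empty denominator."""


@dataclass(frozen=True)
class MatchCounts:
    """Boundary-pixel match counts at tolerance ``d`` (Chebyshev distance)."""

    tp: int
    fn: int
    fp: int
    d: int


@dataclass(frozen=True)
class MetricsReport:
    """The six evaluation coefficients for one (segmentation, reference) pair."""

    br: float
    use: float
    asa: float
    dice: float
    jaccard: float
    ccr: float

    def to_row(self, **keys) -> dict:
        """Flatten to a dict suitable for one CSV/DataFrame row."""
        return {**keys, **asdict(self)}


def boundary_map(labels) -> np.ndarray:
    """Binary boundary image: pixels with any 4-neighbour of another label."""
    lab = np.asarray(labels)
    if lab.ndim != 2:
        raise ValueError(f"expected a 2-D label array, got shape {lab.shape}")
    b = np.zeros(lab.shape, dtype=bool)
    dif = lab[:-1, :] != lab[1:, :]
    b[:-1, :] |= dif
    b[1:, :] |= dif
    dif = lab[:, :-1] != lab[:, 1:]
    b[:, :-1] |= dif
    b[:, 1:] |= dif
    return b


def _chebyshev_dilate(mask: np.ndarray, d: int) -> np.ndarray:
    if d == 0:
        return mask
    return ndimage.maximum_filter(mask, size=2 * d + 1, mode="constant")


def match_counts(B, G, d: int = 2) -> MatchCounts:
    """Count boundary matches between algorithm boundary B and reference G.

    TP: G pixels with some B pixel within Chebyshev distance d. FN: G pixels
    with none. FP: B pixels with no G pixel within d.
    """
    B = np.asarray(B).astype(bool)
    G = np.asarray(G).astype(bool)
    check_same_shape(B, G, "boundary images")
    if d < 0:
        raise ValueError(f"tolerance d must be >= 0, got {d}")
    b_near = _chebyshev_dilate(B, d)
    g_near = _chebyshev_dilate(G, d)
    tp = int(np.count_nonzero(G & b_near))
    fn = int(np.count_nonzero(G & ~b_near))
    fp = int(np.count_nonzero(B & ~g_near))
    return MatchCounts(tp=tp, fn=fn, fp=fp, d=int(d))


def boundary_recall(counts: MatchCounts) -> float:
    """Fraction of reference boundary pixels recovered within tolerance."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise UndefinedMetricError("boundary recall undefined: empty reference boundary")
    return counts.tp / denom


def under_segmentation_error(counts: MatchCounts) -> float:
    """Fraction of algorithm boundary pixels leaking outside the reference."""
    denom = counts.tp + counts.fp
    if denom == 0:
        raise UndefinedMetricError("USE undefined: no true or false boundary positives")
    return counts.fp / denom


def achievable_segmentation_accuracy(counts: MatchCounts, G) -> float:
    """TP over the total count of reference boundary pixels."""
    g_total = int(np.count_nonzero(np.asarray(G).astype(bool)))
    if g_total == 0:
        raise UndefinedMetricError("ASA undefined: empty reference boundary")
    return counts.tp / g_total


def superpixels_to_mask(labels, gt_mask) -> np.ndarray:
    """Binarise a superpixel segmentation by majority vote against a mask.

    A superpixel becomes foreground iff strictly more than half of its
    pixels are foreground in ``gt_mask``; exact ties go to background. This
    is the standard conversion for scoring an over-segmentation against a
    single-object reference mask.
    """
    lab = np.asarray(labels)
    gt = np.asarray(gt_mask).astype(bool)
    check_same_shape(lab, gt, "labels and mask")
    flat = lab.ravel()
    if flat.min() < 0:
        raise ValueError("label map contains unlabeled pixels")
    fg = np.bincount(flat, weights=gt.ravel().astype(np.float64))
    tot = np.bincount(flat)
    fg_labels = fg * 2 > tot
    return fg_labels[lab]


def dice(seg, gt) -> float:
    """Dice overlap 2|SEG∩GT| / (|SEG|+|GT|) of two binary masks."""
    seg = np.asarray(seg).astype(bool)
    gt = np.asarray(gt).astype(bool)
    check_same_shape(seg, gt, "masks")
    denom = int(seg.sum()) + int(gt.sum())
    if denom == 0:
        raise UndefinedMetricError("Dice undefined: both masks empty")
    return 2 * int((seg & gt).sum()) / denom


def jaccard(seg, gt) -> float:
    """Jaccard overlap |SEG∩GT| / |SEG∪GT| of two binary masks."""
    seg = np.asarray(seg).astype(bool)
    gt = np.asarray(gt).astype(bool)
    check_same_shape(seg, gt, "masks")
    union = int((seg | gt).sum())
    if union == 0:
        raise UndefinedMetricError("Jaccard undefined: both masks empty")
    return int((seg & gt).sum()) / union


def ccr(seg, gt) -> float:
    """Correct classification ratio: whole-image pixelwise agreement."""
    seg = np.asarray(seg).astype(bool)
    gt = np.asarray(gt).astype(bool)
    check_same_shape(seg, gt, "masks")
    return int((seg == gt).sum()) / seg.size


def evaluate(labels, gt_labels=None, gt_mask=None, d: int = 2) -> MetricsReport:
    """Compute the full six-coefficient report for one segmentation.

    Boundary scores need a reference label image (``gt_labels``); region
    scores need a reference binary mask (``gt_mask``). When only a mask is
    given its own boundary serves as the boundary reference; at least one of
    the two references is required.
    """
    if gt_labels is None and gt_mask is None:
        raise ValueError("need gt_labels and/or gt_mask to evaluate")
    if gt_labels is None:
        gt_labels = np.asarray(gt_mask).astype(np.int32)
    if gt_mask is None:
        gt_mask = np.asarray(gt_labels) > 0
    B = boundary_map(labels)
    G = boundary_map(gt_labels)
    counts = match_counts(B, G, d)
    seg_mask = superpixels_to_mask(labels, gt_mask)
    return MetricsReport(
        br=boundary_recall(counts),
        use=under_segmentation_error(counts),
        asa=achievable_segmentation_accuracy(counts, G),
        dice=dice(seg_mask, gt_mask),
        jaccard=jaccard(seg_mask, gt_mask),
        ccr=ccr(seg_mask, gt_mask),
    )
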