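"""End-to-end file pipeline: read image, segment, restore, evaluate, write.

This layer owns disk formats and logging; all numerics live in the
estimators. Inputs are 8-bit PNG/TIFF grayscale slices (16-bit input is
linearly rescaled to [0, 255]; RGB is collapsed to luminance); outputs are a
label TIFF, a boundary-overlay PNG and a metrics CSV.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from ._validation import as_gray_image
from .estimators import SNICPipeline
from .metrics import MetricsReport, boundary_map, evaluate
from .texture import lbp_map

log = logging.getLogger("snicseg")

#: Method presets for batch evaluation. "snic" is the baseline engine
#: (fixed compactness, no texture, full resolution); "improved" enables all
#: three extensions.
METHODS = {
    "snic": dict(adaptive_compactness=False, use_texture=False, enable_downscale=False),
    "improved": dict(adaptive_compactness=True, use_texture=True, enable_downscale=True),
}

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF slice as a float grayscale image in [0, 255]."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    return as_gray_image(arr)


def save_labels(path, labels: np.ndarray) -> None:
    """Write a label image as single-channel TIFF (uint16 when it fits)."""
    lab = np.asarray(labels)
    dtype = np.uint16 if lab.max() < 2**16 else np.int32
    tifffile.imwrite(str(path), lab.astype(dtype))


def save_overlay(path, image: np.ndarray, labels: np.ndarray) -> None:
    """Write the image with superpixel boundaries painted red."""
    rgb = np.repeat(np.asarray(image, dtype=np.uint8)[..., None], 3, axis=2)
    rgb[boundary_map(labels)] = (255, 0, 0)
    iio.imwrite(Path(path), rgb)


def run_pipeline(
    image_path,
    output_dir=None,
    *,
    n_segments: int = 500,
    enable_downscale: bool = True,
    adaptive_compactness: bool = True,
    compactness: float = 20.0,
    gamma: float = 2.0,
    use_texture: bool = True,
    texture_norm: float = 255.0,
    connectivity: int = 4,
    gt_path=None,
    d: int = 2,
) -> tuple[np.ndarray, MetricsReport | None]:
    """Segment one image file; optionally score against a ground-truth file.

    Runs texture extraction, optional 2x decimation, SNIC clustering and
    label restoration; when ``output_dir`` is given, writes ``labels.tif``,
    ``overlay.png`` and (with ground truth) ``metrics.csv`` there. The
    ground-truth file is read as a label image; its foreground mask is
    ``gt > 0``. Returns the full-resolution label image and the metrics
    report (None without ground truth).
    """
    image = load_image(image_path)
    t0 = time.perf_counter()
    pipe = SNICPipeline(
        n_segments=n_segments,
        enable_downscale=enable_downscale,
        adaptive_compactness=adaptive_compactness,
        compactness=compactness,
        gamma=gamma,
        use_texture=use_texture,
        texture_norm=texture_norm,
        connectivity=connectivity,
    )
    pipe.fit(image)
    log.info(
        "segment %s shape=%s K=%d downscale=%s adaptive=%s texture=%s (%.2fs)",
        image_path, image.shape, n_segments, enable_downscale,
        adaptive_compactness, use_texture, time.perf_counter() - t0,
    )
    report = None
    if gt_path is not None:
        gt = _load_gt(gt_path)
        report = evaluate(pipe.labels_, gt_labels=gt, gt_mask=gt > 0, d=d)
        log.info("metrics %s: %s", image_path, report)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = Path(image_path).stem
        save_labels(out / f"{stem}_labels.tif", pipe.labels_)
        save_overlay(out / f"{stem}_overlay.png", np.clip(image, 0, 255), pipe.labels_)
        if report is not None:
            pd.DataFrame([report.to_row(image=stem)]).to_csv(
                out / f"{stem}_metrics.csv", index=False
            )
    return pipe.labels_, report


def _load_gt(path) -> np.ndarray:
    path = Path(path)
    try:
        arr = iio.imread(path)
    except OSError as exc:
        raise OSError(f"cannot read ground truth {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.int32)


def evaluate_batch(image_dir, gt_dir, methods=("snic", "improved"), k_list=(500,), d: int = 2) -> pd.DataFrame:
    """Score every paired (image, ground truth) file per method and K.

    Files are paired by stem; unpaired images are reported with a warning and
    skipped. Returns one row per (image, method, K) plus per-method
    mean/median aggregate rows (``image`` column ``__mean__``/``__median__``).
    """
    image_dir, gt_dir = Path(image_dir), Path(gt_dir)
    rows = []
    images = sorted(
        p for p in image_dir.iterdir()
        if p.suffix.lower() in _IMAGE_SUFFIXES and not p.stem.endswith("_gt")
    ) if image_dir.is_dir() else []
    for img_path in images:
        gt_path = next(
            (gt_dir / (img_path.stem + s) for s in _IMAGE_SUFFIXES
             if (gt_dir / (img_path.stem + s)).exists()),
            None,
        )
        if gt_path is None:
            log.warning("no ground truth for %s; skipped", img_path.name)
            continue
        for method in methods:
            preset = METHODS[method]
            for k in k_list:
                _, report = run_pipeline(
                    img_path, None, n_segments=k, gt_path=gt_path, d=d, **preset
                )
                rows.append(report.to_row(image=img_path.stem, method=method, K=k))
    df = pd.DataFrame(
        rows, columns=["image", "method", "K", "br", "use", "asa", "dice", "jaccard", "ccr"]
    )
    if not df.empty:
        metric_cols = ["br", "use", "asa", "dice", "jaccard", "ccr"]
        aggs = []
        for method, grp in df.groupby("method"):
            for name, agg in (("__mean__", grp[metric_cols].mean()),
                              ("__median__", grp[metric_cols].median())):
                aggs.append({"image": name, "method": method, "K": -1, **agg.to_dict()})
        df = pd.concat([df, pd.DataFrame(aggs)], ignore_index=True)
    return df
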