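# snicseg

Fast superpixel segmentation of grayscale slices (CT exports in PNG/TIFF are
the motivating input), built on SNIC — simple non-iterative clustering —
with three extensions: a per-superpixel **adaptive compactness parameter**
stretched by a Gamma transform, a **local-binary-pattern (LBP) texture
term** in the clustering distance, and a **downscale/segment/restore**
scheme that segments a quarter-size image and restores the label map by
nearest-neighbour lookup, cutting segmentation time by roughly two thirds.

SNIC grows K grid-seeded clusters through one global priority queue ordered
by

d(j,k) = √( (d_x/s)² + (d_c/m)² + (d_t/t)² ),  s = √(N/K)

where d_x, d_c, d_t are the spatial, intensity and LBP-code distances from
candidate pixel j to the centroid of cluster k. Each cluster adapts its own
compactness m from the mean absolute intensity deviation `dev` of its
members,

m = 255 · ((255 − dev)/255)^γ,

so homogeneous clusters stay compact (m → 255, spatial term dominates)
while clusters reaching an edge become intensity-sensitive (m drops). The
package also implements the matching evaluation suite — boundary recall,
under-segmentation error and achievable segmentation accuracy on boundary
pixels with tolerance d, plus Dice/Jaccard/CCR on masks — and seeded
phantom generators with exact ground truth, so everything is testable
without clinical data.

## Worked example

```python
import numpy as np
from snicseg import PhantomSpec, SNICPipeline, make_blob_phantom, evaluate

# 512x512 phantom: bright blob (200) on dark background (30),
# 1 px edge blur, sigma-5 Gaussian noise, exact ground truth
image, gt_labels, gt_mask = make_blob_phantom(PhantomSpec(seed=1))

pipe = SNICPipeline(n_segments=100).fit(image)   # LBP -> decimate -> SNIC -> restore
report = evaluate(pipe.labels_, gt_labels=gt_labels, gt_mask=gt_mask, d=2)
print(f"dice={report.dice:.4f} jaccard={report.jaccard:.4f} ccr={report.ccr:.4f}")
print(f"br={report.br:.4f} use={report.use:.4f}")
```

prints

```
dice=0.9889 jaccard=0.9780 ccr=0.9979
br=0.9731 use=0.9680
```

Dice/Jaccard/CCR score the majority-vote binary mask of the 100 superpixels
against the true blob mask — 0.99 Dice means the blob is recovered almost
exactly despite blur, noise and quarter-resolution clustering. Boundary
recall 0.97 says 97 % of true edge pixels lie within 2 px of a superpixel
boundary. The under-segmentation error looks alarming but is expected: it
is defined on boundary pixels, and an over-segmentation into 100 regions
has many interior boundaries that count as false positives against a single
object outline (see `docs/methods.md`).

The same estimators compose with scikit-learn (`get_params`/`set_params`/
`clone`); `snicseg.snic_segment`, `snicseg.lbp_map`, `snicseg.downscale`,
`snicseg.upscale_labels` and `snicseg.evaluate` are functional wrappers.

## Command line

```bash
snicseg synth --kind blob --seed 42 --out data/            # phantom + GT + mask
snicseg segment --input data/blob.png --output out/ --k 500 --gt data/blob_gt.tif
snicseg metrics --seg out/blob_labels.tif --gt data/blob_gt.tif --d 2
snicseg batch --images data/ --gt data/ --methods snic,improved --k-list 100,500 --out results.csv
```

`segment` writes a label TIFF, a red boundary overlay PNG and (with `--gt`)
a metrics CSV; `--no-downscale`, `--no-texture` and `--fixed-m M` switch
the three extensions off individually, reducing to baseline SNIC.

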