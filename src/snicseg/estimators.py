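"""Scikit-learn style estimators wrapping the segmentation machinery.

``SNICSuperpixels`` is a clustering estimator whose samples are the pixels
of one 2-D image: ``fit(X)`` takes the image itself and exposes the label
image as ``labels_``. ``LBPTexture`` is a stateless transformer producing
the LBP code image, and ``SNICPipeline`` chains texture extraction,
decimation, clustering and label restoration into the full fast-segmentation
procedure. All three follow the sklearn parameter contract
(``get_params``/``set_params``/``clone``-compatible ``__init__``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from ._validation import as_gray_image, check_connectivity, check_same_shape
from .scale import downscale, upscale_labels
from .snic import _run_snic, grid_interval
from .texture import lbp_map


class LBPTexture(TransformerMixin, BaseEstimator):
    """8-neighbour local binary pattern transformer.

    Stateless: ``fit`` only validates. ``transform`` maps a grayscale image
    to its uint8 LBP code image of identical shape.
    """

    def fit(self, X, y=None):
        as_gray_image(X)
        self.n_features_in_ = 8  # one comparison bit per ring neighbour
        return self

    def transform(self, X) -> np.ndarray:
        return lbp_map(X)


class SNICSuperpixels(ClusterMixin, BaseEstimator):
    """SNIC superpixel clustering of one grayscale image.

    Parameters
    ----------
    n_segments : int, default=500
        Target superpixel count K. The seed grid interval, and spatial
        distance normaliser, is ``s = sqrt(N / K)``.
    adaptive_compactness : bool, default=True
        Adapt each cluster's compactness m to its internal intensity
        homogeneity via the Gamma-stretched rule
        ``m = 255 * ((255 - mean_abs_dev) / 255) ** gamma``. When off, the
        fixed ``compactness`` is used and the estimator reduces to baseline
        SNIC (together with ``use_texture=False``).
    compactness : float, default=20.0
        Fixed intensity-distance normaliser m, used only when
        ``adaptive_compactness`` is off. Larger values weight spatial
        proximity more, yielding more regular superpixels.
    gamma : float, default=2.0
        Exponent of the Gamma stretch applied to the adaptive compactness;
        values > 1 spread the raw 200-255 band over a wider interval.
    use_texture : bool, default=True
        Include the LBP texture term in the distance. If no texture image is
        supplied to ``fit``, one is computed from ``X`` at full resolution.
    texture_norm : float, default=255.0
        Normaliser t of the texture distance term; 255 scales absolute LBP
        code differences to [0, 1] like the intensity term.
    connectivity : {4, 8}, default=4
        Pixel neighbourhood used for region growing.
    exact_deviation : bool, default=False
        Recompute each cluster's mean absolute deviation against the current
        centroid after every absorption (O(n) per pixel) instead of the O(1)
        join-time accumulation. Intended for small-image verification runs.

    Attributes
    ----------
    labels_ : ndarray of int32, shape of the fitted image
        Superpixel label per pixel, in ``[0, n_segments)``.
    superpixels_ : list of SuperpixelState
        Final per-cluster centroid, size, deviation and compactness.
    grid_interval_ : float
        The spatial normaliser s actually used.
    texture_ : ndarray or None
        The texture image used in the distance (None when texture is off).
    """

    def __init__(
        self,
        n_segments: int = 500,
        *,
        adaptive_compactness: bool = True,
        compactness: float = 20.0,
        gamma: float = 2.0,
        use_texture: bool = True,
        texture_norm: float = 255.0,
        connectivity: int = 4,
        exact_deviation: bool = False,
    ):
        self.n_segments = n_segments
        self.adaptive_compactness = adaptive_compactness
        self.compactness = compactness
        self.gamma = gamma
        self.use_texture = use_texture
        self.texture_norm = texture_norm
        self.connectivity = connectivity
        self.exact_deviation = exact_deviation

    def fit(self, X, y=None, texture=None):
        """Cluster the image ``X`` into superpixels.

        Parameters
        ----------
        X : array-like
            2-D grayscale image, intensities in [0, 255].
        texture : array-like, optional
            Precomputed texture (LBP) image of the same shape. Computed from
            ``X`` when omitted and ``use_texture`` is on.
        """
        image = as_gray_image(X)
        check_connectivity(self.connectivity)
        if not 1 <= int(self.n_segments) <= image.size:
            raise ValueError(
                f"n_segments must be in [1, {image.size}], got {self.n_segments}"
            )
        if self.use_texture:
            tex = lbp_map(image) if texture is None else np.asarray(texture)
            check_same_shape(image, tex, "image and texture map")
            tex = tex.astype(np.float64)
        else:
            tex = None
        self.labels_, self.superpixels_ = _run_snic(
            image,
            tex,
            int(self.n_segments),
            adaptive_compactness=self.adaptive_compactness,
            compactness=self.compactness,
            gamma=self.gamma,
            texture_norm=self.texture_norm,
            connectivity=self.connectivity,
            exact_deviation=self.exact_deviation,
        )
        self.texture_ = tex
        self.grid_interval_ = grid_interval(image.size, int(self.n_segments))
        return self

    def fit_predict(self, X, y=None, **fit_params) -> np.ndarray:
        """Fit and return the label image (2-D, unlike sklearn's flat labels)."""
        return self.fit(X, **fit_params).labels_


class SNICPipeline(BaseEstimator):
    """Full fast-segmentation pipeline: LBP -> decimate -> SNIC -> restore.

    The texture map is extracted at full resolution first, then both image
    and texture are decimated by deleting odd rows/columns, the quarter-size
    pair is clustered, and the coarse label image is restored to the original
    grid by nearest-retained-pixel lookup. With ``enable_downscale=False``
    the clustering runs at full resolution and restoration is the identity.

    Attributes
    ----------
    labels_ : ndarray of int32
        Label image at the original resolution.
    coarse_labels_ : ndarray of int32
        Label image at the working (possibly decimated) resolution.
    superpixels_ : list of SuperpixelState
    texture_ : ndarray or None
        Full-resolution texture map (None when texture is off).
    """

    def __init__(
        self,
        n_segments: int = 500,
        *,
        enable_downscale: bool = True,
        adaptive_compactness: bool = True,
        compactness: float = 20.0,
        gamma: float = 2.0,
        use_texture: bool = True,
        texture_norm: float = 255.0,
        connectivity: int = 4,
    ):
        self.n_segments = n_segments
        self.enable_downscale = enable_downscale
        self.adaptive_compactness = adaptive_compactness
        self.compactness = compactness
        self.gamma = gamma
        self.use_texture = use_texture
        self.texture_norm = texture_norm
        self.connectivity = connectivity

    def fit(self, X, y=None):
        image = as_gray_image(X)
        texture = lbp_map(image) if self.use_texture else None
        if self.enable_downscale:
            work_img = downscale(image)
            work_tex = downscale(texture) if texture is not None else None
        else:
            work_img, work_tex = image, texture
        est = SNICSuperpixels(
            n_segments=self.n_segments,
            adaptive_compactness=self.adaptive_compactness,
            compactness=self.compactness,
            gamma=self.gamma,
            use_texture=self.use_texture,
            texture_norm=self.texture_norm,
            connectivity=self.connectivity,
        )
        est.fit(work_img, texture=work_tex)
        self.coarse_labels_ = est.labels_
        self.superpixels_ = est.superpixels_
        self.texture_ = texture
        if self.enable_downscale:
            self.labels_ = upscale_labels(est.labels_, image.shape)
        else:
            self.labels_ = est.labels_
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
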