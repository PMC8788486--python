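"""Core clustering engine: seeding, distance, adaptive compactness, growth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snicseg import (
    SuperpixelState,
    absorb_pixel,
    cluster_distance,
    compute_adaptive_m,
    init_seeds,
    snic_segment,
)
from snicseg.snic import M_MIN

from conftest import assert_valid_partition, voronoi_partition


class TestInitSeeds:
    @pytest.mark.parametrize(
        "shape, k, expected",
        [
            ((8, 8), 4, [(2, 2), (2, 6), (6, 2), (6, 6)]),
            ((5, 5), 1, [(2, 2)]),
            ((4, 4), 16, [(r, c) for r in range(4) for c in range(4)]),
        ],
    )
    def test_grid_examples(self, shape, k, expected):
        assert init_seeds(shape, k) == expected

    @pytest.mark.parametrize("k", [0, -1, 65])
    def test_out_of_range_k(self, k):
        with pytest.raises(ValueError):
            init_seeds((8, 8), k)

    @given(
        h=st.integers(2, 40),
        w=st.integers(2, 40),
        frac=st.floats(0.01, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_exactly_k_distinct_inbounds(self, h, w, frac):
        k = max(1, int(frac * h * w))
        seeds = init_seeds((h, w), k)
        assert len(seeds) == k
        assert len(set(seeds)) == k
        assert all(0 <= r < h and 0 <= c < w for r, c in seeds)


class TestClusterDistance:
    def test_zero_for_identical(self):
        st_ = SuperpixelState(label=0, n=1, row=3, col=4, gray=100, tex=50, m=10)
        assert cluster_distance((3, 4), 100, 50, st_, s=5.0) == 0.0

    def test_three_unit_terms(self):
        # dx=5 with s=5, dc=10 with m=10, dt=20 with t=20 -> sqrt(3)
        st_ = SuperpixelState(label=0, n=1, row=0, col=0, gray=0, tex=0, m=10.0)
        d = cluster_distance((3, 4), 10, 20, st_, s=5.0, t_norm=20.0)
        assert d == pytest.approx(math.sqrt(3), abs=1e-12)

    def test_single_intensity_term_normalised(self):
        st_ = SuperpixelState(label=0, n=1, row=0, col=0, gray=0, tex=0, m=42.0)
        d = cluster_distance((0, 0), 42, 0, st_, s=5.0)
        assert d == pytest.approx(1.0)

    def test_texture_term_dropped_when_off(self):
        st_ = SuperpixelState(label=0, n=1, row=0, col=0, gray=0, tex=0, m=10.0)
        d = cluster_distance((0, 0), 0, 200, st_, s=5.0, use_texture=False)
        assert d == 0.0

    def test_nonpositive_normaliser_rejected(self):
        st_ = SuperpixelState(label=0, m=0.0)
        with pytest.raises(ValueError):
            cluster_distance((0, 0), 0, 0, st_, s=5.0)


class TestAdaptiveM:
    def test_zero_deviation_gives_max(self):
        st_ = SuperpixelState(label=0, n=4, dev=0.0)
        for gamma in (0.5, 1, 2, 5):
            assert compute_adaptive_m(st_, gamma) == 255.0

    def test_gamma_stretch_example(self):
        # mean deviation 55 -> raw 200 -> 255*(200/255)^2 ~ 156.86
        st_ = SuperpixelState(label=0, n=2, dev=110.0)
        assert compute_adaptive_m(st_, gamma=2.0) == pytest.approx(
            255 * (200 / 255) ** 2, rel=1e-9
        )
        assert st_.m == pytest.approx(156.86, abs=0.01)

    def test_full_deviation_clamps_to_floor(self):
        st_ = SuperpixelState(label=0, n=1, dev=255.0)
        assert compute_adaptive_m(st_, gamma=3.0) == M_MIN

    def test_unborn_cluster_keeps_max(self):
        st_ = SuperpixelState(label=0, n=0)
        assert compute_adaptive_m(st_, gamma=2.0) == 255.0

    def test_monotone_in_deviation(self):
        ms = []
        for dev in np.linspace(0, 255, 30):
            st_ = SuperpixelState(label=0, n=1, dev=float(dev))
            ms.append(compute_adaptive_m(st_, gamma=2.0))
        assert all(a >= b for a, b in zip(ms, ms[1:]))
        assert all(M_MIN <= m <= 255 for m in ms)


class TestAbsorbPixel:
    def test_running_mean_and_join_time_deviation(self):
        st_ = SuperpixelState(label=0)
        absorb_pixel(st_, (0, 0), 100)
        absorb_pixel(st_, (0, 1), 200)
        assert st_.n == 2
        assert st_.gray == pytest.approx(150)
        assert st_.dev == pytest.approx(100)  # |200 - 100| at join time

    def test_absorbing_centroid_value_changes_nothing(self):
        st_ = SuperpixelState(label=0)
        absorb_pixel(st_, (0, 0), 80)
        absorb_pixel(st_, (2, 0), 80)
        assert st_.gray == 80
        assert st_.dev == 0
        assert st_.row == pytest.approx(1.0)

    def test_sequential_mean(self):
        st_ = SuperpixelState(label=0)
        for i, g in enumerate((10, 20, 30)):
            absorb_pixel(st_, (0, i), g)
        assert st_.gray == pytest.approx(20)


class TestSnicSegment:
    def test_single_cluster_floods_image(self, rng):
        img = rng.integers(0, 256, (12, 9)).astype(np.uint8)
        labels, states = snic_segment(img, n_segments=1)
        assert (labels == 0).all()
        assert states[0].n == img.size

    @pytest.mark.parametrize("shape, k", [((8, 8), 4), ((16, 16), 16)])
    def test_uniform_image_matches_voronoi_oracle(self, shape, k):
        img = np.full(shape, 77, dtype=np.uint8)
        labels, _ = snic_segment(img, n_segments=k)
        assert np.array_equal(labels, voronoi_partition(shape, k))

    def test_uniform_quadrants_are_equal_blocks(self, uniform_image):
        labels, _ = snic_segment(uniform_image[:8, :8], n_segments=4)
        assert np.bincount(labels.ravel()).tolist() == [16, 16, 16, 16]

    def test_two_region_boundary_is_exact(self, step_image):
        labels, _ = snic_segment(
            step_image, n_segments=2, adaptive_compactness=False, compactness=10.0
        )
        expected = np.tile((np.arange(8) >= 4).astype(np.int32), (8, 1))
        assert np.array_equal(labels, expected)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_partition_invariants(self, rng, connectivity):
        img = rng.integers(0, 256, (20, 15)).astype(np.uint8)
        labels, _ = snic_segment(img, n_segments=12, connectivity=connectivity)
        assert_valid_partition(labels, 12, connectivity)

    def test_centroid_consistency(self, blurred_disk_image):
        labels, states = snic_segment(blurred_disk_image, n_segments=9)
        img = blurred_disk_image.astype(float)
        for st_ in states:
            member = labels == st_.label
            rr, cc = np.nonzero(member)
            assert st_.n == member.sum()
            assert st_.row == pytest.approx(rr.mean(), rel=1e-6)
            assert st_.col == pytest.approx(cc.mean(), rel=1e-6)
            assert st_.gray == pytest.approx(img[member].mean(), rel=1e-6)
            assert 0 <= st_.gray <= 255
            assert M_MIN <= st_.m <= 255

    def test_deterministic(self, blurred_disk_image):
        a, _ = snic_segment(blurred_disk_image, n_segments=10)
        b, _ = snic_segment(blurred_disk_image, n_segments=10)
        assert np.array_equal(a, b)

    def test_fixed_m_path_ignores_adaptive_parameters(self, blurred_disk_image):
        """With adaptive compactness off the gamma parameter must be inert."""
        a, _ = snic_segment(
            blurred_disk_image, n_segments=8, adaptive_compactness=False,
            compactness=15.0, gamma=0.5,
        )
        b, _ = snic_segment(
            blurred_disk_image, n_segments=8, adaptive_compactness=False,
            compactness=15.0, gamma=7.0,
        )
        assert np.array_equal(a, b)

    def test_constant_texture_map_equals_no_texture(self, blurred_disk_image):
        """A flat texture channel contributes nothing to the distance."""
        a, _ = snic_segment(blurred_disk_image, n_segments=8)
        b, _ = snic_segment(
            blurred_disk_image, np.zeros((16, 16)), n_segments=8, texture_norm=1e6
        )
        assert np.array_equal(a, b)

    def test_exact_deviation_mode_agrees_on_small_images(
        self, uniform_image, step_image, blurred_disk_image
    ):
        for img in (uniform_image, step_image, blurred_disk_image):
            fast, _ = snic_segment(img, n_segments=min(16, img.size // 4))
            slow, _ = snic_segment(
                img, n_segments=min(16, img.size // 4), exact_deviation=True
            )
            assert np.array_equal(fast, slow)

    def test_invalid_params_rejected(self, uniform_image):
        with pytest.raises(ValueError):
            snic_segment(uniform_image, n_segments=0)
        with pytest.raises(ValueError):
            snic_segment(uniform_image, n_segments=4, connectivity=6)
        with pytest.raises(ValueError):
            snic_segment(np.full((1, 5), 3), n_segments=2)
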