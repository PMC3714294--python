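import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk

import tlmquant as tq
from tlmquant.segmentation import (
    Kernel,
    SHARPEN_5X5,
    SegmentationConfig,
    auto_threshold,
    binarize,
    convolve,
    despeckle,
    label_particles,
    segment_frame,
    subtract_background,
)


class TestSubtractBackground:
    @pytest.mark.parametrize("light", [False, True])
    def test_flat_image_maps_to_zero(self, light):
        img = np.full((32, 32), 100, dtype=np.uint8)
        out = subtract_background(img, 10, light_background=light)
        assert out.dtype == np.uint8
        assert (out == 0).all()

    def test_narrow_spot_preserved_matches_opening_oracle(self):
        """A 1-px spot on flat background: the rolling-ball estimate equals
        the brute-force grayscale-opening background, so the spot survives
        and the background subtracts to ~0."""
        img = np.full((32, 32), 40, dtype=np.uint8)
        img[16, 16] = 200
        out = subtract_background(img, 8)
        oracle_bg = ndimage.grey_opening(img, footprint=disk(8))
        oracle = np.clip(img.astype(int) - oracle_bg, 0, 255)
        np.testing.assert_array_equal(out, oracle)
        assert out[16, 16] == 160
        assert out.sum() == 160  # everything else is zero

    def test_output_always_uint8_range(self, rng):
        img = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        out = subtract_background(img, 50, light_background=True)
        assert out.dtype == np.uint8  # [0, 255] by construction

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            subtract_background(np.zeros((8, 8), dtype=np.uint8), 0)


def brute_force_convolve(image, weights):
    """Nested-loop correlation with edge replication and uint8 clamping."""
    k = weights.shape[0] // 2
    padded = np.pad(image.astype(float), k, mode="edge")
    out = np.zeros_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = (padded[i : i + 2 * k + 1, j : j + 2 * k + 1] * weights).sum()
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


class TestConvolve:
    def test_identity_kernel_is_identity(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        ident = np.zeros((3, 3))
        ident[1, 1] = 1.0
        np.testing.assert_array_equal(convolve(img, Kernel(ident)), img)

    def test_normalized_mean_kernel_on_constant(self):
        img = np.full((10, 10), 77, dtype=np.uint8)
        k = Kernel(np.ones((3, 3)), normalize=True)
        np.testing.assert_array_equal(convolve(img, k), img)

    def test_sharpening_step_edge_matches_brute_force(self, rng):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:, 8:] = 120  # vertical step edge
        out = convolve(img, SHARPEN_5X5)
        oracle = brute_force_convolve(img, SHARPEN_5X5.weights())
        np.testing.assert_array_equal(out, oracle)
        assert out[:, 8:10].max() == 255  # overshoot at the bright side, clipped
        # and on a random image too
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        np.testing.assert_array_equal(
            convolve(img, SHARPEN_5X5), brute_force_convolve(img, SHARPEN_5X5.weights())
        )

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            Kernel(np.ones((4, 4)))


def intermeans_scan_oracle(image):
    """Exhaustive 0–255 scan for the lowest intermeans fixed point."""
    vals = image.ravel().astype(float)
    for t in range(256):
        below = vals[vals <= t]
        above = vals[vals > t]
        mb = below.mean() if below.size else t
        ma = above.mean() if above.size else t
        if t == round((mb + ma) / 2):
            return t
    raise AssertionError("no fixed point")


class TestAutoThreshold:
    def test_two_valued_histogram(self):
        img = np.repeat([10, 200], 128).astype(np.uint8).reshape(16, 16)
        assert auto_threshold(img) == 105

    def test_constant_image_fallback_gives_empty_mask(self):
        img = np.full((8, 8), 50, dtype=np.uint8)
        t = auto_threshold(img)
        assert t == 50
        assert (binarize(img, t, "above") == 0).all()

    def test_matches_exhaustive_scan_and_shift_equivariance(self, rng):
        for _ in range(20):
            img = rng.integers(0, 240, (24, 24)).astype(np.uint8)
            t = auto_threshold(img)
            assert t == intermeans_scan_oracle(img)
            assert auto_threshold(img + np.uint8(10)) == t + 10


class TestBinarize:
    def test_polarity_and_extremes(self, rng):
        img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        assert (binarize(img, 255, "above") == 0).all()  # strict comparison
        low = np.full((5, 5), 200, dtype=np.uint8)
        assert (binarize(low, 100, "above") == 255).all()
        mask = binarize(img, 128, "below")
        assert set(np.unique(mask)) <= {0, 255}
        np.testing.assert_array_equal(mask == 255, img < 128)


class TestDespeckle:
    def test_isolated_pixel_removed_block_preserved(self):
        m = np.zeros((11, 11), dtype=np.uint8)
        m[2, 2] = 255  # lone speckle
        m[5:10, 5:10] = 255  # solid 5x5 block
        out = despeckle(m)
        assert out[2, 2] == 0
        assert (out[6:9, 6:9] == 255).all()  # interior 3x3 intact

    def test_idempotent_on_speckle_free_masks(self):
        """Masks of solid rods (no isolated pixels) are fixed points."""
        for seed in range(5):
            p = tq.ScenarioParams.preset(
                "homogeneous", seed=seed, n_seed_cells=10, field_shape=(192, 192)
            )
            cells = tq.simulate_population(p, 0.0)
            _, _, labels = tq.render_frame(cells, p.field_shape, seed=seed)
            mask = np.where(labels > 0, 255, 0).astype(np.uint8)
            once = despeckle(mask)
            np.testing.assert_array_equal(despeckle(once), once)


class TestLabelParticles:
    def _mask(self, shape, blobs):
        m = np.zeros(shape, dtype=np.uint8)
        for (r0, r1, c0, c1) in blobs:
            m[r0:r1, c0:c1] = 255
        return m

    def test_disjoint_blobs_counted_and_ordered(self):
        m = self._mask((20, 20), [(2, 4, 2, 7), (10, 12, 10, 15)])  # two 10-px blobs
        parts = label_particles(m, min_area=5)
        assert [p.label for p in parts] == [1, 2]
        assert [p.area_px for p in parts] == [10, 10]
        assert parts[0].centroid[0] < parts[1].centroid[0]  # scan order

    def test_min_area_filters(self):
        m = self._mask((10, 10), [(1, 2, 1, 4)])  # 3-px blob
        assert label_particles(m, min_area=5) == []

    def test_touching_blobs_are_one_component(self):
        m = self._mask((10, 20), [(3, 6, 2, 9), (3, 6, 9, 16)])  # share an edge
        assert len(label_particles(m, min_area=1)) == 1

    def test_connectivity_choice(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        m[0, 0] = m[1, 1] = 255  # diagonal contact
        assert len(label_particles(m, connectivity=8)) == 1
        assert len(label_particles(m, connectivity=4)) == 2

    def test_bad_area_range_rejected(self):
        with pytest.raises(ValueError, match="min_area"):
            label_particles(np.zeros((4, 4), dtype=np.uint8), min_area=10, max_area=5)


class TestSegmentFrame:
    def test_recovers_separated_rods(self, small_params):
        cells = tq.simulate_population(small_params, 0.0)
        phase, _, labels = tq.render_frame(cells, small_params.field_shape, seed=7)
        _, particles = segment_frame(phase)
        n_truth, matched, fp = tq.synthetic.match_to_truth(labels, particles)
        assert n_truth == len(cells)
        assert matched >= n_truth - 1
        assert fp == 0

    def test_blank_frame_yields_nothing(self):
        blank = np.full((128, 128), 180, dtype=np.uint8)
        mask, particles = segment_frame(blank)
        assert particles == []
        assert (mask == 0).all()

    def test_bitwise_deterministic(self, small_params):
        cells = tq.simulate_population(small_params, 0.0)
        phase, _, _ = tq.render_frame(cells, small_params.field_shape, seed=3)
        m1, p1 = segment_frame(phase)
        m2, p2 = segment_frame(phase)
        np.testing.assert_array_equal(m1, m2)
        assert [(p.label, p.area_px, p.centroid) for p in p1] == [
            (p.label, p.area_px, p.centroid) for p in p2
        ]

    def test_touching_pair_counts_as_one_cell(self, touching_pair, separated_pair):
        """Contacting cells merge into a single particle (no splitting is
        attempted); well-separated cells stay distinct."""
        phase, _, _ = tq.render_frame(touching_pair, (120, 120), seed=1)
        _, particles = segment_frame(phase)
        assert len(particles) == 1
        phase, _, _ = tq.render_frame(separated_pair, (120, 120), seed=1)
        _, particles = segment_frame(phase)
        assert len(particles) == 2

    def test_config_validation(self):
        with pytest.raises(ValueError, match="threshold_method"):
            SegmentationConfig(threshold_method="magic")
        with pytest.raises(ValueError, match="rolling_ball_radius"):
            SegmentationConfig(rolling_ball_radius=0)
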