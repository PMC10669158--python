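import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from leafdiffuse import (
    BinaryMask,
    DiseaseStyle,
    LeafSpec,
    default_catalogue,
    dilate_mask,
    generate_leaf,
    invert_mask,
    iou,
    leaf_mask_otsu,
    mean_iou,
    otsu_threshold,
    sample_split_mask,
)
from leafdiffuse.masks import (
    INSTANCE_MARKS_1,
    KNOWN_MARKS_1,
    ExtractionFailure,
    MaskConventionError,
    SplitMaskCatalogue,
    load_mask_png,
    save_mask_png,
)
from leafdiffuse.schedule import ConfigurationError


def brute_force_otsu(values, n_bins=256):
    """Independent oracle: naive scan of every histogram cut, recomputing the
    class weights and means from the raw counts at each candidate."""
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_sigma, best_edge = -1.0, None
    for k in range(n_bins - 1):  # cut after bin k
        n0, n1 = counts[: k + 1].sum(), counts[k + 1 :].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / n1
        sigma = (n0 / counts.sum()) * (n1 / counts.sum()) * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma, best_edge = sigma, edges[k + 1]
    return best_edge


class TestOtsu:
    def test_two_level_image_partition_exact(self):
        img = np.concatenate([np.full(40, 0.2), np.full(60, 0.8)])
        th = otsu_threshold(img)
        assert 0.2 < th < 0.8
        np.testing.assert_array_equal(img > th, img == 0.8)

    def test_swapped_proportions_same_partition(self):
        a = np.concatenate([np.full(40, 0.2), np.full(60, 0.8)])
        b = np.concatenate([np.full(60, 0.2), np.full(40, 0.8)])
        assert (a > otsu_threshold(a)).sum() == 60
        assert (b > otsu_threshold(b)).sum() == 40

    def test_bimodal_mixture_low_misclassification(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(0.25, 0.05, 5000)
        hi = rng.normal(0.75, 0.05, 5000)
        img = np.concatenate([lo, hi])
        th = otsu_threshold(img)
        mis = (lo > th).sum() + (hi <= th).sum()
        assert mis / img.size < 0.01

    def test_matches_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            mix = np.concatenate([
                rng.normal(rng.uniform(0.1, 0.4), 0.05, 500),
                rng.normal(rng.uniform(0.6, 0.9), 0.05, 500),
            ])
            th = otsu_threshold(mix, n_bins=64)
            oracle = brute_force_otsu(mix, n_bins=64)
            # same induced partition
            np.testing.assert_array_equal(mix > th, mix > oracle)

    def test_agrees_with_reference_implementation(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(2)
        img = np.concatenate([rng.normal(0.3, 0.04, 800), rng.normal(0.7, 0.06, 700)])
        ours = otsu_threshold(img)
        ref = threshold_otsu(img)
        # both pick the same histogram bin; we report its edge, skimage its
        # center, so agreement is to within one bin width
        bin_width = (img.max() - img.min()) / 256
        assert abs(ours - ref) <= bin_width

    def test_constant_image_rejected(self):
        with pytest.raises(ConfigurationError):
            otsu_threshold(np.full((4, 4), 0.5))


class TestLeafMaskOtsu:
    def test_synthetic_leaf_high_iou(self):
        img, truth = generate_leaf(LeafSpec(size=64), np.random.default_rng(3))
        pred = leaf_mask_otsu(img)
        assert iou(pred, truth) >= 0.95

    def test_uniform_image_fails_extraction(self):
        with pytest.raises((ConfigurationError, ExtractionFailure)):
            leaf_mask_otsu(np.full((16, 16, 3), 0.5))

    def test_detached_shadow_blob_removed_by_largest_component(self):
        img, truth = generate_leaf(LeafSpec(size=64), np.random.default_rng(4))
        shadowed = img.copy()
        shadowed[2:8, 2:8] = 0.25  # small dark blob away from the leaf
        pred = leaf_mask_otsu(shadowed)
        assert pred.grid[2:8, 2:8].sum() == 0
        assert iou(pred, truth) >= 0.95


class TestDilate:
    def test_radius_zero_identity(self):
        m = BinaryMask(np.eye(5, dtype=np.uint8), INSTANCE_MARKS_1)
        assert dilate_mask(m, 0) is m

    def test_single_pixel_radius_one_plus_shape(self):
        g = np.zeros((5, 5), np.uint8)
        g[2, 2] = 1
        out = dilate_mask(BinaryMask(g, INSTANCE_MARKS_1), 1)
        assert out.area() == 5
        assert out.grid[2, 2] and out.grid[1, 2] and out.grid[3, 2]
        assert out.grid[2, 1] and out.grid[2, 3]
        assert not out.grid[1, 1]

    def test_nested_monotonicity(self, rng):
        g = (rng.uniform(size=(12, 12)) < 0.2).astype(np.uint8)
        m = BinaryMask(g, INSTANCE_MARKS_1)
        prev = m
        for r in (1, 2, 3):
            cur = dilate_mask(m, r)
            assert np.all(cur.grid >= prev.grid)
            prev = cur

    def test_negative_radius_rejected(self):
        m = BinaryMask(np.ones((3, 3), np.uint8), INSTANCE_MARKS_1)
        with pytest.raises(ConfigurationError):
            dilate_mask(m, -1)


class TestInvert:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**16 - 1))
    def test_involution_including_tag(self, bits):
        g = np.array([(bits >> i) & 1 for i in range(16)], np.uint8).reshape(4, 4)
        m = BinaryMask(g, INSTANCE_MARKS_1)
        back = invert_mask(invert_mask(m))
        np.testing.assert_array_equal(back.grid, m.grid)
        assert back.convention == m.convention

    def test_full_instance_mask_is_ghost_leaf_configuration(self):
        m = BinaryMask(np.ones((4, 4), np.uint8), INSTANCE_MARKS_1)
        inv = invert_mask(m)
        assert inv.convention == KNOWN_MARKS_1
        assert inv.area() == 0

    def test_area_partition(self, rng):
        g = (rng.uniform(size=(8, 8)) < 0.5).astype(np.uint8)
        m = BinaryMask(g, INSTANCE_MARKS_1)
        assert m.area() + invert_mask(m).area() == g.size


class TestSplitMasks:
    def test_default_catalogue_structure(self):
        cat = default_catalogue((16, 16))
        assert len(cat) == 10
        for i in range(len(cat)):
            m = cat.mask(i)
            assert 0 < m.area() < m.grid.size
        # complement pairs present: left/right, top/bottom, center/border
        names = cat.names
        assert "left-half" in names and "right-half" in names
        assert "center-window" in names and "border-band" in names

    def test_singleton_catalogue_always_sampled(self, rng):
        cat = default_catalogue((8, 8))
        single = SplitMaskCatalogue(cat.names[:1], cat.grids[:1])
        for _ in range(10):
            m = sample_split_mask((8, 8), single, rng)
            np.testing.assert_array_equal(m.grid, cat.grids[0])

    def test_frequencies_uniform_within_binomial_error(self):
        rng = np.random.default_rng(5)
        cat = default_catalogue((8, 8))
        draws = 8000
        counts = np.zeros(len(cat))
        for _ in range(draws):
            m = sample_split_mask((8, 8), cat, rng)
            idx = next(
                i for i in range(len(cat)) if np.array_equal(m.grid, cat.grids[i])
            )
            counts[idx] += 1
        expected = draws / len(cat)
        sigma = np.sqrt(draws * (1 / len(cat)) * (1 - 1 / len(cat)))
        assert np.all(np.abs(counts - expected) < 4 * sigma)

    def test_chi_square_uniformity_not_rejected(self):
        rng = np.random.default_rng(6)
        cat = default_catalogue((8, 8))
        counts = np.zeros(len(cat))
        for _ in range(10_000):
            m = sample_split_mask((8, 8), cat, rng)
            idx = next(
                i for i in range(len(cat)) if np.array_equal(m.grid, cat.grids[i])
            )
            counts[idx] += 1
        assert stats.chisquare(counts).pvalue >= 0.01

    def test_catalogue_coverage_is_left_right_and_top_bottom_balanced(self):
        cat = default_catalogue((16, 16))
        coverage = np.mean([1 - g for g in cat.grids], axis=0)  # unknown frequency
        np.testing.assert_allclose(coverage, coverage[:, ::-1])
        np.testing.assert_allclose(coverage, coverage[::-1, :])

    def test_seeded_reproducibility(self):
        cat = default_catalogue((8, 8))
        a = sample_split_mask((8, 8), cat, np.random.default_rng(9))
        b = sample_split_mask((8, 8), cat, np.random.default_rng(9))
        np.testing.assert_array_equal(a.grid, b.grid)


class TestIoU:
    def test_identical_masks(self):
        m = BinaryMask(np.eye(4, dtype=np.uint8), INSTANCE_MARKS_1)
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = BinaryMask(np.eye(4, dtype=np.uint8), INSTANCE_MARKS_1)
        b = invert_mask(invert_mask(a))
        c = BinaryMask(1 - np.eye(4, dtype=np.uint8), INSTANCE_MARKS_1)
        assert iou(a, c) == 0.0
        assert iou(a, b) == 1.0

    def test_hand_counted_three_by_three(self):
        pred = BinaryMask(
            np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]], np.uint8), INSTANCE_MARKS_1
        )
        truth = BinaryMask(
            np.array([[1, 1, 1], [0, 1, 1], [0, 1, 0]], np.uint8), INSTANCE_MARKS_1
        )
        assert iou(pred, truth) == pytest.approx(3 / 7)

    def test_both_empty_counts_as_agreement(self):
        z = BinaryMask(np.zeros((3, 3), np.uint8), INSTANCE_MARKS_1)
        assert iou(z, z) == 1.0

    def test_convention_mismatch_rejected(self):
        a = BinaryMask(np.eye(3, dtype=np.uint8), INSTANCE_MARKS_1)
        b = BinaryMask(np.eye(3, dtype=np.uint8), KNOWN_MARKS_1)
        with pytest.raises(MaskConventionError):
            iou(a, b)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**9 - 1), st.integers(0, 2**9 - 1))
    def test_symmetry_and_range(self, p_bits, t_bits):
        mk = lambda bits: BinaryMask(
            np.array([(bits >> i) & 1 for i in range(9)], np.uint8).reshape(3, 3),
            INSTANCE_MARKS_1,
        )
        a, b = mk(p_bits), mk(t_bits)
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == iou(b, a)
        assert (v == 1.0) == np.array_equal(a.grid, b.grid)

    def test_mean_iou(self):
        m1 = BinaryMask(np.eye(3, dtype=np.uint8), INSTANCE_MARKS_1)
        m0 = BinaryMask(1 - np.eye(3, dtype=np.uint8), INSTANCE_MARKS_1)
        assert mean_iou([(m1, m1), (m1, m0)]) == pytest.approx(0.5)


class TestMaskIO:
    def test_png_round_trip_with_sidecar(self, tmp_path, rng):
        g = (rng.uniform(size=(8, 8)) < 0.5).astype(np.uint8)
        m = BinaryMask(g, KNOWN_MARKS_1)
        save_mask_png(m, tmp_path / "m.png", provenance="test")
        back = load_mask_png(tmp_path / "m.png")
        np.testing.assert_array_equal(back.grid, g)
        assert back.convention == KNOWN_MARKS_1
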