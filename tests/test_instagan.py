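import numpy as np
import pytest

from leafdiffuse.instagan import (
    FeatureEncoders,
    IdentityGenerator,
    InstancePair,
    LossReport,
    LossWeights,
    TinyConvEncoder,
    TinyDiscriminator,
    TinyTranslator,
    TranslationResult,
    background_weight,
    compute_losses,
    context_loss,
    cycle_loss,
    encode_discriminator_context,
    encode_generator_context,
    encode_instance_context,
    identity_loss,
    lsgan_generator_loss,
    lsgan_loss,
    sequential_minibatch_loss,
    total_loss,
)
from leafdiffuse.masks import INSTANCE_MARKS_1, BinaryMask


def imask(grid):
    return BinaryMask(np.asarray(grid, dtype=np.uint8), INSTANCE_MARKS_1)


@pytest.fixture
def linear_encoders():
    w = np.arange(16, dtype=float).reshape(4, 4)
    f_img = lambda x: np.array([np.asarray(x).sum()])
    f_mask = lambda m: np.array([m.sum(), (m * w).sum()])
    return FeatureEncoders(f_GX=f_img, f_GA=f_mask, f_DX=f_img, f_DA=f_mask)


@pytest.fixture
def pair(rng):
    a = imask(rng.integers(0, 2, (4, 4)))
    b = imask(rng.integers(0, 2, (4, 4)))
    return InstancePair(
        x=rng.uniform(0, 1, (4, 4, 3)), a=[a, imask(np.eye(4))],
        y=rng.uniform(0, 1, (4, 4, 3)), b=[b, imask(1 - np.eye(4))],
    )


class TestEncodings:
    def test_permutation_invariance(self, pair, linear_encoders):
        fwd = encode_generator_context(pair.x, pair.a, linear_encoders)
        rev = encode_generator_context(pair.x, pair.a[::-1], linear_encoders)
        np.testing.assert_array_equal(fwd, rev)
        fwd_d = encode_discriminator_context(pair.x, pair.a, linear_encoders)
        rev_d = encode_discriminator_context(pair.x, pair.a[::-1], linear_encoders)
        np.testing.assert_array_equal(fwd_d, rev_d)

    def test_single_instance_encoding_appends_its_feature(self, pair, linear_encoders):
        a1 = pair.a[:1]
        joint = encode_generator_context(pair.x, a1, linear_encoders)
        per = encode_instance_context(pair.x, a1, 0, linear_encoders)
        np.testing.assert_array_equal(per[: joint.size], joint)
        np.testing.assert_array_equal(
            per[joint.size :], linear_encoders.f_GA(a1[0].as_float())
        )

    def test_linear_encoder_sums_instances(self, pair, linear_encoders):
        out = encode_generator_context(pair.x, pair.a, linear_encoders)
        expected = linear_encoders.f_GA(pair.a[0].as_float()) + linear_encoders.f_GA(
            pair.a[1].as_float()
        )
        np.testing.assert_allclose(out[1:], expected)

    def test_duplicated_mask_doubles_summed_term(self, pair, linear_encoders):
        one = encode_discriminator_context(pair.x, pair.a[:1], linear_encoders)
        two = encode_discriminator_context(pair.x, pair.a[:1] * 2, linear_encoders)
        np.testing.assert_allclose(two[1:], 2 * one[1:])

    def test_zero_encoder_pads_with_zeros(self, pair):
        enc = FeatureEncoders(
            f_GX=lambda x: np.ones(3), f_GA=lambda m: np.zeros(2),
            f_DX=lambda x: np.ones(3), f_DA=lambda m: np.zeros(2),
        )
        out = encode_discriminator_context(pair.x, pair.a, enc)
        np.testing.assert_array_equal(out, [1, 1, 1, 0, 0])

    def test_empty_mask_list_rejected(self, pair, linear_encoders):
        with pytest.raises(ValueError):
            encode_generator_context(pair.x, [], linear_encoders)


class TestLSGAN:
    def test_perfect_discriminator_zero_loss(self):
        assert lsgan_loss(np.ones(4), np.zeros(4)) == 0.0

    def test_maximally_confused_scores(self):
        assert lsgan_loss(np.zeros(3), np.ones(3)) == pytest.approx(2.0)

    def test_half_scores_quarter_terms(self):
        assert lsgan_loss(np.full(2, 0.5), np.full(2, 0.5)) == pytest.approx(0.5)

    def test_generator_form_targets_one(self):
        assert lsgan_generator_loss(np.ones(3)) == 0.0
        assert lsgan_generator_loss(np.zeros(3)) == pytest.approx(1.0)


class TestContentLosses:
    def test_identity_generators_zero_everything(self, pair):
        g = IdentityGenerator()
        assert cycle_loss(pair, g, g) == 0.0
        assert identity_loss(pair, g, g) == 0.0
        fake_y, fake_x = g(pair.x, pair.a), g(pair.y, pair.b)
        assert context_loss(pair, (fake_y, fake_x)) == 0.0

    def test_cycle_shift_closed_form(self, pair):
        shift = lambda img, masks: TranslationResult(np.asarray(img) + 0.05, list(masks))
        loss = cycle_loss(pair, shift, shift)
        # each direction round-trips with +0.1 on every image element
        assert loss == pytest.approx(0.1 * pair.x.size + 0.1 * pair.y.size)

    def test_identity_constant_generator_closed_form(self):
        a = [imask(np.ones((2, 2)))]
        pair = InstancePair(
            x=np.full((2, 2, 3), 0.7), a=a, y=np.full((2, 2, 3), 0.7), b=a
        )
        const = lambda img, masks: TranslationResult(np.full_like(np.asarray(img), 0.5), list(masks))
        # 0.2 per element, both directions
        assert identity_loss(pair, const, const) == pytest.approx(0.2 * 12 * 2)

    def test_context_ignores_instance_pixels(self, pair):
        def translate_inside(img, masks):
            out = np.asarray(img).copy()
            union = np.max([m.as_float() for m in masks], axis=0).astype(bool)
            out[union] += 0.3
            return TranslationResult(out, list(masks))

        fake_y = translate_inside(pair.x, pair.a)
        fake_x = translate_inside(pair.y, pair.b)
        assert context_loss(pair, (fake_y, fake_x)) == pytest.approx(0.0)

    def test_context_background_shift_closed_form(self, pair):
        shift = lambda img, masks: TranslationResult(np.asarray(img) + 0.2, list(masks))
        fake_y, fake_x = shift(pair.x, pair.a), shift(pair.y, pair.b)
        k_x = background_weight(pair.a, fake_y.masks).sum()
        k_y = background_weight(pair.b, fake_x.masks).sum()
        assert context_loss(pair, (fake_y, fake_x)) == pytest.approx(
            0.2 * 3 * (k_x + k_y)
        )

    def test_full_image_mask_makes_context_vanish(self):
        full = [imask(np.ones((3, 3)))]
        pair = InstancePair(
            x=np.zeros((3, 3, 3)), a=full, y=np.ones((3, 3, 3)), b=full
        )
        anything = lambda img, masks: TranslationResult(np.asarray(img) + 5.0, list(masks))
        fake_y, fake_x = anything(pair.x, pair.a), anything(pair.y, pair.b)
        assert context_loss(pair, (fake_y, fake_x)) == 0.0


class TestTotalLoss:
    def test_all_zero_parts(self):
        rep = total_loss(LossReport(0, 0, 0, 0), LossWeights(10, 10, 10))
        assert rep.total == 0.0

    def test_unit_parts_arithmetic(self):
        rep = total_loss(LossReport(1, 1, 1, 1), LossWeights(10, 10, 10))
        assert rep.total == pytest.approx(31.0)

    def test_zero_weights_leave_adversarial_term(self):
        rep = total_loss(LossReport(2.5, 9, 9, 9), LossWeights(0, 0, 0))
        assert rep.total == pytest.approx(2.5)

    def test_linear_in_each_weight(self):
        parts = LossReport(1.0, 2.0, 3.0, 4.0)
        base = total_loss(parts, LossWeights(1, 1, 1)).total
        bumped = total_loss(parts, LossWeights(2, 1, 1)).total
        assert bumped - base == pytest.approx(parts.cycle)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-1, 0, 0)


class TestSequentialMinibatch:
    def test_single_group_reduces_to_combined_loss(self, pair):
        g_xy, g_yx = TinyTranslator(seed=1), TinyTranslator(seed=2)
        d_x, d_y = TinyDiscriminator(seed=3), TinyDiscriminator(seed=4)
        w = LossWeights(10, 10, 10)
        seq = sequential_minibatch_loss(pair, 1, g_xy, g_yx, d_x, d_y, w)
        combined = compute_losses(pair, g_xy, g_yx, d_x, d_y, w).total
        assert seq == pytest.approx(combined, abs=1e-12)

    def test_two_groups_identity_generators_hand_expansion(self, pair):
        from leafdiffuse.instagan import TranslationResult, lsgan_pair_loss

        g = IdentityGenerator()
        d_x, d_y = TinyDiscriminator(seed=3), TinyDiscriminator(seed=4)
        w = LossWeights(10, 10, 10)
        seq = sequential_minibatch_loss(pair, 2, g, g, d_x, d_y, w)
        # content terms vanish; adversarial terms accumulate translated masks
        expected = lsgan_pair_loss(
            pair,
            TranslationResult(pair.y, pair.b[:1]),
            TranslationResult(pair.x, pair.a[:1]),
            d_x, d_y,
        ) + lsgan_pair_loss(
            pair,
            TranslationResult(pair.y, pair.b),
            TranslationResult(pair.x, pair.a),
            d_x, d_y,
        )
        assert seq == pytest.approx(expected, abs=1e-12)

    def test_group_count_exceeding_instances_rejected(self, pair):
        g = IdentityGenerator()
        d = TinyDiscriminator()
        with pytest.raises(ValueError):
            sequential_minibatch_loss(pair, 3, g, g, d, d)

    def test_permuting_within_group_leaves_loss_unchanged(self, rng):
        masks_a = [imask(rng.integers(0, 2, (4, 4))) for _ in range(4)]
        masks_b = [imask(rng.integers(0, 2, (4, 4))) for _ in range(4)]
        x, y = rng.uniform(0, 1, (4, 4, 3)), rng.uniform(0, 1, (4, 4, 3))
        g = IdentityGenerator()
        d_x, d_y = TinyDiscriminator(seed=3), TinyDiscriminator(seed=4)
        p1 = InstancePair(x, masks_a, y, masks_b)
        # swap the two members of the first group (groups of 2)
        p2 = InstancePair(x, [masks_a[1], masks_a[0]] + masks_a[2:],
                          y, [masks_b[1], masks_b[0]] + masks_b[2:])
        l1 = sequential_minibatch_loss(p1, 2, g, g, d_x, d_y)
        l2 = sequential_minibatch_loss(p2, 2, g, g, d_x, d_y)
        assert l1 == pytest.approx(l2, rel=1e-12)


class TestTinyNetworks:
    def test_losses_finite_and_nonnegative_with_tiny_nets(self, pair):
        g_xy, g_yx = TinyTranslator(seed=5), TinyTranslator(seed=6)
        d_x, d_y = TinyDiscriminator(seed=7), TinyDiscriminator(seed=8)
        rep = compute_losses(pair, g_xy, g_yx, d_x, d_y)
        for v in rep.as_dict().values():
            assert np.isfinite(v) and v >= 0.0

    def test_encoder_deterministic_and_channel_checked(self, rng):
        enc = TinyConvEncoder(in_channels=3, d=8, seed=0)
        x = rng.uniform(0, 1, (6, 6, 3))
        np.testing.assert_array_equal(enc(x), enc(x))
        with pytest.raises(ValueError):
            enc(rng.uniform(0, 1, (6, 6, 2)))

    def test_pair_requires_instance_convention(self, rng):
        from leafdiffuse.masks import KNOWN_MARKS_1, MaskConventionError

        bad = BinaryMask(np.ones((4, 4), np.uint8), KNOWN_MARKS_1)
        with pytest.raises(MaskConventionError):
            InstancePair(rng.uniform(0, 1, (4, 4, 3)), [bad],
                         rng.uniform(0, 1, (4, 4, 3)), [bad])
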