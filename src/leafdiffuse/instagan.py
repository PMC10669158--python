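"""Instance-mask-guided translation losses (InstaGAN family).

Translation runs between a healthy-leaf domain X and a diseased-leaf
domain Y, each sample paired with a set of binary instance masks
(domains A and B).  Set-valued inputs are encoded permutation-invariantly
by summing per-mask features:

    h_G(x, a)  = [f_GX(x); sum_i f_GA(a_i)]             (generator context)
    h_Gn(x, a) = [f_GX(x); sum_i f_GA(a_i); f_GA(a_n)]  (n-th instance)
    h_D(x, a)  = [f_DX(x); sum_i f_DA(a_i)]             (discriminator)

Training combines a least-squares adversarial loss with cycle-consistency,
identity and context-preserving L1 terms,

    L = L_LSGAN + lam_cyc L_cyc + lam_idt L_idt + lam_ctx L_ctx,

and a sequential mini-batch variant translates instance subsets in M
groups, scoring the adversarial term on the cumulative translated masks.
L1 terms are plain sums of absolute differences over image and mask
elements.  The bundled reference networks are deliberately tiny (single
3x3 conv layers) so the loss surface is exercisable on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .masks import INSTANCE_MARKS_1, BinaryMask

__all__ = [
    "InstancePair",
    "TranslationResult",
    "LossWeights",
    "LossReport",
    "FeatureEncoders",
    "encode_generator_context",
    "encode_instance_context",
    "encode_discriminator_context",
    "lsgan_loss",
    "lsgan_generator_loss",
    "lsgan_pair_loss",
    "cycle_loss",
    "identity_loss",
    "context_loss",
    "background_weight",
    "total_loss",
    "compute_losses",
    "sequential_minibatch_loss",
    "IdentityGenerator",
    "TinyConvEncoder",
    "TinyTranslator",
    "TinyDiscriminator",
]


class TranslationResult(NamedTuple):
    """Output of a generator: translated image plus reconstructed masks."""

    image: np.ndarray
    masks: list[BinaryMask]


# (image, masks) -> TranslationResult
Generator = Callable[[np.ndarray, Sequence[BinaryMask]], TranslationResult]
# (image, masks) -> score array
Discriminator = Callable[[np.ndarray, Sequence[BinaryMask]], np.ndarray]


@dataclass(frozen=True)
class InstancePair:
    """A healthy-domain sample (x, a) and a diseased-domain sample (y, b)."""

    x: np.ndarray
    a: list[BinaryMask]
    y: np.ndarray
    b: list[BinaryMask]

    def __post_init__(self) -> None:
        for masks, img, name in ((self.a, self.x, "a"), (self.b, self.y, "b")):
            if len(masks) < 1:
                raise ValueError(f"mask set {name} must contain at least one mask")
            for m in masks:
                m.require(INSTANCE_MARKS_1)
                if m.shape != np.shape(img)[:2]:
                    raise ValueError(f"mask raster in {name} does not match its image")


@dataclass(frozen=True)
class LossWeights:
    """Multipliers for the cycle, identity and context terms (>= 0)."""

    lambda_cyc: float = 10.0
    lambda_idt: float = 10.0
    lambda_ctx: float = 10.0

    def __post_init__(self) -> None:
        if min(self.lambda_cyc, self.lambda_idt, self.lambda_ctx) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass(frozen=True)
class LossReport:
    lsgan: float
    cycle: float
    identity: float
    context: float
    total: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "lsgan": self.lsgan,
            "cycle": self.cycle,
            "identity": self.identity,
            "context": self.context,
            "total": self.total,
        }


@dataclass(frozen=True)
class FeatureEncoders:
    """The four feature extractors behind the set encodings."""

    f_GX: Callable[[np.ndarray], np.ndarray]
    f_GA: Callable[[np.ndarray], np.ndarray]
    f_DX: Callable[[np.ndarray], np.ndarray]
    f_DA: Callable[[np.ndarray], np.ndarray]


# ---------------------------------------------------------------------------
# set encodings


def _sum_mask_features(
    masks: Sequence[BinaryMask], f: Callable[[np.ndarray], np.ndarray]
) -> np.ndarray:
    if len(masks) == 0:
        raise ValueError("instance mask list may not be empty")
    return np.sum([f(m.as_float()) for m in masks], axis=0)


def encode_generator_context(
    x: np.ndarray, a: Sequence[BinaryMask], encoders: FeatureEncoders
) -> np.ndarray:
    """Permutation-invariant generator context [f_GX(x); sum f_GA(a_i)]."""
    return np.concatenate([encoders.f_GX(x), _sum_mask_features(a, encoders.f_GA)])


def encode_instance_context(
    x: np.ndarray, a: Sequence[BinaryMask], n: int, encoders: FeatureEncoders
) -> np.ndarray:
    """Per-instance encoding: the joint context with f_GA(a_n) appended."""
    return np.concatenate(
        [encode_generator_context(x, a, encoders), encoders.f_GA(a[n].as_float())]
    )


def encode_discriminator_context(
    x: np.ndarray, a: Sequence[BinaryMask], encoders: FeatureEncoders
) -> np.ndarray:
    """Discriminator counterpart [f_DX(x); sum f_DA(a_i)]."""
    return np.concatenate([encoders.f_DX(x), _sum_mask_features(a, encoders.f_DA)])


# ---------------------------------------------------------------------------
# losses


def lsgan_loss(d_real_out: np.ndarray, d_fake_out: np.ndarray) -> float:
    """One domain's least-squares adversarial term (discriminator form).

    Mean of (D(real) - 1)^2 plus mean of D(fake)^2; the full two-domain
    objective sums this over both discriminators (see lsgan_pair_loss).
    """
    r = np.asarray(d_real_out, dtype=np.float64)
    f = np.asarray(d_fake_out, dtype=np.float64)
    return float(np.mean((r - 1.0) ** 2) + np.mean(f**2))


def lsgan_generator_loss(d_fake_out: np.ndarray) -> float:
    """Generator-side target: mean of (D(fake) - 1)^2."""
    f = np.asarray(d_fake_out, dtype=np.float64)
    return float(np.mean((f - 1.0) ** 2))


def lsgan_pair_loss(
    pair: InstancePair,
    fake_x: TranslationResult,
    fake_y: TranslationResult,
    D_X: Discriminator,
    D_Y: Discriminator,
) -> float:
    """Two-domain LSGAN: real pairs scored toward 1, translations toward 0."""
    return lsgan_loss(D_X(pair.x, pair.a), D_X(fake_x.image, fake_x.masks)) + lsgan_loss(
        D_Y(pair.y, pair.b), D_Y(fake_y.image, fake_y.masks)
    )


def _pair_l1(
    img1: np.ndarray, masks1: Sequence[BinaryMask], img2: np.ndarray, masks2: Sequence[BinaryMask]
) -> float:
    total = float(np.abs(np.asarray(img1, float) - np.asarray(img2, float)).sum())
    for m1, m2 in zip(masks1, masks2):
        total += float(np.abs(m1.as_float() - m2.as_float()).sum())
    return total


def cycle_loss(pair: InstancePair, G_XY: Generator, G_YX: Generator) -> float:
    """L1 between round-tripped (image, masks) and the originals, both ways."""
    fwd = G_XY(pair.x, pair.a)
    back = G_YX(fwd.image, fwd.masks)
    loss = _pair_l1(back.image, back.masks, pair.x, pair.a)
    fwd2 = G_YX(pair.y, pair.b)
    back2 = G_XY(fwd2.image, fwd2.masks)
    loss += _pair_l1(back2.image, back2.masks, pair.y, pair.b)
    return loss


def identity_loss(pair: InstancePair, G_XY: Generator, G_YX: Generator) -> float:
    """L1 between each generator applied to its *target* domain and that input."""
    idt_y = G_XY(pair.y, pair.b)
    idt_x = G_YX(pair.x, pair.a)
    return _pair_l1(idt_y.image, idt_y.masks, pair.y, pair.b) + _pair_l1(
        idt_x.image, idt_x.masks, pair.x, pair.a
    )


def background_weight(
    source_masks: Sequence[BinaryMask], translated_masks: Sequence[BinaryMask]
) -> np.ndarray:
    """Default context weight: 1 where every mask of both sets is background."""
    stack = [m.as_float() for m in source_masks] + [m.as_float() for m in translated_masks]
    return (np.max(stack, axis=0) == 0).astype(np.float64)


def context_loss(
    pair: InstancePair,
    translated: tuple[TranslationResult, TranslationResult],
    weight_fn: Callable[[Sequence[BinaryMask], Sequence[BinaryMask]], np.ndarray] = background_weight,
) -> float:
    """Masked L1 keeping non-instance pixels unchanged during translation.

    ``translated`` is (G_XY(x,a), G_YX(y,b)); the weight map w(a, b') is 1
    only on pixels outside all instances in both mask sets.
    """
    fake_y, fake_x = translated

    def masked(w: np.ndarray, u: np.ndarray, v: np.ndarray) -> float:
        diff = np.abs(np.asarray(u, float) - np.asarray(v, float))
        if diff.ndim == w.ndim + 1:
            w = w[..., None]
        return float((w * diff).sum())

    return masked(weight_fn(pair.a, fake_y.masks), pair.x, fake_y.image) + masked(
        weight_fn(pair.b, fake_x.masks), pair.y, fake_x.image
    )


def total_loss(parts: LossReport, weights: LossWeights) -> LossReport:
    """Weighted combination; returns the report with the total filled in."""
    total = (
        parts.lsgan
        + weights.lambda_cyc * parts.cycle
        + weights.lambda_idt * parts.identity
        + weights.lambda_ctx * parts.context
    )
    return LossReport(parts.lsgan, parts.cycle, parts.identity, parts.context, total)


def compute_losses(
    pair: InstancePair,
    G_XY: Generator,
    G_YX: Generator,
    D_X: Discriminator,
    D_Y: Discriminator,
    weights: LossWeights = LossWeights(),
) -> LossReport:
    """Evaluate every term of the combined objective for one pair."""
    fake_y = G_XY(pair.x, pair.a)
    fake_x = G_YX(pair.y, pair.b)
    parts = LossReport(
        lsgan=lsgan_pair_loss(pair, fake_x, fake_y, D_X, D_Y),
        cycle=cycle_loss(pair, G_XY, G_YX),
        identity=identity_loss(pair, G_XY, G_YX),
        context=context_loss(pair, (fake_y, fake_x)),
    )
    return total_loss(parts, weights)


def sequential_minibatch_loss(
    pair: InstancePair,
    M: int,
    G_XY: Generator,
    G_YX: Generator,
    D_X: Discriminator,
    D_Y: Discriminator,
    weights: LossWeights = LossWeights(),
) -> float:
    """Sequential mini-batch objective over M instance groups.

    Instance masks are partitioned into M contiguous groups; each group is
    translated in turn, the adversarial term is scored on the cumulative
    translated masks, and the content terms (cycle/identity/context) are
    scored on the current group.  With M = 1 this is exactly the combined
    loss.
    """
    n_inst = min(len(pair.a), len(pair.b))
    if not 1 <= M <= n_inst:
        raise ValueError(f"M={M} must be between 1 and the instance count {n_inst}")
    a_groups = [list(g) for g in np.array_split(np.array(pair.a, dtype=object), M)]
    b_groups = [list(g) for g in np.array_split(np.array(pair.b, dtype=object), M)]
    total = 0.0
    cum_b: list[BinaryMask] = []
    cum_a: list[BinaryMask] = []
    for a_m, b_m in zip(a_groups, b_groups):
        sub = InstancePair(pair.x, a_m, pair.y, b_m)
        fake_y = G_XY(pair.x, a_m)
        fake_x = G_YX(pair.y, b_m)
        cum_b = cum_b + list(fake_y.masks)
        cum_a = cum_a + list(fake_x.masks)
        total += lsgan_pair_loss(
            pair,
            TranslationResult(fake_x.image, cum_a),
            TranslationResult(fake_y.image, cum_b),
            D_X,
            D_Y,
        )
        total += (
            weights.lambda_cyc * cycle_loss(sub, G_XY, G_YX)
            + weights.lambda_idt * identity_loss(sub, G_XY, G_YX)
            + weights.lambda_ctx * context_loss(sub, (fake_y, fake_x))
        )
    return total


# ---------------------------------------------------------------------------
# tiny reference networks (forward-only, deterministic from their seed)


class IdentityGenerator:
    """Returns its input unchanged; the fixpoint of all content losses."""

    def __call__(self, image: np.ndarray, masks: Sequence[BinaryMask]) -> TranslationResult:
        return TranslationResult(np.asarray(image, float).copy(), list(masks))


def _conv3x3(img: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    # img (H, W, C), kernels (3, 3, C, K) -> valid conv (H-2, W-2, K)
    win = np.lib.stride_tricks.sliding_window_view(img, (3, 3), axis=(0, 1))
    return np.einsum("hwcij,ijck->hwk", win, kernels)


class TinyConvEncoder:
    """One 3x3 conv + ReLU + global average pool + linear projection."""

    def __init__(self, in_channels: int, d: int = 8, n_filters: int = 6, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.kernels = rng.standard_normal((3, 3, in_channels, n_filters)) * 0.3
        self.proj = rng.standard_normal((n_filters, d)) * 0.5
        self.d = d

    def __call__(self, arr: np.ndarray) -> np.ndarray:
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[..., None]
        if arr.shape[-1] != self.kernels.shape[2]:
            raise ValueError(
                f"encoder expects {self.kernels.shape[2]} channels, got {arr.shape[-1]}"
            )
        feat = np.maximum(_conv3x3(arr, self.kernels), 0.0).mean(axis=(0, 1))
        return feat @ self.proj


class TinyTranslator:
    """Residual conv perturbation; masks pass through unchanged."""

    def __init__(self, seed: int = 0, strength: float = 0.1):
        rng = np.random.default_rng(seed)
        self.kernels = rng.standard_normal((3, 3, 3, 3)) * 0.3
        self.strength = strength

    def __call__(self, image: np.ndarray, masks: Sequence[BinaryMask]) -> TranslationResult:
        img = np.asarray(image, dtype=np.float64)
        delta = np.zeros_like(img)
        delta[1:-1, 1:-1, :] = np.tanh(_conv3x3(img, self.kernels))
        out = np.clip(img + self.strength * delta, 0.0, 1.0)
        return TranslationResult(out, list(masks))


class TinyDiscriminator:
    """Scores the permutation-invariant joint encoding with a linear head."""

    def __init__(self, in_channels: int = 3, d: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoders = FeatureEncoders(
            f_GX=TinyConvEncoder(in_channels, d, seed=seed),
            f_GA=TinyConvEncoder(1, d, seed=seed + 1),
            f_DX=TinyConvEncoder(in_channels, d, seed=seed + 2),
            f_DA=TinyConvEncoder(1, d, seed=seed + 3),
        )
        self.head = rng.standard_normal(2 * d) * 0.3

    def __call__(self, image: np.ndarray, masks: Sequence[BinaryMask]) -> np.ndarray:
        h = encode_discriminator_context(image, masks, self.encoders)
        return np.atleast_1d(h @ self.head)
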