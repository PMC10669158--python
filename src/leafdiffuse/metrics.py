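"""Evaluation measures for generated imagery: PSNR, SSIM, IS, FID, KID.

Distribution-level measures (IS/FID/KID) operate on a FeatureMatrix of
embeddings produced by a pluggable extractor; the bundled default is a
deterministic seeded random-projection map so everything runs offline.
FID compares the first two moments of real and generated embeddings,

    FID = ||mu_r - mu_f||^2 + Tr(S_r + S_f - 2 (S_r S_f)^{1/2}),

with the matrix square root taken by eigendecomposition of the
symmetrized product.  KID is the unbiased squared-MMD estimate with the
degree-3 polynomial kernel k(x, y) = (x.y/d + 1)^3, averaged over seeded
subsets and reported as mean +/- std.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .schedule import ConfigurationError

__all__ = [
    "MetricReport",
    "psnr",
    "ssim_global",
    "inception_score",
    "fid",
    "fid_from_moments",
    "kid",
    "extract_features",
    "RandomProjectionExtractor",
    "IdentityExtractor",
]


@dataclass
class MetricReport:
    """Named results of an evaluation run; KID follows mean +/- std form."""

    psnr: float | None = None
    ssim: float | None = None
    is_mean: float | None = None
    is_std: float | None = None
    fid: float | None = None
    kid_mean: float | None = None
    kid_std: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def psnr(x: np.ndarray, y: np.ndarray, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio 20 log10(MAX / sqrt(MSE)) in dB.

    Identical images (MSE = 0) return the +inf sentinel.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(20.0 * np.log10(max_value / np.sqrt(mse)))


def ssim_global(
    x: np.ndarray,
    y: np.ndarray,
    c1: float | None = None,
    c2: float | None = None,
    data_range: float = 1.0,
    windowed: bool = False,
) -> float:
    """Structural similarity from whole-image statistics.

    Uses the global means, variances and covariance in the single-window
    SSIM formula; the conventional stabilizers are c1 = (0.01 L)^2 and
    c2 = (0.03 L)^2 for dynamic range L.  ``windowed=True`` switches to
    the sliding-window local mean variant instead.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if c1 is None:
        c1 = (0.01 * data_range) ** 2
    if c2 is None:
        c2 = (0.03 * data_range) ** 2
    if c1 <= 0 or c2 <= 0:
        raise ValueError("SSIM stabilizers must be positive")
    if windowed:
        from skimage.metrics import structural_similarity

        return float(
            structural_similarity(
                x, y, data_range=data_range,
                channel_axis=-1 if x.ndim == 3 else None,
            )
        )
    mu_x, mu_y = x.mean(), y.mean()
    var_x, var_y = x.var(), y.var()
    cov = float(np.mean((x - mu_x) * (y - mu_y)))
    return float(
        ((2 * mu_x * mu_y + c1) * (2 * cov + c2))
        / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


def inception_score(probs: np.ndarray, n_splits: int = 10) -> tuple[float, float]:
    """exp of the mean KL between per-sample class posteriors and the marginal.

    ``probs`` is an (n, k) matrix of class probabilities, each row summing
    to 1; the score is computed per split and reported as mean/std.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] < 1:
        raise ValueError("probs must be a nonempty (n, k) matrix")
    if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("rows must be nonnegative and sum to 1 within 1e-6")
    n = probs.shape[0]
    n_splits = min(n_splits, n)
    scores = []
    for chunk in np.array_split(probs, n_splits):
        marginal = chunk.mean(axis=0, keepdims=True)
        kl = np.sum(chunk * (np.log(chunk + 1e-16) - np.log(marginal + 1e-16)), axis=1)
        scores.append(np.exp(kl.mean()))
    return float(np.mean(scores)), float(np.std(scores))


def _cov_and_mean(feats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    feats = np.asarray(feats, dtype=np.float64)
    if feats.ndim != 2 or feats.shape[0] < 2:
        raise ValueError("feature matrix must be (n >= 2, d)")
    if not np.all(np.isfinite(feats)):
        raise ValueError("feature matrix contains non-finite values")
    return feats.mean(axis=0), np.cov(feats, rowvar=False).reshape(
        feats.shape[1], feats.shape[1]
    )


def fid_from_moments(
    mu1: np.ndarray, sigma1: np.ndarray, mu2: np.ndarray, sigma2: np.ndarray,
    eig_tol: float = 1e-6,
) -> float:
    """Frechet distance between two Gaussians given their exact moments.

    Tr((S1 S2)^{1/2}) is evaluated as Tr((S1^{1/2} S2 S1^{1/2})^{1/2}) via
    symmetric eigendecompositions; eigenvalues above -eig_tol are clipped
    to zero, more negative ones raise.
    """
    mu1, mu2 = np.asarray(mu1, float), np.asarray(mu2, float)
    s1 = np.atleast_2d(np.asarray(sigma1, float))
    s2 = np.atleast_2d(np.asarray(sigma2, float))
    diff = float(np.sum((mu1 - mu2) ** 2))
    w, v = np.linalg.eigh((s1 + s1.T) / 2.0)
    root1 = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    inner = root1 @ ((s2 + s2.T) / 2.0) @ root1
    w2 = np.linalg.eigvalsh((inner + inner.T) / 2.0)
    if np.any(w2 < -eig_tol):
        raise FloatingPointError(f"covariance product has eigenvalue {w2.min():.3g} < -{eig_tol}")
    tr_root = float(np.sum(np.sqrt(np.clip(w2, 0.0, None))))
    return diff + float(np.trace(s1) + np.trace(s2)) - 2.0 * tr_root


def fid(real: np.ndarray, fake: np.ndarray) -> float:
    """Frechet distance between the sample moments of two feature matrices."""
    mu_r, s_r = _cov_and_mean(real)
    mu_f, s_f = _cov_and_mean(fake)
    if mu_r.shape != mu_f.shape:
        raise ValueError("feature dimensionality mismatch")
    return fid_from_moments(mu_r, s_r, mu_f, s_f)


def _poly_kernel(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    return (x @ y.T / d + 1.0) ** 3


def kid(
    real: np.ndarray,
    fake: np.ndarray,
    n_subsets: int = 100,
    subset_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Unbiased squared-MMD between feature sets, subset mean +/- std."""
    real = np.asarray(real, dtype=np.float64)
    fake = np.asarray(fake, dtype=np.float64)
    if real.shape[1] != fake.shape[1]:
        raise ValueError("feature dimensionality mismatch")
    n = min(real.shape[0], fake.shape[0])
    if subset_size is None:
        subset_size = min(n, 1000)
    if subset_size < 2:
        raise ConfigurationError("subset_size must be >= 2")
    if subset_size > n:
        raise ConfigurationError(f"subset_size {subset_size} exceeds sample count {n}")
    rng = rng or np.random.default_rng()
    m = subset_size
    estimates = []
    for _ in range(n_subsets):
        xs = real[rng.choice(real.shape[0], m, replace=False)]
        ys = fake[rng.choice(fake.shape[0], m, replace=False)]
        kxx = _poly_kernel(xs, xs)
        kyy = _poly_kernel(ys, ys)
        kxy = _poly_kernel(xs, ys)
        mmd2 = (
            (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
            + (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
            - 2.0 * kxy.mean()
        )
        estimates.append(mmd2)
    return float(np.mean(estimates)), float(np.std(estimates))


# ---------------------------------------------------------------------------
# feature extraction


class IdentityExtractor:
    """Flattens each image; d equals the pixel count."""

    def __init__(self, d: int):
        self.d = d

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return np.asarray(image, dtype=np.float64).ravel()


class RandomProjectionExtractor:
    """Deterministic offline embedding: average-pool then random projection.

    Images are average-pooled onto a fixed ``pool x pool`` grid per
    channel, flattened, and projected by a fixed seeded Gaussian matrix
    followed by tanh.  No weights are downloaded; an adapter wrapping a
    pretrained classifier can be slotted in through the same callable
    contract.
    """

    def __init__(self, d: int = 32, pool: int = 4, channels: int = 3, seed: int = 7):
        self.d = d
        self.pool = pool
        rng = np.random.default_rng(seed)
        self.proj = rng.standard_normal((pool * pool * channels, d)) / np.sqrt(
            pool * pool * channels
        )

    def __call__(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 2:
            img = img[..., None]
        h, w, c = img.shape
        p = self.pool
        ys = np.linspace(0, h, p + 1).astype(int)
        xs = np.linspace(0, w, p + 1).astype(int)
        pooled = np.empty((p, p, c))
        for i in range(p):
            for j in range(p):
                pooled[i, j] = img[ys[i] : ys[i + 1], xs[j] : xs[j + 1]].mean(axis=(0, 1))
        v = pooled.ravel()
        if v.size != self.proj.shape[0]:
            raise ValueError("channel count does not match the extractor")
        return np.tanh(v @ self.proj)


def extract_features(
    images: np.ndarray | list, extractor: Callable[[np.ndarray], np.ndarray]
) -> np.ndarray:
    """Row-per-image feature matrix for a batch of images."""
    rows = []
    expected = getattr(extractor, "d", None)
    for img in images:
        row = np.asarray(extractor(img), dtype=np.float64).ravel()
        if expected is not None and row.size != expected:
            raise ValueError(
                f"extractor declared d={expected} but produced {row.size}"
            )
        rows.append(row)
    return np.stack(rows)
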