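"""Noise schedules for the Gaussian diffusion chain.

A schedule fixes the per-step corruption variances ``beta[t]`` for
``t = 1..T`` together with the cumulative signal retention
``alpha_bar[t] = prod_{s<=t} (1 - beta[s])``, which governs the
single-step forward marginal ``q(x_t | x_0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseSchedule", "build_noise_schedule", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when schedule or sampler parameters are out of contract."""


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step variances and cumulative products of a diffusion chain.

    Attributes
    ----------
    T : int
        Number of forward steps; timesteps are 1-based, ``t = 0`` is the
        clean image.
    beta : np.ndarray
        ``beta[t-1]`` is the noise variance added at step ``t``; each value
        lies in (0, 1).
    alpha_bar : np.ndarray
        ``alpha_bar[t-1]`` is the running product of ``1 - beta`` through
        step ``t``; strictly decreasing, in (0, 1).
    """

    T: int
    beta: np.ndarray
    alpha_bar: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=np.float64)
        if beta.ndim != 1 or beta.shape[0] != self.T:
            raise ConfigurationError(
                f"beta must be a length-{self.T} vector, got shape {beta.shape}"
            )
        if np.any(beta <= 0.0) or np.any(beta >= 1.0):
            raise ConfigurationError("all beta values must lie strictly in (0, 1)")
        object.__setattr__(self, "beta", beta)
        alpha_bar = np.cumprod(1.0 - beta)
        if self.alpha_bar is not None:
            if not np.allclose(self.alpha_bar, alpha_bar, atol=1e-12, rtol=0.0):
                raise ConfigurationError(
                    "alpha_bar does not match the running product of (1 - beta)"
                )
        object.__setattr__(self, "alpha_bar", alpha_bar)

    # -- step-indexed accessors (1-based t; t=0 is the clean image) -------
    def beta_at(self, t: int) -> float:
        self._check_t(t)
        return float(self.beta[t - 1])

    def alpha_bar_at(self, t: int) -> float:
        """Cumulative product through step ``t``; ``alpha_bar_at(0) == 1``."""
        if t == 0:
            return 1.0
        self._check_t(t)
        return float(self.alpha_bar[t - 1])

    def posterior_variance(self, t: int) -> float:
        """Variance of ``q(x_{t-1} | x_t, x_0)``: beta-tilde at step ``t``."""
        self._check_t(t)
        ab_t = self.alpha_bar_at(t)
        ab_prev = self.alpha_bar_at(t - 1)
        return float((1.0 - ab_prev) / (1.0 - ab_t) * self.beta_at(t))

    def _check_t(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise IndexError(f"timestep t={t} outside 1..{self.T}")


def build_noise_schedule(
    T: int,
    kind: str = "linear",
    beta_min: float = 1e-4,
    beta_max: float = 0.02,
) -> NoiseSchedule:
    """Construct a noise schedule of ``T`` steps.

    ``linear`` interpolates beta evenly from ``beta_min`` to ``beta_max``
    (the conventional DDPM default of 1e-4 -> 0.02).  ``cosine`` uses the
    squared-cosine alpha-bar profile with the usual small offset, with the
    implied betas clipped into ``(beta_min, beta_max]``-independent bounds
    (0, 0.999] for numerical safety.
    """
    if T < 1:
        raise ConfigurationError(f"T must be >= 1, got {T}")
    if not (0.0 < beta_min <= beta_max < 1.0):
        raise ConfigurationError(
            f"need 0 < beta_min <= beta_max < 1, got ({beta_min}, {beta_max})"
        )
    if kind == "linear":
        beta = np.linspace(beta_min, beta_max, T)
    elif kind == "cosine":
        s = 0.008
        steps = np.arange(T + 1, dtype=np.float64)
        f = np.cos((steps / T + s) / (1.0 + s) * np.pi / 2.0) ** 2
        alpha_bar = f / f[0]
        beta = np.clip(1.0 - alpha_bar[1:] / alpha_bar[:-1], 1e-8, 0.999)
    else:
        raise ConfigurationError(f"unknown schedule kind {kind!r}")
    return NoiseSchedule(T=T, beta=beta)
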