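"""Gaussian diffusion: forward corruption, learned reversal, training loss.

The forward chain corrupts a clean image ``x_0`` to white noise ``x_T``
through ``q(x_t | x_{t-1}) = N(sqrt(1-beta_t) x_{t-1}, beta_t I)``, whose
``t``-step marginal collapses to the single draw
``x_t = sqrt(alpha_bar_t) x_0 + sqrt(1-alpha_bar_t) eps``.  The learned
reverse kernel ``p(x_{t-1} | x_t)`` is Gaussian with mean derived from a
network that predicts the cumulative noise eps, trained with the simple
MSE objective ``E ||eps - eps_hat(x_t, t)||^2``.

Images live in [0,1] at I/O boundaries and in [-1,1] inside the chain;
timesteps are 1-based with ``t = 0`` the clean image.
"""

from __future__ import annotations

from typing import Callable, NamedTuple

import numpy as np

from .schedule import NoiseSchedule

__all__ = [
    "DiffusionState",
    "to_diffusion_range",
    "from_diffusion_range",
    "q_sample_step",
    "q_sample",
    "predict_x0_from_eps",
    "posterior_mean",
    "p_sample",
    "ddim_step",
    "simple_loss",
    "sample_unconditional",
    "ddim_sample",
    "OracleEpsilonModel",
    "FixedNoiseModel",
]

# (x_t, t) -> predicted cumulative noise, same shape as x_t
EpsilonModel = Callable[[np.ndarray, int], np.ndarray]


class DiffusionState(NamedTuple):
    """A sample on the diffusion trajectory: the raster and its timestep."""

    x: np.ndarray
    t: int


def to_diffusion_range(image: np.ndarray) -> np.ndarray:
    """Map an I/O image in [0,1] to the chain's working range [-1,1]."""
    return np.asarray(image, dtype=np.float64) * 2.0 - 1.0


def from_diffusion_range(x: np.ndarray, clip: bool = True) -> np.ndarray:
    """Map a chain sample back to [0,1]; clipping happens only at emission."""
    out = (np.asarray(x, dtype=np.float64) + 1.0) / 2.0
    return np.clip(out, 0.0, 1.0) if clip else out


def q_sample_step(
    x_prev: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """One forward step: scale by sqrt(1-beta_t) and add N(0, beta_t) noise."""
    beta = schedule.beta_at(t)
    z = rng.standard_normal(np.shape(x_prev))
    return np.sqrt(1.0 - beta) * x_prev + np.sqrt(beta) * z


def q_sample(
    x0: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    noise: np.ndarray,
) -> np.ndarray:
    """Jump the clean sample straight to step ``t`` via the closed-form marginal."""
    x0 = np.asarray(x0, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != x0.shape:
        raise ValueError(f"noise shape {noise.shape} != x0 shape {x0.shape}")
    ab = schedule.alpha_bar_at(t)
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * noise


def predict_x0_from_eps(
    x_t: np.ndarray, t: int, eps: np.ndarray, schedule: NoiseSchedule
) -> np.ndarray:
    """Invert the closed-form marginal to recover the implied clean sample."""
    ab = schedule.alpha_bar_at(t)
    return (x_t - np.sqrt(1.0 - ab) * eps) / np.sqrt(ab)


def posterior_mean(
    x_t: np.ndarray, t: int, eps: np.ndarray, schedule: NoiseSchedule
) -> np.ndarray:
    """DDPM posterior mean mu(x_t, eps_hat) of the reverse kernel at step t."""
    beta = schedule.beta_at(t)
    ab = schedule.alpha_bar_at(t)
    return (x_t - beta / np.sqrt(1.0 - ab) * eps) / np.sqrt(1.0 - beta)


def p_sample(
    model: EpsilonModel,
    x_t: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
    variance: str = "posterior",
) -> np.ndarray:
    """One learned reverse step ``x_t -> x_{t-1}``.

    The mean comes from the model's noise prediction via the standard
    posterior-mean formula; the variance is the fixed posterior variance
    beta-tilde by default (``variance="posterior"``) or beta itself
    (``variance="beta"``).  The final step ``t = 1`` is deterministic.
    """
    eps = np.asarray(model(x_t, t), dtype=np.float64)
    if eps.shape != np.shape(x_t):
        raise ValueError(
            f"model output shape {eps.shape} != input shape {np.shape(x_t)}"
        )
    if not np.all(np.isfinite(eps)):
        raise FloatingPointError(f"non-finite model output at timestep t={t}")
    mu = posterior_mean(x_t, t, eps, schedule)
    if t == 1:
        return mu
    if variance == "posterior":
        var = schedule.posterior_variance(t)
    elif variance == "beta":
        var = schedule.beta_at(t)
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    return mu + np.sqrt(var) * rng.standard_normal(np.shape(x_t))


def ddim_step(
    model: EpsilonModel, x_t: np.ndarray, t: int, schedule: NoiseSchedule
) -> np.ndarray:
    """Deterministic (eta = 0) reverse step: re-noise the implied x0 to t-1."""
    eps = np.asarray(model(x_t, t), dtype=np.float64)
    x0_hat = predict_x0_from_eps(x_t, t, eps, schedule)
    ab_prev = schedule.alpha_bar_at(t - 1)
    return np.sqrt(ab_prev) * x0_hat + np.sqrt(1.0 - ab_prev) * eps


def simple_loss(
    model: EpsilonModel,
    x0: np.ndarray,
    t: np.ndarray | int,
    noise: np.ndarray,
    schedule: NoiseSchedule,
) -> float:
    """Simplified training objective: mean squared noise-prediction error.

    ``x0``/``noise`` may be a single raster or a leading-axis batch with
    per-item timesteps.  Zero iff the model reproduces the injected noise.
    """
    x0 = np.asarray(x0, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != x0.shape:
        raise ValueError(f"noise shape {noise.shape} != x0 shape {x0.shape}")
    ts = np.atleast_1d(np.asarray(t, dtype=int))
    if ts.size == 1:
        x0b, nb = x0[None], noise[None]
    else:
        if x0.shape[0] != ts.size:
            raise ValueError("batch size of x0 and t disagree")
        x0b, nb = x0, noise
    total = 0.0
    for i, ti in enumerate(ts):
        x_t = q_sample(x0b[i], int(ti), schedule, nb[i])
        eps_hat = np.asarray(model(x_t, int(ti)), dtype=np.float64)
        total += float(np.mean((nb[i] - eps_hat) ** 2))
    return total / ts.size


def sample_unconditional(
    model: EpsilonModel,
    shape: tuple[int, ...],
    schedule: NoiseSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """Full ancestral reverse chain from white noise; returns x_0 in [-1,1]."""
    x = rng.standard_normal(shape)
    for t in range(schedule.T, 0, -1):
        try:
            x = p_sample(model, x, t, schedule, rng)
        except FloatingPointError as exc:
            raise FloatingPointError(f"reverse chain failed at t={t}: {exc}") from exc
    return np.clip(x, -1.0, 1.0)


def ddim_sample(
    model: EpsilonModel,
    shape: tuple[int, ...],
    schedule: NoiseSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """Deterministic sampler variant: only the initial draw is stochastic."""
    x = rng.standard_normal(shape)
    for t in range(schedule.T, 0, -1):
        x = ddim_step(model, x, t, schedule)
    return np.clip(x, -1.0, 1.0)


class OracleEpsilonModel:
    """Noise oracle that knows the clean sample it is denoising.

    Returns the exact cumulative noise implied by ``x_t`` and the known
    ``x0``; with it, the reverse chain reconstructs ``x0`` exactly at the
    last step regardless of trajectory.  Used for round-trip testing.
    """

    def __init__(self, x0: np.ndarray, schedule: NoiseSchedule):
        self.x0 = np.asarray(x0, dtype=np.float64)
        self.schedule = schedule

    def __call__(self, x_t: np.ndarray, t: int) -> np.ndarray:
        ab = self.schedule.alpha_bar_at(t)
        return (x_t - np.sqrt(ab) * self.x0) / np.sqrt(1.0 - ab)


class FixedNoiseModel:
    """Returns a fixed noise field regardless of input; a loss-oracle stub."""

    def __init__(self, noise: np.ndarray):
        self.noise = np.asarray(noise, dtype=np.float64)

    def __call__(self, x_t: np.ndarray, t: int) -> np.ndarray:
        return self.noise
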