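"""Closed-form mathematics of the Gaussian diffusion process.

The forward process gradually corrupts an image ``x0`` with Gaussian noise
over ``T`` discrete timesteps according to a variance schedule ``beta``:

    q(x_t | x_{t-1}) = N(x_t; sqrt(1 - beta_t) x_{t-1}, beta_t I)

Because Gaussian compositions stay Gaussian, the marginal at any t is
available in closed form through the cumulative products ``alpha_bar``:

    q(x_t | x0) = N(x_t; sqrt(alpha_bar_t) x0, (1 - alpha_bar_t) I)

This module holds the schedule container, the closed-form forward sampler,
the exact reverse-process posterior, the epsilon-parameterized reverse mean,
and the simple noise-prediction training loss.

Timesteps are 1-based at every public interface (t = 1..T); vectors inside
:class:`NoiseSchedule` are stored 0-based, so ``betas[t-1]`` is the variance
added at step t. Schedule vectors are kept in float64: ``alpha_bar_T`` is a
product of 1000 near-unit factors and accumulates error in float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "NoiseSchedule",
    "make_linear_schedule",
    "scaled_linear_schedule",
    "q_sample",
    "posterior_mean_var",
    "mu_from_eps",
    "simple_loss",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-timestep variances of the forward process and derived quantities.

    Attributes
    ----------
    T : int
        Number of diffusion timesteps.
    betas : ndarray, shape (T,)
        Forward variances beta_t in (0, 1); ``betas[t-1]`` is beta_t.
    alphas : ndarray, shape (T,)
        1 - beta_t.
    alpha_bars : ndarray, shape (T,)
        Running products of alphas; strictly decreasing, in (0, 1).
    posterior_vars : ndarray, shape (T,)
        Variance of the exact reverse posterior q(x_{t-1} | x_t, x0),
        ``(1 - alpha_bar_{t-1}) / (1 - alpha_bar_t) * beta_t`` with the
        convention alpha_bar_0 := 1 (so the t=1 entry is 0).
    """

    T: int
    betas: np.ndarray
    alphas: np.ndarray = field(repr=False, default=None)
    alpha_bars: np.ndarray = field(repr=False, default=None)
    posterior_vars: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        betas = np.asarray(self.betas, dtype=np.float64)
        if betas.shape != (self.T,):
            raise ValueError(f"betas must have shape ({self.T},)")
        if np.any(betas <= 0.0) or np.any(betas >= 1.0):
            raise ValueError("betas must lie strictly inside (0, 1)")
        alphas = 1.0 - betas
        alpha_bars = np.cumprod(alphas)
        prev = np.concatenate([[1.0], alpha_bars[:-1]])  # alpha_bar_0 := 1
        posterior_vars = (1.0 - prev) / (1.0 - alpha_bars) * betas
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "alpha_bars", alpha_bars)
        object.__setattr__(self, "posterior_vars", posterior_vars)

    # -- 1-based accessors -------------------------------------------------
    def beta(self, t: int) -> float:
        self._check_t(t)
        return float(self.betas[t - 1])

    def alpha(self, t: int) -> float:
        self._check_t(t)
        return float(self.alphas[t - 1])

    def alpha_bar(self, t: int) -> float:
        """Cumulative product alpha_bar_t; alpha_bar_0 == 1 by convention."""
        if t == 0:
            return 1.0
        self._check_t(t)
        return float(self.alpha_bars[t - 1])

    def posterior_var(self, t: int) -> float:
        self._check_t(t)
        return float(self.posterior_vars[t - 1])

    def _check_t(self, t: int) -> None:
        if not (1 <= int(t) <= self.T):
            raise ValueError(f"timestep t={t} outside [1, {self.T}]")

    # -- serialization -----------------------------------------------------
    def to_yaml(self) -> str:
        b = self.betas
        return yaml.safe_dump(
            {"T": int(self.T), "beta_start": float(b[0]), "beta_end": float(b[-1])}
        )

    @classmethod
    def from_yaml(cls, text: str) -> "NoiseSchedule":
        cfg = yaml.safe_load(text)
        return make_linear_schedule(int(cfg["T"]), float(cfg["beta_start"]),
                                    float(cfg["beta_end"]))


def make_linear_schedule(T: int, beta_start: float = 1e-4,
                         beta_end: float = 0.02) -> NoiseSchedule:
    """Linearly spaced variance schedule from ``beta_start`` to ``beta_end``.

    The default range over T=1000 steps drives alpha_bar_T below 0.01 so the
    fully-noised marginal is indistinguishable from a standard Gaussian.
    """
    if T < 1:
        raise ValueError(f"T must be a positive integer, got {T}")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError(
            f"need 0 < beta_start <= beta_end < 1, got ({beta_start}, {beta_end})"
        )
    betas = np.linspace(beta_start, beta_end, T, dtype=np.float64)
    return NoiseSchedule(T=T, betas=betas)


def scaled_linear_schedule(T: int, ref_T: int = 1000,
                           ref_beta_start: float = 1e-4,
                           ref_beta_end: float = 0.02) -> NoiseSchedule:
    """Linear schedule for a shorter chain with the reference chain's total
    noising budget.

    Scaling both beta endpoints by ref_T / T keeps the sum of the betas —
    and hence the terminal signal attenuation alpha_bar_T ~ exp(-sum beta) —
    approximately equal to the reference schedule's, so x_T remains
    noise-dominated even for desk-scale chain lengths.
    """
    s = ref_T / T
    return make_linear_schedule(T, ref_beta_start * s, ref_beta_end * s)


def _broadcastable(x0, xt=None, eps=None):
    arrs = [np.asarray(a) for a in (x0, xt, eps) if a is not None]
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError(f"shape mismatch: {a.shape} vs {shape}")
    return arrs


def q_sample(x0: np.ndarray, t: int, eps: np.ndarray,
             schedule: NoiseSchedule) -> np.ndarray:
    """Sample x_t from q(x_t | x0) with the supplied standard-normal draw.

    x_t = sqrt(alpha_bar_t) * x0 + sqrt(1 - alpha_bar_t) * eps
    """
    x0, eps = _broadcastable(x0, eps=eps)
    ab = schedule.alpha_bar(int(t))
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def posterior_mean_var(x0: np.ndarray, xt: np.ndarray, t: int,
                       schedule: NoiseSchedule):
    """Exact reverse posterior q(x_{t-1} | x_t, x0).

    Returns the mean

        mu~_t = [sqrt(alpha_t)(1 - alpha_bar_{t-1}) x_t
                 + sqrt(alpha_bar_{t-1})(1 - alpha_t) x0] / (1 - alpha_bar_t)

    and the scalar variance beta~_t. At t=1 (alpha_bar_0 := 1) the mean
    collapses to x0 and the variance to 0.
    """
    x0, xt = _broadcastable(x0, xt)
    t = int(t)
    schedule._check_t(t)
    ab_t = schedule.alpha_bar(t)
    ab_prev = schedule.alpha_bar(t - 1)
    a_t = schedule.alpha(t)
    denom = 1.0 - ab_t
    coef_xt = np.sqrt(a_t) * (1.0 - ab_prev) / denom
    coef_x0 = np.sqrt(ab_prev) * (1.0 - a_t) / denom
    mean = coef_xt * xt + coef_x0 * x0
    return mean, schedule.posterior_var(t)


def mu_from_eps(xt: np.ndarray, t: int, eps_hat: np.ndarray,
                schedule: NoiseSchedule):
    """Reverse-process mean parameterized by the predicted noise.

        mu_theta(x_t, t) = (x_t - (1 - alpha_t)/sqrt(1 - alpha_bar_t) eps_hat)
                           / sqrt(alpha_t)

    Returns ``(mean, sigma2)`` where sigma2 = beta_t is the sampler's fixed
    reverse variance.
    """
    xt, eps_hat = _broadcastable(xt, eps_hat)
    t = int(t)
    schedule._check_t(t)
    a_t = schedule.alpha(t)
    ab_t = schedule.alpha_bar(t)
    mean = (xt - (1.0 - a_t) / np.sqrt(1.0 - ab_t) * eps_hat) / np.sqrt(a_t)
    return mean, schedule.beta(t)


def simple_loss(eps_true: np.ndarray, eps_pred: np.ndarray) -> float:
    """Mean squared error between true and predicted noise.

    The expectation over elements (rather than a summed squared norm) keeps
    the loss scale independent of image resolution and batch size.
    """
    eps_true, eps_pred = _broadcastable(eps_true, eps_pred)
    d = eps_pred.astype(np.float64) - eps_true.astype(np.float64)
    return float(np.mean(d * d))
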