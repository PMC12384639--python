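"""Ancestral sampling from the learned reverse diffusion process.

Starting from pure noise x_T ~ N(0, I), each step draws

    x_{t-1} ~ N(mu_theta(x_t, t), beta_t I)

where the mean is recovered from the model's noise prediction. At the final
step (t = 1) the noise term is suppressed and the posterior mean is returned
directly, so no irreducible noise is injected into the finished sample.

A classifier-free guidance hook is provided: given unconditional and
conditional noise predictions it extrapolates between them by a scale
factor. The generator here is trained unconditionally, so with no
conditioning branch the hook reduces to the identity on the unconditional
prediction; it exists so a conditional denoiser can be plugged in without
touching the sampling loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import NoiseSchedule, mu_from_eps, posterior_mean_var

__all__ = ["SamplerConfig", "ancestral_sample", "guided_eps"]


@dataclass
class SamplerConfig:
    """Sampling run parameters.

    ``steps`` must equal the schedule's T: the chain is the full ancestral
    reverse process with no step skipping or implicit striding.
    """

    steps: int = 1000
    guidance_scale: float = 3.0
    seed: int = 0
    batch: int = 1
    # Clip the implied clean-image estimate to [-clip_x0, clip_x0] (the
    # training data support) before forming the reverse mean; None disables.
    # Keeps imperfect noise predictions at low timesteps from compounding
    # into divergent trajectories.
    clip_x0: float = 0.5


def guided_eps(eps_uncond: np.ndarray, eps_cond: np.ndarray = None,
               scale: float = 3.0) -> np.ndarray:
    """Classifier-free guidance combination of noise predictions.

    Returns eps_uncond + scale * (eps_cond - eps_uncond). With no
    conditional prediction available the hook is the identity.
    """
    eps_uncond = np.asarray(eps_uncond)
    if eps_cond is None:
        return eps_uncond
    eps_cond = np.asarray(eps_cond)
    if eps_cond.shape != eps_uncond.shape:
        raise ValueError(f"shape mismatch: {eps_cond.shape} vs "
                         f"{eps_uncond.shape}")
    return eps_uncond + scale * (eps_cond - eps_uncond)


def ancestral_sample(model, schedule: NoiseSchedule, config: SamplerConfig,
                     shape=None, cond_model=None, return_trajectory=False,
                     rng=None):
    """Generate a batch of samples by full reverse-diffusion iteration.

    Parameters
    ----------
    model : callable
        ``model(x, t_batch) -> eps_hat`` (a UNet or any array-to-array map).
    schedule : NoiseSchedule
    config : SamplerConfig
        ``config.steps`` must equal ``schedule.T``.
    shape : tuple, optional
        Per-sample shape (C, H, W); inferred from ``model.spec`` when absent.
    cond_model : callable, optional
        Conditional noise predictor for classifier-free guidance; when None
        the guidance hook is a no-op.
    return_trajectory : bool
        Also return the list of intermediate states x_T ... x_0.
    rng : numpy Generator, optional
        Overrides the seeded generator derived from ``config.seed``.

    Returns
    -------
    samples : ndarray, shape (batch, C, H, W)
    trajectory : list of ndarray, only when ``return_trajectory`` is True.
    """
    if config.steps != schedule.T:
        raise ValueError(
            f"steps={config.steps} must equal schedule T={schedule.T}; "
            "the sampler performs full ancestral sampling without striding")
    if shape is None:
        spec = getattr(model, "spec", None)
        if spec is None:
            raise ValueError("shape is required for models without a .spec")
        shape = (spec.in_channels, spec.image_size, spec.image_size)
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    x = rng.standard_normal((config.batch, *shape)).astype(np.float32)
    trajectory = [x.copy()] if return_trajectory else None

    for t in range(schedule.T, 0, -1):
        t_batch = np.full(config.batch, t, dtype=np.int64)
        eps_hat = np.asarray(_predict(model, x, t_batch))
        if cond_model is not None:
            eps_hat = guided_eps(eps_hat, _predict(cond_model, x, t_batch),
                                 config.guidance_scale)
        if config.clip_x0 is not None:
            ab = schedule.alpha_bar(t)
            x0_hat = (x - np.sqrt(1.0 - ab) * eps_hat) / np.sqrt(ab)
            x0_hat = np.clip(x0_hat, -config.clip_x0, config.clip_x0)
            mean, _ = posterior_mean_var(x0_hat, x, t, schedule)
            sigma2 = schedule.beta(t)   # sampler variance stays beta_t
        else:
            mean, sigma2 = mu_from_eps(x, t, eps_hat, schedule)
        if t > 1:
            z = rng.standard_normal(x.shape)
            x = (mean + np.sqrt(sigma2) * z).astype(np.float32)
        else:
            x = mean.astype(np.float32)   # posterior mean at the last step
        if return_trajectory:
            trajectory.append(x.copy())

    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite values in sampled batch")
    if return_trajectory:
        return x, trajectory
    return x


def _predict(model, x, t_batch):
    pred = getattr(model, "predict", None)
    if pred is not None:
        return pred(x, t_batch)
    return model(x, t_batch)
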