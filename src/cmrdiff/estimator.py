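"""scikit-learn-style estimator wrapping training and sampling.

:class:`DiffusionImageGenerator` follows the fit/sample estimator protocol
(``get_params``/``set_params``, fitted attributes with trailing
underscores), so runs compose with standard model-selection tooling. It is
a thin orchestration layer: the mathematics lives in ``schedule``, the
denoiser in ``nn.unet``, optimization in ``trainer`` and generation in
``sampler``.
"""

from __future__ import annotations

import inspect

import numpy as np

from .schedule import make_linear_schedule
from .nn.unet import UNetSpec, build_unet
from .trainer import TrainConfig, train
from .sampler import SamplerConfig, ancestral_sample

__all__ = ["DiffusionImageGenerator"]


class DiffusionImageGenerator:
    """Unconditional diffusion generator of single-channel images.

    Parameters
    ----------
    image_size : int
        Side length of training and generated images.
    level_channels, down_kinds, up_kinds, heads, norm_groups : UNet shape.
    timesteps : int
        Diffusion chain length T.
    beta_start, beta_end : float
        Linear variance-schedule endpoints.
    lr_max, lr_min, warmup_steps, total_steps, batch_size, weight_decay,
    clip_norm : optimization settings (see :class:`TrainConfig`).
    seed : int
        Seed for weight init, batch/noise draws and sampling default.

    Attributes (after ``fit``)
    --------------------------
    model_ : UNet denoiser with trained weights.
    schedule_ : NoiseSchedule used for training and sampling.
    history_ : list of per-step records (step, loss, lr, val_loss).
    n_images_ : number of training images seen.
    """

    def __init__(self, image_size=128, level_channels=(64, 128, 256, 512, 1024),
                 down_kinds=("plain", "plain", "plain", "attn", "attn"),
                 up_kinds=("attn", "attn", "plain", "plain", "plain"),
                 heads=8, norm_groups=16, time_embed_dim=256,
                 timesteps=1000, beta_start=1e-4, beta_end=0.02,
                 lr_max=2e-4, lr_min=1e-6, warmup_steps=100, total_steps=None,
                 epochs=300, batch_size=16, weight_decay=1e-5, clip_norm=1.0,
                 seed=0):
        args, _, _, values = inspect.getargvalues(inspect.currentframe())
        for name in args:
            if name != "self":
                setattr(self, name, values[name])

    # -- sklearn protocol ---------------------------------------------------
    @classmethod
    def _param_names(cls):
        sig = inspect.signature(cls.__init__)
        return [p for p in sig.parameters if p != "self"]

    def get_params(self, deep=True):
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params):
        valid = set(self._param_names())
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r} for "
                                 f"{type(self).__name__}")
            setattr(self, k, v)
        return self

    # -- estimator API --------------------------------------------------
    def _unet_spec(self) -> UNetSpec:
        return UNetSpec(image_size=self.image_size,
                        level_channels=tuple(self.level_channels),
                        down_kinds=tuple(self.down_kinds),
                        up_kinds=tuple(self.up_kinds), heads=self.heads,
                        norm_groups=self.norm_groups,
                        time_embed_dim=self.time_embed_dim)

    def fit(self, X, y=None, val_batch=None, progress=False):
        """Train the denoiser on images X of shape (n, H, W) or (n, 1, H, W)
        with values in [-0.5, 0.5]."""
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[:, None]
        if X.shape[2] != self.image_size or X.shape[3] != self.image_size:
            raise ValueError(f"images must be {self.image_size}px square")
        if val_batch is not None:
            val_batch = np.asarray(val_batch)
            if val_batch.ndim == 3:
                val_batch = val_batch[:, None]
        self.schedule_ = make_linear_schedule(self.timesteps,
                                              self.beta_start, self.beta_end)
        rng = np.random.default_rng(self.seed)
        self.model_ = build_unet(self._unet_spec(), rng=rng)
        cfg = TrainConfig(lr_max=self.lr_max, lr_min=self.lr_min,
                          warmup_steps=self.warmup_steps,
                          total_steps=self.total_steps, epochs=self.epochs,
                          batch_size=self.batch_size,
                          weight_decay=self.weight_decay,
                          clip_norm=self.clip_norm, seed=self.seed)
        self.history_ = train(self.model_, X, self.schedule_, cfg,
                              val_batch=val_batch, progress=progress)
        self.n_images_ = X.shape[0]
        return self

    def sample(self, n: int = 1, seed: int = None, return_trajectory=False):
        """Generate ``n`` images by full ancestral sampling."""
        self._check_fitted()
        cfg = SamplerConfig(steps=self.schedule_.T,
                            seed=self.seed if seed is None else seed,
                            batch=n)
        return ancestral_sample(self.model_, self.schedule_, cfg,
                                return_trajectory=return_trajectory)

    def score(self, X, y=None, seed: int = None) -> float:
        """Negative denoising loss on held-out images (higher is better)."""
        self._check_fitted()
        from .trainer import _validation_loss
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[:, None]
        s = self.seed if seed is None else seed
        return -_validation_loss(self.model_, X.astype(np.float32),
                                 self.schedule_, seed=s)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
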