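"""Optimization loop for the noise-prediction objective.

Training minimizes the simple denoising loss: per step, a batch of clean
images is drawn, each paired with a uniform timestep t ~ U(1, T) and a fresh
standard-normal noise tensor; the noised image is formed in closed form and
the mean squared error between true and predicted noise is backpropagated.

The optimizer is AdamW (decoupled weight decay) with a linear learning-rate
warmup followed by cosine annealing, and global-norm gradient clipping.
Checkpoints carry model weights, optimizer moments and RNG state so an
interrupted run resumes bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .schedule import NoiseSchedule
from .nn.autograd import Tensor, no_grad
from .nn.unet import UNet, UNetSpec

__all__ = ["TrainConfig", "lr_at_step", "clip_by_global_norm", "AdamW",
           "train", "save_train_checkpoint", "load_train_checkpoint"]


@dataclass
class TrainConfig:
    """Hyperparameters of a training run.

    ``total_steps`` may be given directly; otherwise it is derived from
    ``epochs`` and the dataset size (steps per epoch = ceil(N / batch_size)).
    The cosine-annealing schedule is step-indexed.
    """

    lr_max: float = 2e-4
    lr_min: float = 1e-6
    warmup_steps: int = 100
    total_steps: int = None
    epochs: int = 300
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    weight_decay: float = 1e-5
    clip_norm: float = 1.0
    batch_size: int = 16
    precision: str = "reduced"       # "full" (float64) or "reduced" (float32)
    seed: int = 0
    checkpoint_every: int = 0        # 0 disables periodic checkpoints
    eval_every: int = 50

    def __post_init__(self):
        if self.lr_min >= self.lr_max:
            raise ValueError("lr_min must be < lr_max")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if self.precision not in ("full", "reduced"):
            raise ValueError("precision must be 'full' or 'reduced'")

    def resolve_total_steps(self, n_images: int) -> int:
        if self.total_steps is not None:
            return int(self.total_steps)
        per_epoch = -(-n_images // self.batch_size)
        return int(self.epochs * per_epoch)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))


def lr_at_step(s: int, cfg: TrainConfig, total_steps: int = None) -> float:
    """Learning rate at step ``s``: linear ramp 0 -> lr_max over the warmup,
    then cosine annealing

        lr(s) = lr_min + (lr_max - lr_min)/2 * (1 + cos(pi (s - s_w)/(s_max - s_w)))
    """
    s_max = total_steps if total_steps is not None else cfg.total_steps
    if s_max is None:
        raise ValueError("total_steps is required")
    if not (0 <= s <= s_max):
        raise ValueError(f"step {s} outside [0, {s_max}]")
    w = cfg.warmup_steps
    if w >= s_max:
        raise ValueError("warmup_steps must be < total_steps")
    if s < w:
        return cfg.lr_max * s / w
    frac = (s - w) / (s_max - w)
    return cfg.lr_min + 0.5 * (cfg.lr_max - cfg.lr_min) * (1.0 + np.cos(np.pi * frac))


def clip_by_global_norm(grads, max_norm: float):
    """Scale a set of gradient arrays so their joint L2 norm is at most
    ``max_norm``; direction is preserved. Returns the (possibly rescaled)
    list and is the identity on an empty set."""
    if max_norm <= 0:
        raise ValueError("max_norm must be positive")
    grads = list(grads)
    if not grads:
        return grads
    total = np.sqrt(sum(float(np.sum(np.square(g, dtype=np.float64)))
                        for g in grads))
    if total <= max_norm or total == 0.0:
        return grads
    scale = max_norm / total
    return [g * scale for g in grads]


class AdamW:
    """AdamW over a list of parameter Tensors (decoupled weight decay)."""

    def __init__(self, params, cfg: TrainConfig):
        self.params = list(params)
        self.cfg = cfg
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def step(self, lr: float):
        c = self.cfg
        self.t += 1
        b1, b2 = c.adam_beta1, c.adam_beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            update = (m / bc1) / (np.sqrt(v / bc2) + c.adam_eps)
            p.data = p.data - lr * (update + c.weight_decay * p.data)

    def state(self):
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state(self, state):
        self.t = int(state["t"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src


def _batch_loss(model, x0, t_batch, eps, schedule):
    """Autograd loss tensor for one batch with per-sample timesteps."""
    ab = schedule.alpha_bars[t_batch - 1].reshape(-1, 1, 1, 1)
    xt = (np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps).astype(x0.dtype)
    d = model(xt, t_batch) - Tensor(eps.astype(x0.dtype))
    return (d * d).mean()


def _validation_loss(model, val_batch, schedule, seed=12345):
    """Loss on a fixed validation batch with frozen timesteps and noise."""
    rng = np.random.default_rng(seed)
    x0 = np.asarray(val_batch)
    t_batch = rng.integers(1, schedule.T + 1, size=x0.shape[0])
    eps = rng.standard_normal(x0.shape).astype(x0.dtype)
    with no_grad():
        return float(_batch_loss(model, x0, t_batch, eps, schedule).data)


def save_train_checkpoint(path, model: UNet, opt: AdamW, rng, step: int,
                          history):
    from .nn.unet import save_checkpoint
    extra = {}
    for i, (m, v) in enumerate(zip(opt.m, opt.v)):
        extra[f"adam_m_{i}"] = m
        extra[f"adam_v_{i}"] = v
    extra["opt_t"] = opt.t
    extra["step"] = step
    extra["rng_state"] = json.dumps(rng.bit_generator.state)
    extra["history"] = json.dumps(history)
    save_checkpoint(path, model, extra=extra)


def load_train_checkpoint(path, cfg: TrainConfig):
    from .nn.unet import load_checkpoint
    dtype = np.float64 if cfg.precision == "full" else np.float32
    model, extra = load_checkpoint(path, dtype=dtype)
    opt = AdamW(model.parameters(), cfg)
    n = len(opt.params)
    opt.load_state({"t": int(extra["opt_t"]),
                    "m": [extra[f"adam_m_{i}"] for i in range(n)],
                    "v": [extra[f"adam_v_{i}"] for i in range(n)]})
    rng = np.random.default_rng()
    rng.bit_generator.state = json.loads(str(extra["rng_state"]))
    step = int(extra["step"])
    history = json.loads(str(extra["history"]))
    return model, opt, rng, step, history


def train(model: UNet, dataset: np.ndarray, schedule: NoiseSchedule,
          cfg: TrainConfig, val_batch: np.ndarray = None,
          checkpoint_path=None, resume_from=None, stop_at_step: int = None,
          progress=False):
    """Run the denoising-objective optimization loop.

    Parameters
    ----------
    model : UNet
    dataset : ndarray, shape (N, C, H, W), values in [-0.5, 0.5]
    schedule : NoiseSchedule
    cfg : TrainConfig
    val_batch : ndarray, optional
        Fixed batch evaluated every ``cfg.eval_every`` steps; its loss is
        recorded in the history under ``val_loss``.
    checkpoint_path : path, optional
        Where periodic checkpoints (every ``cfg.checkpoint_every`` steps, and
        at the end) are written.
    resume_from : path, optional
        Resume an interrupted run bit-exactly (model, optimizer, RNG).
    stop_at_step : int, optional
        Pause the run after this step (a checkpoint is written when
        ``checkpoint_path`` is set); the learning-rate schedule still spans
        the full run length, so resuming reproduces an uninterrupted run.

    Returns
    -------
    history : list of dict with keys step, loss, lr (and val_loss at
        evaluation steps).
    """
    dataset = np.asarray(dataset)
    if dataset.ndim != 4:
        raise ValueError("dataset must be (N, C, H, W)")
    lo, hi = float(dataset.min()), float(dataset.max())
    if lo < -0.5 - 1e-6 or hi > 0.5 + 1e-6:
        raise ValueError(f"dataset values outside [-0.5, 0.5]: [{lo}, {hi}]")
    dtype = np.float64 if cfg.precision == "full" else np.float32
    dataset = dataset.astype(dtype)
    n = dataset.shape[0]
    total = cfg.resolve_total_steps(n)

    if resume_from is not None:
        model, opt, rng, start_step, history = load_train_checkpoint(
            resume_from, cfg)
    else:
        opt = AdamW(model.parameters(), cfg)
        rng = np.random.default_rng(cfg.seed)
        start_step, history = 0, []

    params = opt.params
    end = total if stop_at_step is None else min(total, stop_at_step)
    it = range(start_step + 1, end + 1)
    if progress:
        try:
            from tqdm import tqdm
            it = tqdm(it, desc="train")
        except ImportError:
            pass

    for step in it:
        idx = rng.integers(0, n, size=cfg.batch_size)
        t_batch = rng.integers(1, schedule.T + 1, size=cfg.batch_size)
        eps = rng.standard_normal((cfg.batch_size, *dataset.shape[1:]))
        x0 = dataset[idx]
        model.zero_grad()
        loss = _batch_loss(model, x0, t_batch, eps.astype(dtype), schedule)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise FloatingPointError(
                f"non-finite training loss {loss_val} at step {step}; "
                "check data range and learning rate")
        loss.backward()
        grads = clip_by_global_norm([p.grad for p in params], cfg.clip_norm)
        for p, g in zip(params, grads):
            p.grad = g
        lr = lr_at_step(step, cfg, total_steps=total)
        opt.step(lr)
        rec = {"step": step, "loss": loss_val, "lr": lr}
        if val_batch is not None and (step % cfg.eval_every == 0 or
                                      step == total):
            rec["val_loss"] = _validation_loss(model, val_batch, schedule)
        history.append(rec)
        if (checkpoint_path is not None and cfg.checkpoint_every and
                step % cfg.checkpoint_every == 0):
            save_train_checkpoint(checkpoint_path, model, opt, rng, step,
                                  history)

    if checkpoint_path is not None:
        save_train_checkpoint(checkpoint_path, model, opt, rng, end, history)
    return history
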