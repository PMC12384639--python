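"""Image-fidelity metrics: Fréchet feature distance, SSIM and MS-SSIM.

Three complementary views of generator quality:

* **Fréchet distance** between Gaussian fits to feature embeddings of the
  real and generated sets — ``||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2})``.
  The feature extractor is pluggable behind :class:`FeatureExtractor`; the
  packaged default is a fixed-seed random-projection convolutional
  extractor, so distances live on a documented, self-consistent scale
  rather than the Inception scale.
* **SSIM against nearest training neighbors** — for each generated image,
  the maximum SSIM over the training set, quantifying per-sample realism
  (and revealing memorization when it approaches 1).
* **Pairwise MS-SSIM** among generated images — a diversity probe; the
  report prints the value without imposing a direction of preference.

SSIM uses the standard stabilization constants k1=0.01, k2=0.03 with a 7x7
Gaussian window (sigma 1.5) and dynamic range 1.0, matching images scaled
to [-0.5, 0.5].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, ndimage

__all__ = ["FeatureSet", "MetricReport", "SSIMConfig", "FeatureExtractor",
           "RandomConvFeatures", "frechet_distance", "frechet_from_moments",
           "ssim", "ms_ssim", "nn_ssim_score", "pairwise_msssim",
           "evaluate_fidelity"]


@dataclass(frozen=True)
class FeatureSet:
    """n_samples x d feature embedding of an image set."""

    matrix: np.ndarray
    extractor_id: str = "unknown"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 1:
            raise ValueError("feature matrix must be (n >= 2, d >= 1)")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite feature values")
        object.__setattr__(self, "matrix", m)


@dataclass
class MetricReport:
    fid: float
    ssim_mean: float
    ssim_sd: float
    msssim_mean: float
    msssim_sd: float
    n_real: int
    n_gen: int

    def to_dict(self):
        return {k: (float(v) if not isinstance(v, int) else v)
                for k, v in self.__dict__.items()}


def frechet_from_moments(mu1, sigma1, mu2, sigma2, eps: float = 1e-6) -> float:
    """Gaussian Fréchet distance from explicit first and second moments."""
    mu1, mu2 = np.atleast_1d(mu1), np.atleast_1d(mu2)
    sigma1, sigma2 = np.atleast_2d(sigma1), np.atleast_2d(sigma2)
    diff = mu1 - mu2
    with warnings.catch_warnings():
        # rank-deficient sample covariances (n <= d) are routine for small
        # image sets; the diagonal-offset retry below handles breakdowns
        warnings.simplefilter("ignore", linalg.LinAlgWarning)
        covmean = np.asarray(linalg.sqrtm(sigma1 @ sigma2))
        if not np.isfinite(covmean).all():
            off = eps * np.eye(sigma1.shape[0])
            covmean = np.asarray(linalg.sqrtm((sigma1 + off) @ (sigma2 + off)))
    covmean = np.real(covmean)
    val = float(diff @ diff + np.trace(sigma1) + np.trace(sigma2)
                - 2.0 * np.trace(covmean))
    return max(val, 0.0)


def frechet_distance(A, B) -> float:
    """Fréchet distance between the Gaussian moment fits of two feature sets."""
    fa = A.matrix if isinstance(A, FeatureSet) else FeatureSet(A).matrix
    fb = B.matrix if isinstance(B, FeatureSet) else FeatureSet(B).matrix
    if fa.shape[1] != fb.shape[1]:
        raise ValueError(f"feature dimensions differ: {fa.shape[1]} vs "
                         f"{fb.shape[1]}")
    mu1, mu2 = fa.mean(axis=0), fb.mean(axis=0)
    s1 = np.cov(fa, rowvar=False).reshape(fa.shape[1], fa.shape[1])
    s2 = np.cov(fb, rowvar=False).reshape(fb.shape[1], fb.shape[1])
    return frechet_from_moments(mu1, s1, mu2, s2)


# ---------------------------------------------------------------------------
# SSIM / MS-SSIM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSIMConfig:
    window_size: int = 7
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2
    g = np.exp(-0.5 * (r / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def _filter(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return ndimage.correlate(img, kernel, mode="reflect")


def _ssim_components(a, b, cfg: SSIMConfig):
    """Windowed luminance and contrast-structure maps."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    k = _gaussian_kernel(cfg.window_size, cfg.sigma)
    c1 = (cfg.k1 * cfg.data_range) ** 2
    c2 = (cfg.k2 * cfg.data_range) ** 2
    mu_a, mu_b = _filter(a, k), _filter(b, k)
    var_a = _filter(a * a, k) - mu_a ** 2
    var_b = _filter(b * b, k) - mu_b ** 2
    cov = _filter(a * b, k) - mu_a * mu_b
    lum = (2 * mu_a * mu_b + c1) / (mu_a ** 2 + mu_b ** 2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    return lum, cs


def ssim(a: np.ndarray, b: np.ndarray, cfg: SSIMConfig = None) -> float:
    """Mean structural similarity between two images; 1 means identical."""
    cfg = cfg or SSIMConfig()
    lum, cs = _ssim_components(a, b, cfg)
    return float(np.mean(lum * cs))


# standard five-scale MS-SSIM exponents
_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])


def _downsample2(img: np.ndarray) -> np.ndarray:
    """2x smoothing-and-decimation (average pooling)."""
    h, w = img.shape
    img = img[:h - h % 2, :w - w % 2]
    return 0.25 * (img[0::2, 0::2] + img[1::2, 0::2]
                   + img[0::2, 1::2] + img[1::2, 1::2])


def ms_ssim(a: np.ndarray, b: np.ndarray, scales: int = 5,
            cfg: SSIMConfig = None) -> float:
    """Multi-scale SSIM: contrast-structure terms at every scale, luminance
    only at the coarsest, combined with the standard exponent vector
    (renormalized when fewer than five scales are requested)."""
    cfg = cfg or SSIMConfig()
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    min_side = min(a.shape)
    need = cfg.window_size * (1 << (scales - 1))
    if min_side < need:
        raise ValueError(f"image side {min_side} too small for {scales} "
                         f"scales with a {cfg.window_size}px window "
                         f"(needs >= {need})")
    if scales == 1:
        # degenerate pyramid: plain SSIM (no clipping, unit exponent)
        lum, cs = _ssim_components(a, b, cfg)
        return float(np.mean(lum * cs))
    w = _MSSSIM_WEIGHTS[:scales]
    w = w / w.sum()
    vals = []
    for s in range(scales):
        lum, cs = _ssim_components(a, b, cfg)
        if s == scales - 1:
            vals.append(np.mean(lum * cs))
        else:
            vals.append(np.mean(cs))
            a, b = _downsample2(a), _downsample2(b)
    # negative contrast-structure means (possible on anticorrelated inputs)
    # are clipped at zero before the fractional exponents
    vals = np.maximum(np.asarray(vals), 0.0)
    return float(np.prod(vals ** w))


def nn_ssim_score(gen_set, train_set, cfg: SSIMConfig = None):
    """Mean and sd over generated images of the best SSIM against the
    training set (exhaustive nearest-neighbor search under SSIM itself)."""
    gen_set, train_set = np.asarray(gen_set), np.asarray(train_set)
    if len(gen_set) == 0 or len(train_set) == 0:
        raise ValueError("both image sets must be non-empty")
    scores = [max(ssim(g, tr, cfg) for tr in train_set) for g in gen_set]
    return float(np.mean(scores)), float(np.std(scores))


def pairwise_msssim(images, max_pairs: int = None,
                    rng: np.random.Generator = None, scales: int = 5,
                    cfg: SSIMConfig = None):
    """Mean and sd of MS-SSIM over unordered pairs of an image set.

    All C(n, 2) pairs are evaluated when feasible; above ``max_pairs`` a
    seeded subsample of pairs is used.
    """
    images = np.asarray(images)
    n = len(images)
    if n < 2:
        raise ValueError("need at least 2 images")
    pairs = list(itertools.combinations(range(n), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = rng if rng is not None else np.random.default_rng(0)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    vals = [ms_ssim(images[i], images[j], scales=scales, cfg=cfg)
            for i, j in pairs]
    return float(np.mean(vals)), float(np.std(vals))


# ---------------------------------------------------------------------------
# feature extractors
# ---------------------------------------------------------------------------

class FeatureExtractor:
    """Interface: map a stack of 2-D images to an (n, d) feature matrix."""

    extractor_id = "base"

    def extract(self, images) -> FeatureSet:
        raise NotImplementedError


class RandomConvFeatures(FeatureExtractor):
    """Fixed-seed random-projection convolutional feature extractor.

    Two stages of random 5x5 convolutions (stride 2) with ReLU, followed by
    per-channel global mean and standard-deviation pooling. Filters are
    frozen at construction from the seed, so features — and therefore
    Fréchet distances — are reproducible across runs and platforms.
    """

    def __init__(self, channels=(12, 24), seed: int = 7):
        rng = np.random.default_rng(seed)
        self.filters = []
        c_in = 1
        for c_out in channels:
            w = rng.normal(0, 1.0 / np.sqrt(c_in * 25),
                           size=(c_out, c_in, 5, 5))
            self.filters.append(w)
            c_in = c_out
        self.extractor_id = f"randconv-{'x'.join(map(str, channels))}-s{seed}"

    @staticmethod
    def _conv_stride2(x, w):
        # x: (B, C, H, W), w: (Cout, Cin, 5, 5)
        pad = 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (5, 5), axis=(2, 3))
        win = win[:, :, ::2, ::2]
        B, C, Ho, Wo = win.shape[:4]
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * 25)
        out = col @ w.reshape(w.shape[0], -1).T
        return out.reshape(B, Ho, Wo, -1).transpose(0, 3, 1, 2)

    def extract(self, images) -> FeatureSet:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        for w in self.filters:
            x = np.maximum(self._conv_stride2(x, w), 0.0)
        mean = x.mean(axis=(2, 3))
        sd = x.std(axis=(2, 3))
        return FeatureSet(np.concatenate([mean, sd], axis=1),
                          extractor_id=self.extractor_id)


def evaluate_fidelity(real_images, gen_images,
                      extractor: FeatureExtractor = None,
                      cfg: SSIMConfig = None, scales: int = 5,
                      max_pairs: int = 2000,
                      rng: np.random.Generator = None) -> MetricReport:
    """Full metric report: Fréchet feature distance, nearest-neighbor SSIM
    of generated against real, and pairwise MS-SSIM diversity."""
    extractor = extractor or RandomConvFeatures()
    real_images = np.asarray(real_images)
    gen_images = np.asarray(gen_images)
    fid = frechet_distance(extractor.extract(real_images),
                           extractor.extract(gen_images))
    s_mean, s_sd = nn_ssim_score(gen_images, real_images, cfg)
    m_mean, m_sd = pairwise_msssim(gen_images, max_pairs=max_pairs, rng=rng,
                                   scales=scales, cfg=cfg)
    return MetricReport(fid=fid, ssim_mean=s_mean, ssim_sd=s_sd,
                        msssim_mean=m_mean, msssim_sd=m_sd,
                        n_real=len(real_images), n_gen=len(gen_images))
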