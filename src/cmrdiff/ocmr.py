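"""OCMR-style multi-coil k-space reading, reconstruction and preprocessing.

OCMR files store raw cine acquisitions as HDF5 with a single complex k-space
array organized across nine dimensions,

    [kx, ky, kz, coil, phase, set, slice, rep, avg],

i.e. frequency encoding, two phase encodings, receiver coils, cardiac
phases, velocity-encoding sets, anatomical slices, repetitions and signal
averages. This module loads such volumes, reconstructs magnitude frames by
coil-wise centered inverse FFT followed by root-sum-of-squares combination,
and applies the training preprocessing chain: bias-field correction,
histogram matching to a reference template, and z-score standardization
followed by an affine rescale onto exactly [-0.5, 0.5] (the bounded range
the diffusion model trains on).

The FFT convention is unitary and centered, which makes image-domain energy
equal k-space energy per coil (Parseval), a property the tests rely on.
Bias correction is a pluggable low-order polynomial log-domain fit — a
self-contained surrogate for full N4 that removes smooth multiplicative
inhomogeneity; any callable with the same signature can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage

__all__ = ["KSPACE_AXES", "KSpaceVolume", "ImageFrame", "load_kspace",
           "save_kspace", "reconstruct_rss", "PreprocessConfig", "preprocess",
           "polynomial_bias_correct", "match_histogram_to_reference",
           "default_reference_histogram", "frame_to_model_input"]

KSPACE_AXES = ("kx", "ky", "kz", "coil", "phase", "set", "slice", "rep", "avg")


@dataclass(frozen=True)
class KSpaceVolume:
    """A nine-axis complex k-space array plus acquisition attributes."""

    data: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.ndim != len(KSPACE_AXES):
            raise ValueError(
                f"k-space must have {len(KSPACE_AXES)} axes "
                f"{KSPACE_AXES}, got rank {d.ndim}")
        if not np.iscomplexobj(d):
            raise TypeError("k-space data must be complex")
        if min(d.shape) < 1:
            raise ValueError("all axis lengths must be >= 1")
        object.__setattr__(self, "data", d)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ImageFrame:
    """A reconstructed or preprocessed 2-D magnitude frame."""

    pixels: np.ndarray
    slice_index: int = 0
    phase_index: int = 0
    provenance: dict = field(default_factory=dict)


def load_kspace(path) -> KSpaceVolume:
    """Read a nine-axis complex k-space volume from an HDF5 file.

    The dataset must be named ``kData`` and may be stored either as a native
    complex array or as a compound array with ``real``/``imag`` fields (the
    layout OCMR uses).
    """
    try:
        fh = h5py.File(path, "r")
    except OSError as e:
        raise OSError(f"cannot open {path!r} as HDF5: {e}") from e
    with fh:
        if "kData" not in fh:
            raise KeyError(f"{path!r} has no 'kData' dataset "
                           f"(found: {list(fh.keys())})")
        ds = fh["kData"]
        raw = ds[...]
        if raw.dtype.names and {"real", "imag"} <= set(raw.dtype.names):
            data = raw["real"].astype(np.complex128)
            data.imag = raw["imag"]
        else:
            data = np.asarray(raw)
            if not np.iscomplexobj(data):
                raise TypeError(f"'kData' in {path!r} is neither complex nor "
                                "a real/imag compound array")
        if data.ndim != len(KSPACE_AXES):
            raise ValueError(
                f"'kData' has rank {data.ndim}; expected the 9-axis layout "
                f"{KSPACE_AXES}")
        attrs = {k: v for k, v in ds.attrs.items()}
        attrs.update({k: v for k, v in fh.attrs.items()})
    return KSpaceVolume(data=data, attrs=attrs)


def save_kspace(path, vol: KSpaceVolume):
    """Write a volume in the layout :func:`load_kspace` reads."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("kData", data=vol.data)
        for k, v in vol.attrs.items():
            ds.attrs[k] = v


def _ifft2c(k: np.ndarray) -> np.ndarray:
    """Centered, unitary 2-D inverse FFT over the first two axes."""
    shifted = np.fft.ifftshift(k, axes=(0, 1))
    img = np.fft.ifft2(shifted, axes=(0, 1), norm="ortho")
    return np.fft.fftshift(img, axes=(0, 1))


def reconstruct_rss(vol: KSpaceVolume, phase: int = 0, slice_index: int = 0,
                    set_index: int = 0, rep: int = 0) -> ImageFrame:
    """Magnitude image for one (phase, slice): per-coil centered inverse FFT
    then root-sum-of-squares across coils, with signal averages collapsed by
    mean."""
    d = vol.data
    for name, idx in (("phase", phase), ("slice", slice_index),
                      ("set", set_index), ("rep", rep)):
        ax = KSPACE_AXES.index(name)
        if not (0 <= idx < d.shape[ax]):
            raise IndexError(f"{name} index {idx} out of range "
                             f"[0, {d.shape[ax]})")
    k = d[:, :, :, :, phase, set_index, slice_index, rep, :]
    k = k.mean(axis=-1)          # collapse signal averages
    k = k[:, :, 0, :]            # 2-D acquisition: single kz plane
    coil_imgs = _ifft2c(k)       # (kx, ky, coil)
    rss = np.sqrt(np.sum(np.abs(coil_imgs) ** 2, axis=-1))
    return ImageFrame(pixels=rss, slice_index=slice_index, phase_index=phase,
                      provenance={"axes": KSPACE_AXES,
                                  "recon": "ifft2c+rss"})


# ---------------------------------------------------------------------------
# preprocessing chain
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    bias_correct: bool = True
    histogram_match: bool = True
    zscore: bool = True
    poly_order: int = 3
    hist_levels: int = 256


def polynomial_bias_correct(pixels: np.ndarray, order: int = 3) -> np.ndarray:
    """Remove smooth multiplicative intensity inhomogeneity.

    Fits a 2-D polynomial of total degree <= ``order`` to the log-image by
    least squares and divides it out (preserving the mean log level). This
    captures the slowly varying coil-shading component that full N4
    estimates iteratively.
    """
    p = np.asarray(pixels, dtype=np.float64)
    floor = max(p.max(), 1e-12) * 1e-6
    logp = np.log(np.maximum(p, floor))
    h, w = p.shape
    y, x = np.mgrid[:h, :w]
    y = (y - (h - 1) / 2) / max(h - 1, 1)
    x = (x - (w - 1) / 2) / max(w - 1, 1)
    cols = [np.ones(p.size)]
    for total in range(1, order + 1):
        for i in range(total + 1):
            cols.append((x ** (total - i) * y ** i).ravel())
    A = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(A, logp.ravel(), rcond=None)
    fitted = (A @ coef).reshape(h, w)
    corrected = np.exp(logp - fitted + fitted.mean())
    return corrected


def default_reference_histogram(levels: int = 256) -> np.ndarray:
    """Intensity quantiles of a canonical noiseless phantom rendering, used
    as the packaged histogram-matching template."""
    from .phantom import PhantomConfig, generate_phantom

    cfg = PhantomConfig()
    ph = generate_phantom(cfg, np.random.default_rng(20240301))
    ref = ph.image + 0.5    # onto [0, 1]
    return np.quantile(ref, np.linspace(0, 1, levels))


def match_histogram_to_reference(pixels: np.ndarray,
                                 reference: np.ndarray,
                                 levels: int = 256) -> np.ndarray:
    """Monotone quantile mapping of ``pixels`` onto a reference distribution.

    ``reference`` is either a template image (its quantiles are taken) or a
    pre-computed monotone quantile vector.
    """
    ref = np.asarray(reference, dtype=np.float64).ravel()
    q = np.linspace(0, 1, levels)
    ref_q = ref if ref.size == levels and np.all(np.diff(ref) >= 0) \
        else np.quantile(ref, q)
    if ref_q[-1] <= ref_q[0]:
        raise ValueError("degenerate reference histogram (constant values)")
    src_q = np.quantile(pixels, q)
    if src_q[-1] <= src_q[0]:
        raise ValueError("cannot histogram-match a constant image")
    return np.interp(pixels, src_q, ref_q,
                     left=ref_q[0], right=ref_q[-1])


def preprocess(frame: ImageFrame, reference_hist: np.ndarray = None,
               cfg: PreprocessConfig = None) -> ImageFrame:
    """Bias-correct -> histogram-match -> z-score -> rescale to [-0.5, 0.5].

    Each stage is individually toggleable through ``cfg``. The final affine
    rescale always runs so the output range is exactly [-0.5, 0.5]; a
    constant input is a normalization error.
    """
    cfg = cfg or PreprocessConfig()
    p = np.asarray(frame.pixels, dtype=np.float64)
    if not np.all(np.isfinite(p)):
        raise ValueError("frame contains non-finite pixels")
    if p.max() <= p.min():
        raise ValueError("cannot normalize a constant frame")
    stages = []
    if cfg.bias_correct:
        p = polynomial_bias_correct(p, order=cfg.poly_order)
        stages.append("bias_correct")
    if cfg.histogram_match:
        ref = reference_hist if reference_hist is not None \
            else default_reference_histogram(cfg.hist_levels)
        p = match_histogram_to_reference(p, ref, levels=cfg.hist_levels)
        stages.append("histogram_match")
    if cfg.zscore:
        sd = p.std()
        if sd == 0:
            raise ValueError("zero-variance frame after earlier stages")
        p = (p - p.mean()) / sd
        stages.append("zscore")
    p = (p - p.min()) / (p.max() - p.min()) - 0.5
    stages.append("rescale")
    prov = dict(frame.provenance)
    prov["preprocess"] = stages
    return ImageFrame(pixels=p, slice_index=frame.slice_index,
                      phase_index=frame.phase_index, provenance=prov)


def frame_to_model_input(frame: ImageFrame, size: int = 128) -> ImageFrame:
    """Center-crop to square, then bilinear-resize to ``size`` x ``size``."""
    p = np.asarray(frame.pixels, dtype=np.float64)
    h, w = p.shape
    side = min(h, w)
    top, left = (h - side) // 2, (w - side) // 2
    p = p[top:top + side, left:left + side]
    if side != size:
        p = ndimage.zoom(p, size / side, order=1, grid_mode=True,
                         mode="nearest")
        p = p[:size, :size]
    prov = dict(frame.provenance)
    prov["resized_to"] = size
    return ImageFrame(pixels=p, slice_index=frame.slice_index,
                      phase_index=frame.phase_index, provenance=prov)
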