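"""Anatomical-fidelity analysis over label masks.

Given cohorts of segmentation masks (labels 0 background, 1 LV, 2 RV,
3 myocardium), this module computes:

* per-structure pixel proportions (percent of all image pixels);
* binary shape descriptors — area, perimeter, roundness 4*pi*A/P^2,
  moment-ellipse eccentricity, convex-hull solidity;
* clinically interpreted ratios — LV/myocardium area ratio, RV/LV area
  ratio, and mean myocardial wall thickness measured by 360 radial rays
  cast from the LV centroid;
* two-sample Kolmogorov–Smirnov comparisons per metric between a "real"
  and a "generated" cohort, with a significance flag at alpha = 0.05.

Shape descriptors are computed on the largest connected component after
discarding fragments below 5 pixels; roundness is sensitive to the
perimeter estimator, so the contour-length estimator with diagonal
correction (as implemented by scikit-image's ``regionprops.perimeter``)
is used and documented as part of the metric definition. Solidity uses the
rasterized convex hull of ``regionprops``; note that a rasterized disk's
solidity sits a few percent below the analytic value of 1 because the hull
bridges the staircase notches of the boundary (about 0.96 at radius 20,
converging to 1 with size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure

from .phantom import LABELS

__all__ = ["ClassDistribution", "ShapeFeatures", "CardiacMetrics", "KSResult",
           "class_distribution", "shape_features", "myo_thickness",
           "cardiac_metrics", "ks_two_sample", "compare_cohorts",
           "STRUCTURES"]

STRUCTURES = ("LV", "RV", "Myo")
_MIN_FRAGMENT = 5   # pixels; smaller connected components are noise


@dataclass(frozen=True)
class ClassDistribution:
    """Percent of total image pixels occupied by each structure."""

    lv: float
    rv: float
    myo: float

    def as_dict(self):
        return {"LV": self.lv, "RV": self.rv, "Myo": self.myo}


@dataclass(frozen=True)
class ShapeFeatures:
    area: float
    perimeter: float
    roundness: float
    eccentricity: float
    solidity: float
    degenerate: bool = False

    def as_dict(self):
        return {"area": self.area, "roundness": self.roundness,
                "eccentricity": self.eccentricity, "solidity": self.solidity}


@dataclass(frozen=True)
class CardiacMetrics:
    lv_myo_ratio: float
    rv_lv_ratio: float      # nan when the RV is absent
    myo_thickness: float

    def as_dict(self):
        return {"lv_myo_ratio": self.lv_myo_ratio,
                "rv_lv_ratio": self.rv_lv_ratio,
                "myo_thickness": self.myo_thickness}


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov–Smirnov statistic with asymptotic p-value."""

    D: float
    p: float
    n: int
    m: int


def class_distribution(mask: np.ndarray) -> ClassDistribution:
    """Per-structure pixel percentage of the whole image."""
    mask = np.asarray(mask)
    labels = np.unique(mask)
    known = set(LABELS.values())
    if not set(labels.tolist()) <= known:
        raise ValueError(f"unknown labels {sorted(set(labels) - known)}")
    total = mask.size
    pct = {name: 100.0 * np.count_nonzero(mask == lab) / total
           for name, lab in LABELS.items()}
    return ClassDistribution(lv=pct["LV"], rv=pct["RV"], myo=pct["Myo"])


def _largest_component(binary: np.ndarray) -> np.ndarray:
    lab = measure.label(binary, connectivity=2)
    if lab.max() == 0:
        raise ValueError("empty mask")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = sizes >= _MIN_FRAGMENT
    keep[0] = False
    if keep.any():
        sizes = sizes * keep
    return lab == sizes.argmax()


def shape_features(binary_mask: np.ndarray) -> ShapeFeatures:
    """Morphology of the largest connected component of a binary mask."""
    binary = np.asarray(binary_mask).astype(bool)
    comp = _largest_component(binary)
    props = measure.regionprops(comp.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    if area < 2 or perimeter == 0.0:
        return ShapeFeatures(area=area, perimeter=perimeter,
                             roundness=np.nan, eccentricity=np.nan,
                             solidity=np.nan, degenerate=True)
    roundness = 4.0 * np.pi * area / perimeter ** 2
    return ShapeFeatures(area=area, perimeter=perimeter, roundness=roundness,
                         eccentricity=float(props.eccentricity),
                         solidity=float(props.solidity))


def myo_thickness(myo_mask: np.ndarray, lv_mask: np.ndarray,
                  n_rays: int = 360, step: float = 0.25) -> float:
    """Mean myocardial wall thickness in pixels.

    Casts ``n_rays`` equal-angle rays from the LV centroid; along each ray
    the thickness is the distance between the innermost and outermost
    myocardium crossing. Rays that never cross the wall are skipped; if no
    ray crosses, the geometry is invalid.
    """
    myo = np.asarray(myo_mask).astype(bool)
    lv = np.asarray(lv_mask).astype(bool)
    if not myo.any() or not lv.any():
        raise ValueError("both LV and myocardium masks must be non-empty")
    cy, cx = np.argwhere(lv).mean(axis=0)
    h, w = myo.shape
    r_max = float(np.hypot(h, w))
    radii = np.arange(step, r_max, step)
    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    thicknesses = []
    for ang in angles:
        ys = np.clip(np.round(cy + radii * np.sin(ang)).astype(int), 0, h - 1)
        xs = np.clip(np.round(cx + radii * np.cos(ang)).astype(int), 0, w - 1)
        hit = myo[ys, xs]
        if hit.any():
            idx = np.flatnonzero(hit)
            thicknesses.append(radii[idx[-1]] - radii[idx[0]] + step)
    if not thicknesses:
        raise ValueError("no ray crossed the myocardium; centroid outside "
                         "the ring?")
    return float(np.mean(thicknesses))


def cardiac_metrics(mask: np.ndarray) -> CardiacMetrics:
    """LV/Myo and RV/LV area ratios plus mean wall thickness."""
    mask = np.asarray(mask)
    lv = mask == LABELS["LV"]
    rv = mask == LABELS["RV"]
    myo = mask == LABELS["Myo"]
    lv_area, rv_area, myo_area = lv.sum(), rv.sum(), myo.sum()
    if lv_area == 0 or myo_area == 0:
        raise ValueError("mask must contain both LV and myocardium")
    rv_lv = float(rv_area) / lv_area if rv_area else np.nan
    return CardiacMetrics(lv_myo_ratio=float(lv_area) / myo_area,
                          rv_lv_ratio=rv_lv,
                          myo_thickness=myo_thickness(myo, lv))


def ks_two_sample(x, y) -> KSResult:
    """Two-sample KS test: D = sup |ECDF_x - ECDF_y| with the asymptotic
    Kolmogorov p-value at effective size nm/(n+m)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return KSResult(D=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                    n=int(x.size), m=int(y.size))


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

def _collect_metrics(masks) -> dict:
    """Per-mask metric samples for one cohort; non-finite values dropped
    metric-wise at comparison time."""
    out = {f"class_pct_{s}": [] for s in STRUCTURES}
    for s in STRUCTURES:
        for f in ("area", "roundness", "eccentricity", "solidity"):
            out[f"shape_{s}_{f}"] = []
    out.update({"lv_myo_ratio": [], "rv_lv_ratio": [], "myo_thickness": []})
    for mask in masks:
        dist = class_distribution(mask).as_dict()
        for s in STRUCTURES:
            out[f"class_pct_{s}"].append(dist[s])
        for s in STRUCTURES:
            binary = np.asarray(mask) == LABELS[s]
            if binary.any():
                feats = shape_features(binary).as_dict()
            else:
                feats = {k: np.nan for k in
                         ("area", "roundness", "eccentricity", "solidity")}
            for f, v in feats.items():
                out[f"shape_{s}_{f}"].append(v)
        try:
            cm = cardiac_metrics(mask).as_dict()
        except ValueError:
            cm = {"lv_myo_ratio": np.nan, "rv_lv_ratio": np.nan,
                  "myo_thickness": np.nan}
        for k, v in cm.items():
            out[k].append(v)
    return {k: np.asarray(v, dtype=np.float64) for k, v in out.items()}


def compare_cohorts(real_masks, gen_masks, alpha: float = 0.05):
    """Metric-by-metric comparison of two mask cohorts.

    Returns a list of 18 row dicts (3 class-distribution, 12 shape, 3
    cardiac metrics): cohort means and sds, relative difference of the
    generated mean against the real mean, KS statistic, p-value and a
    significance flag at ``alpha``.
    """
    if len(real_masks) < 2 or len(gen_masks) < 2:
        raise ValueError("need at least 2 masks per cohort")
    real = _collect_metrics(real_masks)
    gen = _collect_metrics(gen_masks)
    rows = []
    for key in real:
        x = real[key][np.isfinite(real[key])]
        y = gen[key][np.isfinite(gen[key])]
        if x.size < 2 or y.size < 2:
            rows.append({"metric": key, "real_mean": np.nan,
                         "real_sd": np.nan, "gen_mean": np.nan,
                         "gen_sd": np.nan, "rel_diff_pct": np.nan,
                         "ks_D": np.nan, "p_value": np.nan,
                         "significant": False, "n_real": int(x.size),
                         "n_gen": int(y.size)})
            continue
        ks = ks_two_sample(x, y)
        rm, gm = float(x.mean()), float(y.mean())
        rel = 100.0 * (gm - rm) / rm if rm != 0 else np.nan
        rows.append({"metric": key, "real_mean": rm,
                     "real_sd": float(x.std(ddof=1)), "gen_mean": gm,
                     "gen_sd": float(y.std(ddof=1)), "rel_diff_pct": rel,
                     "ks_D": ks.D, "p_value": ks.p,
                     "significant": bool(ks.p < alpha),
                     "n_real": ks.n, "n_gen": ks.m})
    return rows
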