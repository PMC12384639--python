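"""Fidelity metrics: Fréchet distance, SSIM, MS-SSIM, neighbor/diversity scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmrdiff.fidelity import (FeatureSet, SSIMConfig, RandomConvFeatures,
                              frechet_distance, frechet_from_moments, ssim,
                              ms_ssim, nn_ssim_score, pairwise_msssim,
                              evaluate_fidelity, _gaussian_kernel)


class TestFrechet:
    def test_identical_sets_give_zero(self, rng):
        f = rng.normal(size=(20, 5))
        assert frechet_distance(f, f.copy()) < 1e-6

    def test_one_dimensional_closed_form(self):
        # exact moments: N(0,1) vs N(2,1) -> (0-2)^2 + (1-1)^2 = 4
        assert frechet_from_moments([0.0], [[1.0]], [2.0], [[1.0]]) == \
            pytest.approx(4.0, abs=1e-9)

    def test_diagonal_covariance_oracle(self, rng):
        mu1, mu2 = rng.normal(size=(2, 3))
        v1, v2 = rng.uniform(0.5, 2.0, size=(2, 3))
        got = frechet_from_moments(mu1, np.diag(v1), mu2, np.diag(v2))
        want = np.sum((mu1 - mu2) ** 2 + (np.sqrt(v1) - np.sqrt(v2)) ** 2)
        assert got == pytest.approx(want, rel=1e-8)

    def test_symmetry_and_nonnegativity(self, rng):
        a = rng.normal(size=(30, 4))
        b = rng.normal(loc=0.5, size=(25, 4))
        d_ab = frechet_distance(a, b)
        d_ba = frechet_distance(b, a)
        assert d_ab >= 0
        assert d_ab == pytest.approx(d_ba, rel=1e-6)

    def test_common_shift_invariance(self, rng):
        a = rng.normal(size=(30, 4))
        b = rng.normal(loc=0.3, size=(30, 4))
        shift = rng.normal(size=4)
        assert frechet_distance(a, b) == pytest.approx(
            frechet_distance(a + shift, b + shift), rel=1e-6, abs=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            frechet_distance(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)))

    def test_feature_set_validation(self):
        with pytest.raises(ValueError):
            FeatureSet(np.array([[np.inf, 1.0], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            FeatureSet(np.zeros((1, 3)))


def literal_ssim_loops(a, b, kernel, k1=0.01, k2=0.03, L=1.0):
    """Independent SSIM transcription: explicit loops over window positions."""
    n = kernel.shape[0]
    r = n // 2
    ap = np.pad(a, r, mode="symmetric")
    bp = np.pad(b, r, mode="symmetric")
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    vals = []
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            wa = ap[i:i + n, j:j + n]
            wb = bp[i:i + n, j:j + n]
            mu_a = np.sum(kernel * wa)
            mu_b = np.sum(kernel * wb)
            va = np.sum(kernel * wa * wa) - mu_a ** 2
            vb = np.sum(kernel * wb * wb) - mu_b ** 2
            cov = np.sum(kernel * wa * wb) - mu_a * mu_b
            vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                        / ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))


class TestSSIM:
    def test_identity_is_one(self, rng):
        a = rng.uniform(-0.5, 0.5, size=(16, 16))
        assert ssim(a, a.copy()) == pytest.approx(1.0)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_bounded(self, seed):
        r = np.random.default_rng(seed)
        a = r.uniform(-0.5, 0.5, size=(12, 12))
        b = r.uniform(-0.5, 0.5, size=(12, 12))
        assert -1.0 <= ssim(a, b) <= 1.0

    def test_matches_literal_loop_transcription(self, rng):
        a = rng.uniform(-0.5, 0.5, size=(8, 8))
        b = rng.uniform(-0.5, 0.5, size=(8, 8))
        cfg = SSIMConfig()
        kernel = _gaussian_kernel(cfg.window_size, cfg.sigma)
        assert ssim(a, b, cfg) == pytest.approx(
            literal_ssim_loops(a, b, kernel), rel=1e-10)

    def test_agrees_with_skimage(self, rng):
        # independent implementation cross-check with matched window settings
        from skimage.metrics import structural_similarity
        a = rng.uniform(0, 1, size=(64, 64))
        b = np.clip(a + rng.normal(0, 0.1, size=(64, 64)), 0, 1)
        mine = ssim(a, b, SSIMConfig(window_size=11, sigma=1.5))
        theirs = structural_similarity(a, b, gaussian_weights=True, sigma=1.5,
                                       use_sample_covariance=False,
                                       data_range=1.0)
        assert mine == pytest.approx(theirs, abs=0.01)

    def test_affine_shift_invariance_within_range(self, rng):
        a = rng.uniform(-0.3, 0.1, size=(16, 16))
        b = rng.uniform(-0.3, 0.1, size=(16, 16))
        # identical offset applied to both images barely moves SSIM
        assert ssim(a + 0.15, b + 0.15) == pytest.approx(ssim(a, b), abs=0.06)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8)), np.zeros((8, 9)))


class TestMSSSIM:
    def test_identity_is_one(self, rng):
        a = rng.uniform(-0.5, 0.5, size=(128, 128))
        assert ms_ssim(a, a.copy()) == pytest.approx(1.0)

    def test_single_scale_equals_ssim(self, rng):
        a = rng.uniform(-0.5, 0.5, size=(32, 32))
        b = rng.uniform(-0.5, 0.5, size=(32, 32))
        assert ms_ssim(a, b, scales=1) == pytest.approx(ssim(a, b), rel=1e-10)

    def test_matches_reference_pyramid(self, rng):
        # independent pyramid: loop-based SSIM components per scale
        from cmrdiff.fidelity import _MSSSIM_WEIGHTS, _downsample2, \
            _ssim_components
        a = rng.uniform(-0.5, 0.5, size=(64, 64))
        b = np.clip(a + rng.normal(0, 0.2, size=(64, 64)), -0.5, 0.5)
        scales = 3
        cfg = SSIMConfig()
        w = _MSSSIM_WEIGHTS[:scales]
        w = w / w.sum()
        aa, bb = a.copy(), b.copy()
        terms = []
        for s in range(scales):
            lum, cs = _ssim_components(aa, bb, cfg)
            terms.append(np.mean(lum * cs) if s == scales - 1
                         else np.mean(cs))
            if s < scales - 1:
                aa, bb = _downsample2(aa), _downsample2(bb)
        want = np.prod(np.maximum(terms, 0.0) ** w)
        assert ms_ssim(a, b, scales=3) == pytest.approx(want, rel=1e-12)

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(ValueError):
            ms_ssim(np.zeros((16, 16)), np.zeros((16, 16)), scales=5)


class TestNeighborAndDiversity:
    def test_subset_self_match_is_one(self, rng):
        train = rng.uniform(-0.5, 0.5, size=(6, 16, 16))
        mean, sd = nn_ssim_score(train[:3], train)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_single_train_image_reduces_to_plain_ssim(self, rng):
        g = rng.uniform(-0.5, 0.5, size=(1, 16, 16))
        t = rng.uniform(-0.5, 0.5, size=(1, 16, 16))
        mean, _ = nn_ssim_score(g, t)
        assert mean == pytest.approx(ssim(g[0], t[0]))

    def test_matches_exhaustive_all_pairs(self, rng):
        gen = rng.uniform(-0.5, 0.5, size=(5, 12, 12))
        train = rng.uniform(-0.5, 0.5, size=(5, 12, 12))
        mean, sd = nn_ssim_score(gen, train)
        best = [max(ssim(g, t) for t in train) for g in gen]
        assert mean == pytest.approx(np.mean(best))
        assert sd == pytest.approx(np.std(best))

    def test_identical_images_fully_similar(self):
        imgs = np.tile(np.linspace(-0.5, 0.5, 32 * 32).reshape(1, 32, 32),
                       (4, 1, 1))
        mean, sd = pairwise_msssim(imgs, scales=2)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_three_images_three_pairs(self, rng):
        imgs = rng.uniform(-0.5, 0.5, size=(3, 32, 32))
        full = pairwise_msssim(imgs, scales=2)
        capped = pairwise_msssim(imgs, max_pairs=3, scales=2)
        assert full == capped

    def test_subsample_cap_equals_full_when_not_binding(self, rng):
        imgs = rng.uniform(-0.5, 0.5, size=(10, 32, 32))
        assert pairwise_msssim(imgs, scales=2) == \
            pairwise_msssim(imgs, max_pairs=45, scales=2)

    def test_too_few_images(self, rng):
        with pytest.raises(ValueError):
            pairwise_msssim(rng.normal(size=(1, 16, 16)))


class TestExtractorAndReport:
    def test_extractor_deterministic(self, rng):
        imgs = rng.uniform(-0.5, 0.5, size=(4, 32, 32))
        a = RandomConvFeatures(seed=3).extract(imgs)
        b = RandomConvFeatures(seed=3).extract(imgs)
        assert np.array_equal(a.matrix, b.matrix)

    def test_fid_separates_phantoms_from_noise(self, phantom_cohort, rng):
        images, _, _ = phantom_cohort
        ex = RandomConvFeatures()
        a = ex.extract(images[:80])
        b = ex.extract(images[80:160])
        noise = rng.uniform(-0.5, 0.5, size=(80, 128, 128))
        close = frechet_distance(a, b)
        far = frechet_distance(a, ex.extract(noise))
        assert far > 10 * close

    def test_report_fields(self, rng):
        real = rng.uniform(-0.5, 0.5, size=(6, 32, 32))
        gen = rng.uniform(-0.5, 0.5, size=(5, 32, 32))
        rep = evaluate_fidelity(real, gen, scales=2)
        assert rep.fid >= 0
        assert -1 <= rep.ssim_mean <= 1
        assert -1 <= rep.msssim_mean <= 1
        assert rep.n_real == 6 and rep.n_gen == 5
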