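"""SSIM/PSNR/MSE/SNR against closed forms and independent oracles."""

import numpy as np
import pytest

from raman3d.errors import ShapeError, ValidationError
from raman3d.metrics import (
    evaluate,
    mse,
    psnr,
    psnr_cube,
    snr,
    spectral_snr_cube,
    ssim,
    ssim_cube,
)


class TestMSE:
    def test_zero_on_identity(self, rng):
        a = rng.normal(size=17)
        assert mse(a, a) == 0.0

    def test_closed_form(self):
        assert mse(np.array([1.0, 2.0]), np.array([2.0, 4.0])) == pytest.approx(2.5)

    def test_matches_explicit_loop_oracle(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=40)
        expected = sum((bi - ai) ** 2 for ai, bi in zip(a, b)) / len(a)
        assert abs(mse(a, b) - expected) <= 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mse(np.array([]), np.array([]))


class TestPSNR:
    def test_closed_form_20db(self):
        """R=1, MSE=0.01 → 20 dB."""
        x = np.zeros(100)
        y = np.full(100, 0.1)
        assert psnr(x, y, 1.0) == pytest.approx(20.0)

    def test_identity_is_infinite(self, rng):
        a = rng.normal(size=(4, 4))
        assert psnr(a, a) == np.inf

    def test_composes_with_mse_oracle(self, rng):
        x, y = rng.uniform(size=64), rng.uniform(size=64)
        expected = 10 * np.log10(1.0 / mse(x, y))
        assert abs(psnr(x, y, 1.0) - expected) <= 1e-9


class TestSNR:
    def test_identity_is_infinite(self, rng):
        a = rng.normal(size=16)
        assert snr(a, a) == np.inf

    def test_closed_form(self):
        """a=[3,4], b=[4,4] → 10·log10(25/1) ≈ 13.979 dB."""
        assert snr(np.array([3.0, 4.0]), np.array([4.0, 4.0])) == pytest.approx(
            10 * np.log10(25.0), abs=1e-9
        )

    def test_matches_explicit_sum_oracle(self, rng):
        a, b = rng.uniform(1, 2, size=30), rng.uniform(1, 2, size=30)
        expected = 10 * np.log10(sum(v * v for v in a) / sum((u - v) ** 2 for u, v in zip(b, a)))
        assert abs(snr(a, b) - expected) <= 1e-9

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            snr(np.zeros(5), np.ones(5))


class TestSSIM:
    def test_self_similarity_is_exactly_one(self, rng):
        x = rng.uniform(size=(12, 12))
        assert ssim(x, x) == 1.0
        assert ssim(x, x, window="global") == 1.0

    def test_symmetry(self, rng):
        x, y = rng.uniform(size=(10, 10)), rng.uniform(size=(10, 10))
        assert abs(ssim(x, y) - ssim(y, x)) <= 1e-12

    def test_global_mode_matches_moment_oracle(self, rng):
        """Whole-image statistics plugged into the canonical formula."""
        x, y = rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8))
        c1, c2 = 0.01**2, 0.03**2
        mu_x, mu_y = x.mean(), y.mean()
        cov = ((x - mu_x) * (y - mu_y)).mean()
        expected = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
            (mu_x**2 + mu_y**2 + c1) * (x.var() + y.var() + c2)
        )
        assert abs(ssim(x, y, window="global") - expected) <= 1e-12

    def test_sliding_window_tracks_skimage(self, rng):
        """Cross-check against the scikit-image implementation with matched
        settings (Gaussian weights, sigma 1.5, population covariance)."""
        skimage = pytest.importorskip("skimage.metrics")
        x, y = rng.uniform(size=(32, 32)), rng.uniform(size=(32, 32))
        ours = ssim(x, y, window="gaussian", sigma=1.5, width=11)
        theirs = skimage.structural_similarity(
            x, y, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False,
        )
        assert abs(ours - theirs) < 0.02

    def test_cube_averages_over_bands(self, rng):
        x = rng.uniform(size=(8, 8, 3))
        y = rng.uniform(size=(8, 8, 3))
        per_band = [ssim(x[:, :, b], y[:, :, b]) for b in range(3)]
        assert ssim_cube(x, y) == pytest.approx(np.mean(per_band))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            ssim(np.zeros((4, 4)), np.zeros((4, 5)))


class TestEvaluate:
    def test_identity_collection(self, rng):
        refs = [rng.uniform(size=(6, 6, 4)) for _ in range(2)]
        report = evaluate(refs, refs)
        assert report.mean_ssim == 1.0
        assert report.mean_mse == 0.0
        assert report.mean_psnr_db == np.inf

    def test_single_sample_means_equal_per_sample(self, rng):
        ref = [rng.uniform(size=(6, 6, 4))]
        pred = [ref[0] + rng.normal(0, 0.05, size=(6, 6, 4))]
        report = evaluate(pred, ref)
        assert report.n == 1
        assert report.mean_psnr_db == report.per_sample[0][1]

    def test_two_sample_means_are_hand_averages(self, rng):
        refs = [rng.uniform(size=(6, 6, 4)) for _ in range(2)]
        preds = [r + rng.normal(0, 0.03, size=r.shape) for r in refs]
        report = evaluate(preds, refs)
        expected_psnr = np.mean([psnr_cube(r, p) for r, p in zip(refs, preds)])
        assert report.mean_psnr_db == pytest.approx(expected_psnr)

    def test_permutation_invariant_means(self, rng):
        refs = [rng.uniform(size=(6, 6, 4)) for _ in range(3)]
        preds = [r + rng.normal(0, 0.03, size=r.shape) for r in refs]
        fwd = evaluate(preds, refs)
        rev = evaluate(preds[::-1], refs[::-1])
        assert fwd.mean_ssim == pytest.approx(rev.mean_ssim)
        assert fwd.mean_snr_db == pytest.approx(rev.mean_snr_db)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            evaluate([np.zeros((2, 2, 2))], [])

    def test_zero_power_reference_rejected(self):
        with pytest.raises(ValidationError):
            spectral_snr_cube(np.zeros((2, 2, 3)), np.ones((2, 2, 3)))
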