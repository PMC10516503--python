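"""POCS partial-Fourier reconstruction, denoising backends, tricubic interpolation."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from pfsr.baseline import (
    PocsConfig, denoise3d, non_dl_pipeline, pocs_pf_reconstruct,
    tricubic_upsample, trilinear_upsample, _pocs_core,
)
from pfsr.degrade import DegradationConfig, make_pf_mask, simulate_ulf_pair, zero_fill_reconstruct
from pfsr.grid import VolumeGrid, fft_centered, ifft_centered
from pfsr.metrics import nrmse


def smooth_slice(seed=5, n=64):
    """A compact-support, band-limited 2D phantom slice (non-negative)."""
    from pfsr.phantom import PhantomSpec, generate_labeled_phantom

    item = generate_labeled_phantom(PhantomSpec(grid_size=n, seed=seed))
    img = gaussian_filter(item.volume.values[:, :, n // 2].astype(float), 1.0)
    return img / img.max()


def slice_nrmse(x, ref):
    return float(np.sqrt(np.mean((x - ref) ** 2)) / (ref.max() - ref.min()))


class TestPocs:
    def test_full_sampling_is_identity(self):
        img = smooth_slice()
        mask = make_pf_mask((64, 64), 1.0, 1.0)
        rec = pocs_pf_reconstruct(img, mask, PocsConfig(n_iter=5))
        np.testing.assert_allclose(rec, np.abs(img), atol=1e-8)

    def test_zero_iterations_equals_zero_fill(self, t1_phantom64):
        cfg = DegradationConfig(seed=2)
        inp, _ = simulate_ulf_pair(t1_phantom64.volume, cfg)
        mask = make_pf_mask((32, 32), 0.7, 0.7)
        rec = pocs_pf_reconstruct(inp, mask, PocsConfig(n_iter=0))
        zf = zero_fill_reconstruct(inp, mask)
        np.testing.assert_allclose(rec.values, zf.values, atol=1e-6)

    def test_hermitian_case_recovers_below_two_percent(self):
        """Real non-negative truth, zero phase, f = 0.7: POCS exploits
        Hermitian symmetry and lands well below the zero-fill error."""
        img = smooth_slice()
        mask = make_pf_mask((64, 64), 0.7, 0.7)
        zf = np.abs(ifft_centered(fft_centered(img) * mask.values))
        rec = pocs_pf_reconstruct(img, mask, PocsConfig(n_iter=10))
        assert slice_nrmse(rec, img) < slice_nrmse(zf, img)
        assert slice_nrmse(rec, img) < 0.02

    def test_linear_phase_case_beats_zero_fill(self):
        img = smooth_slice()
        ramp = np.exp(1j * (np.arange(64)[:, None] * 0.05 + np.arange(64)[None, :] * 0.08))
        cplx = img * ramp
        mask = make_pf_mask((64, 64), 0.7, 0.7)
        zf = np.abs(ifft_centered(fft_centered(cplx) * mask.values))
        rec = pocs_pf_reconstruct(cplx, mask, PocsConfig(n_iter=10))
        assert slice_nrmse(rec, img) < slice_nrmse(zf, img)

    def test_data_consistency_exact_each_iteration(self):
        """Acquired k-space samples of the (complex) iterate equal the
        acquired data after every iteration."""
        img = smooth_slice()
        mask = make_pf_mask((64, 64), 0.7, 0.7)
        data = fft_centered(img.astype(complex)) * mask.values
        for n_iter in (1, 3, 7):
            rec = _pocs_core(
                fft_centered(img.astype(complex)), mask.values, (0, 1), (0.7, 0.7),
                PocsConfig(n_iter=n_iter, tol=1e-30), return_complex=True,
            )
            k = fft_centered(rec)
            np.testing.assert_allclose(k[mask.values], data[mask.values], atol=1e-10)

    def test_empty_phase_band_rejected(self):
        img = smooth_slice()
        mask = make_pf_mask((64, 64), 0.7, 0.7)
        with pytest.raises(ValueError, match="central band"):
            pocs_pf_reconstruct(img, mask, PocsConfig(n_iter=5, phase_band=-1))


class TestDenoise:
    def test_near_identity_on_clean_volume(self, t1_phantom64):
        clean = t1_phantom64.volume
        out = denoise3d(clean, sigma=0.01)
        assert nrmse(out.values, clean.values, window_slices=64) < 0.02

    def test_reduces_noise(self, t1_phantom64):
        rng = np.random.default_rng(0)
        clean = t1_phantom64.volume
        noisy = clean.with_values(
            np.clip(clean.values + rng.normal(0, 0.05, clean.shape).astype(np.float32), 0, 1)
        )
        out = denoise3d(noisy)
        assert nrmse(out.values, clean.values) < nrmse(noisy.values, clean.values)

    def test_deterministic(self, t1_phantom64):
        a = denoise3d(t1_phantom64.volume)
        b = denoise3d(t1_phantom64.volume)
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_bm4d_backend_names_fallback(self, t1_phantom64):
        with pytest.raises((RuntimeError, Exception), match="fallback|bm4d"):
            denoise3d(t1_phantom64.volume, method="bm4d-wrapped")

    def test_unknown_backend(self, t1_phantom64):
        with pytest.raises(ValueError, match="unknown"):
            denoise3d(t1_phantom64.volume, method="wavelet")


class TestTricubic:
    def test_constant(self):
        out = tricubic_upsample(VolumeGrid(np.full((8, 8, 8), 0.4)), 2)
        np.testing.assert_allclose(out.values, 0.4, atol=1e-12)
        assert out.voxel_mm == 0.75

    def test_linear_ramp_exact_in_interior(self):
        """Cubic convolution reproduces linear fields exactly wherever the
        4-sample stencil does not touch the clamped edges."""
        v = np.broadcast_to(np.arange(8.0)[:, None, None], (8, 8, 8)).copy()
        out = tricubic_upsample(VolumeGrid(v), 2).values
        expected = np.broadcast_to(np.arange(16.0)[:, None, None] / 2, (16, 16, 16))
        np.testing.assert_allclose(out[2:-3], expected[2:-3], atol=1e-12)

    def test_on_grid_samples_preserved(self, rng):
        v = rng.random((8, 8, 8))
        out = tricubic_upsample(VolumeGrid(v), 2).values
        np.testing.assert_allclose(out[::2, ::2, ::2], v, atol=1e-12)

    def test_matches_separable_1d_oracle(self, rng):
        """Independently coded 1D cubic-convolution oracle applied per axis."""
        def cubic_1d(a, r):
            n = a.shape[-1]
            out = np.zeros(a.shape[:-1] + (n * r,))
            for j in range(n * r):
                p = j / r
                i0 = int(np.floor(p))
                f = p - i0
                w = [
                    0.5 * (-f + 2 * f**2 - f**3),
                    0.5 * (2 - 5 * f**2 + 3 * f**3),
                    0.5 * (f + 4 * f**2 - 3 * f**3),
                    0.5 * (-(f**2) + f**3),
                ]
                for k in range(4):
                    out[..., j] += w[k] * a[..., min(max(i0 + k - 1, 0), n - 1)]
            return out

        v = rng.random((8, 8, 8))
        out = tricubic_upsample(VolumeGrid(v), 2).values
        oracle = v
        for ax in range(3):
            oracle = np.moveaxis(cubic_1d(np.moveaxis(oracle, ax, -1), 2), -1, ax)
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_linearity(self, rng):
        x, y = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        a, b = 1.7, -0.4
        lhs = tricubic_upsample(VolumeGrid(a * x + b * y + 2.0), 2).values
        rhs = (
            a * tricubic_upsample(VolumeGrid(x + 2.0), 2).values
            + b * tricubic_upsample(VolumeGrid(y + 2.0), 2).values
            - (a + b - 1) * tricubic_upsample(VolumeGrid(np.full((8, 8, 8), 2.0)), 2).values
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_rejects_small_dims(self):
        with pytest.raises(ValueError):
            tricubic_upsample(VolumeGrid(np.zeros((8, 8, 8))[:, :, :8][:3]), 2)


class TestNonDlPipeline:
    def test_degenerate_chain_close_to_tricubic(self, t1_phantom64):
        """Noise-free, fully sampled input: the pipeline reduces to
        denoise(tricubic) which stays near the plain tricubic upsample."""
        cfg = DegradationConfig(pf_fraction=1.0, rician_sigma=0.0, seed=0)
        inp, _ = simulate_ulf_pair(t1_phantom64.volume, cfg)
        mask = make_pf_mask((32, 32), 1.0, 1.0)
        out = non_dl_pipeline(inp, mask)
        plain = tricubic_upsample(inp, 2)
        assert nrmse(out.values, plain.values) < 0.02

    def test_beats_zero_fill_plus_trilinear(self, ulf_pair64):
        inp, tgt = ulf_pair64
        mask = make_pf_mask((32, 32), 0.7, 0.7)
        out = non_dl_pipeline(inp, mask)
        zf_tri = trilinear_upsample(inp, 2)
        assert nrmse(out.values, tgt.values) < nrmse(zf_tri.values, tgt.values)

    def test_deterministic(self, ulf_pair64):
        inp, _ = ulf_pair64
        mask = make_pf_mask((32, 32), 0.7, 0.7)
        a = non_dl_pipeline(inp, mask)
        b = non_dl_pipeline(inp, mask)
        np.testing.assert_array_equal(a.values, b.values)
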