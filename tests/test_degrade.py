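"""Degradation chain: downsampling, PF masks, zero-fill, Rician noise, normalisation."""

import math
import warnings

import numpy as np
import pytest

from pfsr.degrade import (
    DegradationConfig, SamplingMask,
    add_rician_noise, broadcast_mask, kspace_truncate, local_mean_downsample,
    make_pf_mask, normalize_unit, simulate_ulf_pair, zero_fill_reconstruct,
)
from pfsr.grid import VolumeGrid, fft_centered


def vol(arr, **kw):
    return VolumeGrid(np.asarray(arr, dtype=np.float64), **kw)


class TestLocalMeanDownsample:
    def test_constant_preserved(self):
        out = local_mean_downsample(vol(np.full((16, 16, 16), 3.25)), 2)
        np.testing.assert_allclose(out.values, 3.25)
        assert out.voxel_mm == 3.0

    def test_block_of_0_to_7_averages_to_3_5(self):
        tiled = np.tile(np.arange(8, dtype=float).reshape(2, 2, 2), (8, 8, 8))
        out = local_mean_downsample(vol(tiled), 2)
        np.testing.assert_allclose(out.values, 3.5, atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        v = rng.random((16, 16, 16))
        out = local_mean_downsample(vol(v), 2).values
        oracle = np.empty((8, 8, 8))
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    oracle[i, j, k] = v[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * k : 2 * k + 2].mean()
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_global_mean_preserved(self, rng):
        v = rng.random((32, 32, 32))
        out = local_mean_downsample(vol(v), 4)
        assert np.isclose(out.values.mean(), v.mean(), rtol=1e-12)

    def test_non_divisible_names_axis(self):
        with pytest.raises(ValueError, match="axis 1"):
            local_mean_downsample(vol(np.zeros((16, 17, 16))), 2)


class TestKspaceTruncate:
    def test_factor_one_identity(self, rng):
        v = rng.random((8, 8, 8))
        out = kspace_truncate(vol(v), 1)
        np.testing.assert_allclose(out.values, v, rtol=1e-10)

    def test_constant_preserved(self):
        out = kspace_truncate(vol(np.full((16, 16, 16), 0.7)), 2)
        np.testing.assert_allclose(out.values, 0.7, atol=1e-10)
        assert out.voxel_mm == 3.0

    def test_gibbs_overshoot_matches_direct_dft_oracle(self):
        """Truncating a centered box produces ringing overshoot; verified
        against an independently coded, explicit centered-DFT oracle."""
        n, f = 16, 2
        v = np.zeros((n, n, n))
        v[4:12, 4:12, 4:12] = 1.0
        out = kspace_truncate(vol(v), f).values

        # oracle: explicit DFT matrices with centered frequency/space indexing
        m = n // f
        idx_n = np.arange(n) - n // 2
        idx_m = np.arange(m) - m // 2
        F = np.exp(-2j * np.pi * np.outer(idx_n, idx_n) / n) / np.sqrt(n)  # n-point centered DFT
        B = np.exp(2j * np.pi * np.outer(idx_m, idx_m) / m) / np.sqrt(m)  # m-point inverse
        spec = np.einsum("ai,bj,ck,ijk->abc", F, F, F, v)
        keep = slice(n // 2 - m // 2, n // 2 - m // 2 + m)
        oracle = np.einsum("ia,jb,kc,abc->ijk", B, B, B, spec[keep, keep, keep]).real * f ** (-1.5)

        np.testing.assert_allclose(out, oracle, atol=1e-9)
        assert out.max() > v.max()  # Gibbs overshoot


class TestPfMask:
    def test_full_sampling_all_ones(self):
        m = make_pf_mask((64, 64), 1.0, 1.0)
        assert m.n_sampled == 64 * 64

    def test_point_count_at_paper_fraction(self):
        m = make_pf_mask((64, 64), 0.7, 0.7)
        assert m.n_sampled == 45 * 45
        # per-axis line counts
        assert m.values.any(axis=1).sum() == 45
        assert m.values.any(axis=0).sum() == 45

    @pytest.mark.parametrize("n", [8, 17, 32, 33, 64, 128])
    @pytest.mark.parametrize("f", [0.6, 0.7, 0.8, 1.0])
    def test_count_formula(self, n, f):
        m = make_pf_mask((n, n), f, f)
        assert m.n_sampled == math.ceil(f * n) ** 2

    def test_symmetric_center_band_present(self):
        m = make_pf_mask((64, 64), 0.7, 0.7)
        c = 32
        w = math.ceil(0.7 * 64) - 1 - c  # symmetric half-width
        assert m.values[c - w : c + w + 1, c - w : c + w + 1].all()

    def test_elliptical_count_matches_point_in_ellipse_oracle(self):
        n = 64
        m = make_pf_mask((n, n), 1.0, 1.0, elliptical=True)
        count = 0
        c = n // 2
        for i in range(n):
            for j in range(n):
                if ((i - c) / c) ** 2 + ((j - c) / c) ** 2 <= 1.0:
                    count += 1
        assert m.n_sampled == count

    def test_rejects_half_or_less(self):
        with pytest.raises(ValueError, match="0.5"):
            make_pf_mask((64, 64), 0.5, 0.7)


class TestZeroFill:
    def test_all_ones_mask_is_identity_on_magnitude(self, rng):
        v = rng.random((16, 16, 16))
        m = make_pf_mask((16, 16), 1.0, 1.0)
        out = zero_fill_reconstruct(vol(v), m)
        np.testing.assert_allclose(out.values, np.abs(v), atol=1e-10)

    def test_zero_mask_gives_zero(self, rng):
        m = SamplingMask(np.zeros((16, 16), dtype=bool), 0.7, 0.7)
        out = zero_fill_reconstruct(vol(rng.random((16, 16, 16))), m)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-14)

    def test_pf_blurs_pe_axes_only_for_separable_input(self, rng):
        """A separable volume keeps its readout profile exactly (the mask is
        constant along readout), while the PE-plane pattern changes."""
        a = 0.5 + rng.random(16)
        b = 0.5 + rng.random(16)
        c = 0.5 + rng.random(16)
        v = np.einsum("i,j,k->ijk", a, b, c)
        m = make_pf_mask((16, 16), 0.7, 0.7)
        out = zero_fill_reconstruct(vol(v), m).values
        assert np.sqrt(np.mean((out - v) ** 2)) > 0
        # normalised readout profiles coincide at every PE location
        prof = out / out[0]
        ref = v / v[0]
        np.testing.assert_allclose(prof, ref, rtol=1e-8)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mask shape"):
            zero_fill_reconstruct(vol(rng.random((16, 16, 16))), make_pf_mask((8, 8), 0.7, 0.7))


class TestRicianNoise:
    def test_sigma_zero_identity(self, rng):
        v = vol(rng.random((8, 8, 8)))
        out = add_rician_noise(v, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, v.values)

    def test_rayleigh_mean_at_zero_signal(self):
        v = vol(np.zeros((100, 100, 100)))
        out = add_rician_noise(v, 1.0, seed=2)
        se = np.sqrt((2 - np.pi / 2)) / np.sqrt(v.values.size)  # Rayleigh SD / sqrt(n)
        assert abs(out.values.mean() - np.sqrt(np.pi / 2)) < 3 * se

    def test_high_snr_mean(self):
        v = vol(np.full((100, 100, 100), 100.0))
        out = add_rician_noise(v, 1.0, seed=3)
        se = 1.0 / np.sqrt(v.values.size)
        assert abs(out.values.mean() - np.sqrt(100.0**2 + 1.0)) < 3 * se

    @pytest.mark.parametrize("sigma", [0.01, 0.05, 0.1])
    @pytest.mark.parametrize("amp", [0.0, 0.5, 1.0])
    def test_second_moment_identity(self, sigma, amp):
        """E[M²] = A² + 2σ² holds exactly for Rician magnitudes."""
        v = vol(np.full((64, 64, 64), amp))
        out = add_rician_noise(v, sigma, seed=17)
        m2 = (out.values**2).mean()
        expected = amp**2 + 2 * sigma**2
        sd_m2 = np.sqrt(np.var(out.values**2) / v.values.size)
        assert abs(m2 - expected) < 4 * sd_m2 + 1e-12

    def test_rejects_negative_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            add_rician_noise(vol(np.zeros((8, 8, 8))), -0.1, seed=0)


class TestNormalizeUnit:
    def test_affine_map(self):
        v = np.linspace(-2, 6, 8 * 8 * 8).reshape(8, 8, 8)
        out = normalize_unit(vol(v)).values
        assert out.min() == 0.0 and out.max() == 1.0
        np.testing.assert_allclose(out[np.isclose(v, 2.0)], 0.5, atol=1e-12)

    def test_idempotent(self, rng):
        v = rng.random((8, 8, 8))
        v.flat[0], v.flat[-1] = 0.0, 1.0
        out = normalize_unit(vol(v))
        np.testing.assert_allclose(out.values, v, atol=1e-12)

    def test_constant_volume_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_unit(vol(np.full((8, 8, 8), 3.0)))
        np.testing.assert_array_equal(out.values, 0.0)


class TestSimulateUlfPair:
    def test_grids_and_spacing(self, t1_phantom64):
        inp, tgt = simulate_ulf_pair(t1_phantom64.volume, DegradationConfig(seed=1))
        assert tgt.shape == (64, 64, 64) and inp.shape == (32, 32, 32)
        assert tgt.voxel_mm == 1.5 and inp.voxel_mm == 3.0
        for v in (inp, tgt):
            assert v.values.min() >= 0.0 and v.values.max() <= 1.0

    def test_deterministic(self, t1_phantom64):
        cfg = DegradationConfig(seed=5)
        a = simulate_ulf_pair(t1_phantom64.volume, cfg)
        b = simulate_ulf_pair(t1_phantom64.volume, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_no_degradation_limit(self, t1_phantom64):
        """sigma=0, f=1: the input equals the normalised magnitude of the
        truncated target (the chain's no-noise, fully sampled limit)."""
        cfg = DegradationConfig(pf_fraction=1.0, rician_sigma=0.0, seed=0)
        inp, tgt = simulate_ulf_pair(t1_phantom64.volume, cfg)
        low = kspace_truncate(tgt, 2)
        expected = normalize_unit(low.with_values(np.abs(low.values)))
        np.testing.assert_allclose(inp.values, expected.values, atol=1e-6)

    def test_parseval_bound(self, t1_phantom64):
        """Masked spectrum energy is strictly below the full-spectrum energy
        for f < 1 and equal at f = 1 (orthonormal transforms)."""
        tgt = normalize_unit(t1_phantom64.volume)
        low = kspace_truncate(tgt, 2)
        spec = fft_centered(low.values)
        full = np.sum(np.abs(spec) ** 2)
        m = make_pf_mask((32, 32), 0.7, 0.7)
        masked = np.sum(np.abs(spec * broadcast_mask(m, low)) ** 2)
        assert masked < full
        m1 = make_pf_mask((32, 32), 1.0, 1.0)
        np.testing.assert_allclose(np.sum(np.abs(spec * broadcast_mask(m1, low)) ** 2), full)
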