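import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spadspec as sp
from spadspec.preprocess import (
    PreprocessingChain,
    apply_chain,
    detrend,
    msc,
    sg_smooth,
    snv,
)

WL = np.arange(325, 1076, dtype=float)


class TestSavitzkyGolay:
    def test_reproduces_quadratic_exactly(self):
        x = 1e-6 * (WL - 700) ** 2 + 0.1
        np.testing.assert_allclose(sg_smooth(x, 15, 2), x, atol=1e-9)

    def test_constant_unchanged(self):
        x = np.full(WL.size, 0.42)
        np.testing.assert_allclose(sg_smooth(x), x, atol=1e-12)

    def test_reduces_noise_around_smooth_truth(self):
        rng = np.random.default_rng(0)
        truth = 0.3 + 0.1 * np.sin(WL / 60)
        noisy = truth + rng.normal(0, 0.01, WL.size)
        smoothed = sg_smooth(noisy, 15, 2)
        assert np.var(smoothed - truth) < np.var(noisy - truth)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            sg_smooth(np.ones(100), window=14)

    def test_window_exceeding_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            sg_smooth(np.ones(9), window=11)


class TestSNV:
    def test_three_point_hand_value(self):
        # (x - mean)/sd with the n-1 denominator: {0.1,0.2,0.3} -> {-1,0,1}
        np.testing.assert_allclose(snv(np.array([0.1, 0.2, 0.3])), [-1, 0, 1], atol=1e-12)

    def test_output_mean_zero_sd_one(self, small_clean_set):
        samples, _ = small_clean_set
        z = snv(samples.reflectance)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    @given(
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.05, 0.6, 200)
        np.testing.assert_allclose(snv(a * x + b), snv(x), atol=1e-8)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 100)
        np.testing.assert_allclose(snv(snv(x)), snv(x), atol=1e-12)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(np.full(10, 0.3))


class TestDetrend:
    def test_annihilates_polynomial_of_fit_degree(self):
        x = 2.0 + 0.001 * WL + 1e-6 * WL**2
        np.testing.assert_allclose(detrend(x, WL, 2), 0, atol=1e-9)

    def test_residual_orthogonal_to_polynomial_basis(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, WL.size)
        r = detrend(x, WL, 2)
        t = (WL - WL.mean()) / (WL.max() - WL.min())
        for p in range(3):
            assert abs(np.dot(r, t**p)) < 1e-9 * WL.size

    def test_added_linear_ramp_has_no_effect(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, WL.size)
        ramp = 0.5 + 0.002 * WL
        np.testing.assert_allclose(detrend(x + ramp, WL, 2), detrend(x, WL, 2), atol=1e-9)


class TestMSC:
    def test_closed_form_inversion(self):
        ref = 0.2 + 0.3 * np.sin(WL / 100) ** 2
        corrupted = 0.5 + 2.0 * ref
        out, used_ref = msc(corrupted, reference=ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-12)
        np.testing.assert_array_equal(used_ref, ref)

    def test_reference_is_fixed_point(self):
        ref = 0.2 + 0.3 * np.sin(WL / 100) ** 2
        out, _ = msc(ref, reference=ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-12)

    def test_scatter_pair_of_one_leaf_collapses(self):
        # two noise-free renderings of one latent leaf under different
        # gain/offset must agree after MSC against the latent spectrum
        wl_int = sp.DEFAULT_WAVELENGTHS
        latent = sp.synth.generate_spectrum(0.06, wl_int)
        a = 1.3 * latent + 0.05
        b = 0.8 * latent - 0.02
        out, _ = msc(np.vstack([a, b]), reference=latent)
        pre = np.linalg.norm(a - b)
        post = np.linalg.norm(out[0] - out[1])
        assert post < 0.05 * pre
        np.testing.assert_allclose(out[0], out[1], atol=1e-9)

    def test_near_zero_slope_rejected(self):
        ref = np.linspace(0.1, 0.5, 100)
        flat = np.full(100, 0.3) + np.random.default_rng(0).normal(0, 1e-12, 100)
        with pytest.raises(ValueError, match="slope"):
            msc(flat, reference=ref)


class TestChains:
    def test_sg_must_lead(self):
        with pytest.raises(ValueError, match="first"):
            PreprocessingChain(("SNV", "SG"))

    def test_tag_and_shape_preserved(self, default_group_set):
        samples, _ = default_group_set
        out = apply_chain(samples, "SG-SNV-DT")
        assert out.preprocessing_tag == "SG-SNV-DT"
        assert out.reflectance.shape == samples.reflectance.shape
        assert out.sample_ids == samples.sample_ids

    def test_sg_snv_dt_output_centred(self, default_group_set):
        samples, _ = default_group_set
        out = apply_chain(samples, "SG-SNV-DT")
        np.testing.assert_allclose(out.reflectance.mean(axis=1), 0, atol=1e-9)

    def test_msc_reference_recorded_per_group(self, default_group_set):
        samples, _ = default_group_set
        chain = PreprocessingChain.from_tag("SG-MSC")
        apply_chain(samples, chain)
        assert len(chain.fitted_msc_references_) == 9
        for ref in chain.fitted_msc_references_.values():
            assert ref.shape == samples.wavelengths.shape

    def test_snv_and_msc_both_remove_pure_scatter(self):
        wl_int = sp.DEFAULT_WAVELENGTHS
        latent = sp.synth.generate_spectrum(0.055, wl_int)
        pair = np.vstack([1.4 * latent + 0.03, 0.7 * latent - 0.04])
        z = snv(pair)
        np.testing.assert_allclose(z[0], z[1], atol=1e-9)
        m, _ = msc(pair, reference=latent)
        np.testing.assert_allclose(m[0], m[1], atol=1e-9)
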