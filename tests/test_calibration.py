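"""Sequential correction model: amplitude and profile fits, decomposition,
and the sklearn transformer surface."""

import numpy as np
import pytest
from sklearn.base import clone

from mifcal import (
    AmplitudeCorrection,
    AmplitudeFactors,
    AmplitudeTable,
    MicroscopeProfileCorrection,
    SpectraTensor,
    TissueProfileCorrection,
    apply_amplitude,
    apply_microscope_profile,
    apply_tissue_profile,
    decompose_microscope_profile,
    fit_amplitude_factors,
    fit_microscope_profile,
    fit_tissue_profile,
    make_calibration_pipeline,
)
from mifcal.io import FilterGroup, FilterLayout


def _model_tensor(rng, N=4, M=3, R=2, K=6, noise=0.01):
    """Multiplicative-model tensor with mean-one planted factors."""
    B = np.exp(rng.normal(0, 0.15, N))
    B /= B.mean()
    C = np.exp(rng.normal(0, 0.1, M))
    C /= C.mean()
    b = np.exp(rng.normal(0, 0.1, (N, K)))
    b /= b.mean(axis=0)
    w = np.exp(rng.normal(0, 0.1, (M, K)))
    w /= w.mean(axis=0)
    core = (B[:, None, None, None] * C[None, :, None, None]
            * b[:, None, None, :] * w[None, :, None, :])
    vals = core * np.ones((N, M, R, K))
    if noise:
        vals = vals * (1.0 + noise * rng.standard_normal(vals.shape))
    return SpectraTensor(vals, stage="X"), (B, C, b, w)


class TestAmplitudeFactors:
    def test_printed_two_by_two_example(self):
        a = np.array([[[1.2], [0.8]], [[1.1], [0.9]]])  # (N=2, M=2, R=1)
        f = fit_amplitude_factors(AmplitudeTable(a))
        np.testing.assert_allclose(f.B_n, [1.0, 1.0], atol=1e-15)
        np.testing.assert_allclose(f.C_m, [1.15, 0.85], atol=1e-15)

    def test_unit_amplitudes_give_unit_factors(self):
        f = fit_amplitude_factors(AmplitudeTable(np.ones((3, 2, 2))))
        assert np.all(f.B_n == 1.0) and np.all(f.C_m == 1.0)

    def test_sample_only_dependence_leaves_microscopes_at_one(self, rng):
        v = rng.random(4) + 0.5
        a = np.broadcast_to(v[:, None, None], (4, 3, 2)).copy()
        f = fit_amplitude_factors(AmplitudeTable(a))
        np.testing.assert_allclose(f.C_m, v.mean(), atol=1e-15)
        np.testing.assert_allclose(f.C_m / f.C_m.mean(), 1.0, atol=1e-15)

    def test_apply_identity_and_roundtrip(self, rng):
        X, _ = _model_tensor(rng)
        ident = AmplitudeFactors(np.ones(X.N), np.ones(X.M))
        np.testing.assert_array_equal(apply_amplitude(X, ident).values, X.values)
        f = fit_amplitude_factors(AmplitudeTable(rng.random((X.N, X.M, X.R)) + 0.5))
        x = apply_amplitude(X, f)
        back = x.values * f.B_n[:, None, None, None] * f.C_m[None, :, None, None]
        np.testing.assert_allclose(back, X.values, atol=1e-12)

    def test_perfect_model_flattens_to_one(self):
        B = np.array([0.8, 1.2])
        C = np.array([1.1, 0.9])
        X = SpectraTensor(B[:, None, None, None] * C[None, :, None, None]
                          * np.ones((2, 2, 1, 3)), stage="X")
        x = apply_amplitude(X, AmplitudeFactors(B, C))
        np.testing.assert_allclose(x.values, 1.0, atol=1e-15)

    def test_gauge_only_product_matters(self, rng):
        X, _ = _model_tensor(rng)
        f = fit_amplitude_factors(AmplitudeTable(rng.random((X.N, X.M, X.R)) + 0.5))
        g = AmplitudeFactors(f.B_n * 2.5, f.C_m / 2.5)
        np.testing.assert_allclose(
            apply_amplitude(X, f).values, apply_amplitude(X, g).values, rtol=1e-14
        )


class TestProfiles:
    def test_tissue_profile_unit_input(self):
        p = fit_tissue_profile(SpectraTensor(np.ones((2, 2, 1, 3)), stage="x"))
        np.testing.assert_allclose(p.b_nk, 1.0, atol=1e-15)

    def test_two_sample_symmetric_profile(self):
        vals = np.ones((2, 2, 2, 3))
        vals[0, :, :, 1] = 1.2
        vals[1, :, :, 1] = 0.8
        p = fit_tissue_profile(SpectraTensor(vals, stage="x"))
        np.testing.assert_allclose(p.b_nk[:, 1], [1.2, 0.8], atol=1e-12)

    def test_tissue_gauge_per_layer_mean_one(self, rng):
        p = fit_tissue_profile(SpectraTensor(rng.random((4, 3, 2, 5)) + 0.2, stage="x"))
        np.testing.assert_allclose(p.b_nk.mean(axis=0), 1.0, atol=1e-12)

    def test_tissue_apply_roundtrip(self, rng):
        x = SpectraTensor(rng.random((3, 2, 2, 4)) + 0.2, stage="x")
        p = fit_tissue_profile(x)
        y = apply_tissue_profile(x, p)
        np.testing.assert_allclose(y.values * p.b_nk[:, None, None, :], x.values,
                                   atol=1e-12)

    def test_microscope_profile_mirror_cases(self, rng):
        p = fit_microscope_profile(SpectraTensor(np.ones((2, 3, 1, 2)), stage="y"))
        np.testing.assert_allclose(p.w_mk, 1.0, atol=1e-15)
        vals = np.ones((2, 3, 2, 2))
        vals[:, 0, :, 0] = 1.2
        vals[:, 2, :, 0] = 0.8
        p = fit_microscope_profile(SpectraTensor(vals, stage="y"))
        np.testing.assert_allclose(p.w_mk[:, 0], [1.2, 1.0, 0.8], atol=1e-12)
        y = SpectraTensor(rng.random((2, 3, 2, 4)) + 0.2, stage="y")
        p = fit_microscope_profile(y)
        np.testing.assert_allclose(p.w_mk.mean(axis=0), 1.0, atol=1e-12)
        z = apply_microscope_profile(y, p)
        np.testing.assert_allclose(z.values * p.w_mk[None, :, None, :], y.values,
                                   atol=1e-12)


class TestDecomposition:
    def test_constant_profile_decomposes_trivially(self):
        layout = FilterLayout((FilterGroup("a", (0, 1)), FilterGroup("b", (2, 3))))
        w = np.full((2, 4), 1.0)
        w[1] = 0.7
        d = decompose_microscope_profile(w, layout)
        np.testing.assert_allclose(d.w_ill, [1.0, 0.7], atol=1e-15)
        np.testing.assert_allclose(d.w_bb, 1.0, atol=1e-15)
        np.testing.assert_allclose(d.w_nb, 1.0, atol=1e-15)

    def test_group_constant_profile(self):
        layout = FilterLayout((FilterGroup("a", (0, 1)), FilterGroup("b", (2, 3))))
        w = np.array([[1.2, 1.2, 0.8, 0.8]])
        d = decompose_microscope_profile(w, layout)
        assert d.w_ill[0] == pytest.approx(1.0)
        np.testing.assert_allclose(d.w_bb[0], [1.2, 1.2, 0.8, 0.8], atol=1e-12)
        np.testing.assert_allclose(d.w_nb[0], 1.0, atol=1e-12)

    def test_random_profiles_reconstruct_exactly(self, rng):
        layout = FilterLayout((FilterGroup("a", (0, 1, 2)), FilterGroup("b", (3, 4)),
                               FilterGroup("c", (5, 6, 7))))
        for _ in range(25):
            w = np.exp(rng.normal(0, 0.2, (3, 8)))
            d = decompose_microscope_profile(w, layout)
            np.testing.assert_allclose(d.reconstruct(), w, atol=1e-12)
            for g in layout.groups:
                np.testing.assert_allclose(d.w_nb[:, list(g.layers)].mean(axis=1),
                                           1.0, atol=1e-9)


class TestSequentialModel:
    def test_refit_on_corrected_spectra_is_idempotent(self, rng):
        # exact idempotence is a noiseless-model property; noise perturbs the
        # refit at second order
        X, _ = _model_tensor(rng, noise=0.0)
        pipe = make_calibration_pipeline().fit(X)
        z = pipe.transform(X)
        from mifcal import amplitude_summary

        f2 = fit_amplitude_factors(amplitude_summary(z))
        np.testing.assert_allclose(f2.B_n, 1.0, atol=1e-9)
        np.testing.assert_allclose(f2.C_m, 1.0, atol=1e-9)
        x2 = apply_amplitude(z, f2)
        p2 = fit_tissue_profile(x2)
        np.testing.assert_allclose(p2.b_nk, 1.0, atol=1e-9)
        y2 = apply_tissue_profile(x2, p2)
        np.testing.assert_allclose(fit_microscope_profile(y2).w_mk, 1.0, atol=1e-9)

    def test_variance_shrinks_at_every_stage(self, rng):
        from mifcal import layer_std

        X, _ = _model_tensor(rng, N=6, M=3, R=2, K=8, noise=0.01)
        amp = AmplitudeCorrection().fit(X)
        x = amp.transform(X)
        tis = TissueProfileCorrection().fit(x)
        y = tis.transform(x)
        mic = MicroscopeProfileCorrection().fit(y)
        z = mic.transform(y)
        stds = [layer_std(t).mean_sigma for t in (X, x, y, z)]
        assert stds[0] > stds[1] > stds[2] > stds[3]

    def test_factors_recovered_within_noise(self, rng):
        # Gauge-fixed truth = the noiseless fit; the noisy fit must agree
        # within 3 sigma / sqrt(number of entries averaged), elementwise.
        sigma = 0.01
        X, _ = _model_tensor(rng, N=6, M=3, R=2, K=8, noise=0.0)
        noisy = SpectraTensor(
            X.values * (1.0 + sigma * rng.standard_normal(X.values.shape)), stage="X"
        )

        def fit_all(t):
            from mifcal import amplitude_summary

            f = fit_amplitude_factors(amplitude_summary(t))
            x = apply_amplitude(t, f)
            p = fit_tissue_profile(x)
            y = apply_tissue_profile(x, p)
            return f, p, fit_microscope_profile(y)

        f0, p0, m0 = fit_all(X)
        f1, p1, m1 = fit_all(noisy)
        N, M, R, K = X.values.shape
        assert np.abs(f1.B_n - f0.B_n).max() < 3 * sigma / np.sqrt(M * R * K)
        assert np.abs(f1.C_m - f0.C_m).max() < 3 * sigma / np.sqrt(N * R * K)
        assert np.abs(p1.b_nk - p0.b_nk).max() < 3 * sigma / np.sqrt(M * R)
        assert np.abs(m1.w_mk - m0.w_mk).max() < 3 * sigma / np.sqrt(N * R)


class TestSklearnSurface:
    def test_estimators_clone_and_expose_fitted_attributes(self, rng):
        X, _ = _model_tensor(rng)
        est = AmplitudeCorrection()
        clone(est)  # parameterless estimators must still be cloneable
        est.fit(X)
        assert hasattr(est, "B_n_") and hasattr(est, "C_m_")
        assert est.B_n_.shape == (X.N,)

    def test_pipeline_matches_manual_chain(self, rng):
        from mifcal import amplitude_summary

        X, _ = _model_tensor(rng)
        pipe = make_calibration_pipeline()
        z_pipe = pipe.fit_transform(X)
        f = fit_amplitude_factors(amplitude_summary(X))
        x = apply_amplitude(X, f)
        p = fit_tissue_profile(x)
        y = apply_tissue_profile(x, p)
        z = apply_microscope_profile(y, fit_microscope_profile(y))
        np.testing.assert_allclose(z_pipe.values, z.values, atol=1e-14)
        assert z_pipe.stage == "z"

    def test_transformers_accept_plain_arrays(self, rng):
        vals = rng.random((3, 2, 2, 4)) + 0.2
        z = make_calibration_pipeline().fit_transform(vals)
        assert isinstance(z, np.ndarray)
        assert z.shape == vals.shape
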