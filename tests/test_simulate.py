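"""Synthetic-data generator: determinism, closed-form agreement, gauge fixing."""

import hashlib
from dataclasses import replace

import numpy as np
import pytest

from mifcal import (
    SimulationConfig,
    TruthModel,
    build_xbar,
    gauge_fix_truth,
    grand_normalize,
    hpf_fraction_weight,
    simulate_dataset,
    simulate_to_disk,
)


def _flat_truth(config, seed=0, **over):
    """Truth with every factor flat (no sample/microscope differences)."""
    truth = TruthModel.random(config, seed=seed, bb_max=0.0, sample_amp_sigma=0.0,
                              scope_amp_sigma=0.0, tissue_ripple=0.0, illum_sigma=0.0,
                              nb_ripple_amp=0.0, noise_cv=0.0, scan_jitter=0.0,
                              saturation_fraction=0.0)
    over.setdefault("background_flux", 0.0)
    return replace(truth, texture_sigma=0.0, **over)


class TestGeneration:
    def test_noise_free_flat_truth_gives_constant_tissue(self):
        config = SimulationConfig(n_samples=2, n_microscopes=1, height=16, width=16,
                                  n_layers=4, n_groups=2, hpfs_per_scan=2)
        ds = simulate_dataset(config, _flat_truth(config), quantize=False)
        for scan in ds.scans:
            for flux, mask in ds.iter_scan(scan):
                tissue_vals = flux.pixels[mask.mask.astype(bool)]
                for k in range(4):
                    assert np.ptp(tissue_vals[:, k]) < 1e-9

    def test_same_seed_is_byte_identical(self, tmp_path):
        config = SimulationConfig(n_samples=2, n_microscopes=2, height=12, width=12,
                                  n_layers=4, n_groups=2, hpfs_per_scan=2)
        truth = TruthModel.random(config, seed=9)
        a = simulate_dataset(config, truth)
        b = simulate_dataset(config, truth)
        for key in a.counts:
            for t1, t2 in zip(a.counts[key], b.counts[key]):
                assert np.array_equal(t1, t2)
        d1 = tmp_path / "run1"
        d2 = tmp_path / "run2"
        simulate_to_disk(a, d1)
        simulate_to_disk(b, d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            h1 = hashlib.sha256((d1 / rel).read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / rel).read_bytes()).hexdigest()
            assert h1 == h2, rel

    def test_saturated_pixels_appear_at_configured_rate_and_are_masked(self):
        config = SimulationConfig(n_samples=2, n_microscopes=1, n_scan_repeats=1,
                                  hpfs_per_scan=2)
        truth = TruthModel.random(config, seed=3, saturation_fraction=0.01)
        ds = simulate_dataset(config, truth)
        total = sat = unmasked_sat = 0
        for scan in ds.scans:
            for h, tile in enumerate(ds.counts[scan.key]):
                hot = (tile > 65500).any(axis=2)
                total += hot.size
                sat += hot.sum()
                flux, mask = list(ds.iter_scan(scan))[h]
                unmasked_sat += (hot & mask.mask.astype(bool)).sum()
        assert sat / total == pytest.approx(0.01, abs=0.01)
        assert unmasked_sat == 0  # every saturated pixel is masked out

    def test_fully_saturating_configuration_rejected(self):
        config = SimulationConfig(n_samples=1, n_microscopes=1, n_scan_repeats=1,
                                  height=8, width=8, n_layers=2, n_groups=1,
                                  hpfs_per_scan=1, tissue_fraction=1.0)
        truth = _flat_truth(config, signal_flux=1e9, background_flux=1e9)
        with pytest.raises(ValueError, match="saturates"):
            simulate_dataset(config, truth)


class TestClosedForm:
    def test_reduction_matches_analytic_product_formula(self):
        """Noiseless flux pushed through the mean-image/layer-mean/weighting/
        normalization chain with all-ones masks equals the direct product
        formula evaluated on the scene averages."""
        from mifcal import TissueMask

        config = SimulationConfig(n_samples=3, n_microscopes=2, height=12, width=12,
                                  n_layers=4, n_groups=2, hpfs_per_scan=2)
        truth = replace(TruthModel.random(config, seed=4), noise_cv=0.0,
                        scan_jitter=0.0, saturation_fraction=0.0)
        ds = simulate_dataset(config, truth, quantize=False)

        class AllOnesMasks:
            sample_ids = ds.sample_ids
            microscope_ids = ds.microscope_ids
            scans = ds.scans
            K = ds.K
            n_scan_repeats = ds.n_scan_repeats
            layout = ds.layout

            def iter_scan(self, scan):
                for flux, mask in ds.iter_scan(scan):
                    ones = TissueMask(mask=np.ones_like(mask.mask), n_background=0,
                                      n_saturated=0, otsu_threshold=None,
                                      degenerate=False, scan=scan.key, tile_id="t")
                    yield flux, ones

        xbar, hmrn = build_xbar(AllOnesMasks())
        X = grand_normalize(hpf_fraction_weight(xbar, hmrn))

        # analytic expectation from the generative product formula
        omega = truth.omega_mk(config.layout)
        N, M, R, K = X.values.shape
        expected = np.empty((N, M, R, K))
        for n in range(N):
            scene = np.mean([
                sc.region[:, :, None] * sc.scene_spectrum(truth, K)
                for sc in ds.scenes[n]
            ], axis=(0, 1, 2))  # per-layer mean over tiles and pixels
            for m in range(M):
                per_k = (truth.background_flux
                         + truth.signal_flux * truth.A_n[n] * truth.g_m[m]
                         * truth.t_nk[n] * omega[m] * scene)
                expected[n, m, :] = per_k
        expected *= (config.hpf_counts()[:, None, None, None] /
                     config.hpf_counts().sum() / (M * R))
        expected /= expected.mean()
        np.testing.assert_allclose(X.values, expected, rtol=1e-10)


class TestGaugeFixing:
    def test_separable_normalized_truth_is_returned_unchanged(self):
        config = SimulationConfig(n_samples=3, n_microscopes=2, height=8, width=8,
                                  n_layers=4, n_groups=2, hpfs_per_scan=1,
                                  tissue_fraction=1.0)
        truth = _flat_truth(config)
        A = np.array([0.8, 1.0, 1.2])
        g = np.array([0.9, 1.1])
        truth = replace(truth, A_n=A, g_m=g)
        gt = gauge_fix_truth(truth, config)
        np.testing.assert_allclose(gt.B_n, A, atol=1e-12)
        np.testing.assert_allclose(gt.C_m, g, atol=1e-12)
        np.testing.assert_allclose(gt.b_nk, 1.0, atol=1e-12)
        np.testing.assert_allclose(gt.w_mk, 1.0, atol=1e-12)

    def test_global_amplitude_scale_is_gauge_invariant(self):
        config = SimulationConfig(n_samples=3, n_microscopes=2, height=8, width=8,
                                  n_layers=4, n_groups=2, hpfs_per_scan=1,
                                  tissue_fraction=1.0)
        truth = _flat_truth(config)
        truth = replace(truth, A_n=np.array([0.8, 1.0, 1.2]))
        scaled = replace(truth, A_n=truth.A_n * 10.0)
        np.testing.assert_allclose(gauge_fix_truth(scaled, config).B_n,
                                   gauge_fix_truth(truth, config).B_n, atol=1e-12)

    def test_noiseless_fit_equals_gauge_fixed_truth(self):
        from mifcal import run_full_calibration, RunConfig

        config = SimulationConfig(n_samples=4, n_microscopes=2, height=24, width=24,
                                  n_layers=6, n_groups=2, hpfs_per_scan=2)
        truth = replace(TruthModel.random(config, seed=6), noise_cv=0.0,
                        scan_jitter=0.0, saturation_fraction=0.0)
        ds = simulate_dataset(config, truth, quantize=False)
        report = run_full_calibration(
            ds, RunConfig(do_bootstrap=False, do_covariance=False)
        )
        gt = gauge_fix_truth(truth, config, ds.scenes)
        np.testing.assert_allclose(report.amplitude_factors.B_n, gt.B_n, atol=1e-6)
        np.testing.assert_allclose(report.amplitude_factors.C_m, gt.C_m, atol=1e-6)
        np.testing.assert_allclose(report.tissue_profile.b_nk, gt.b_nk, atol=1e-6)
        np.testing.assert_allclose(report.microscope_profile.w_mk, gt.w_mk, atol=1e-6)
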