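"""End-to-end orchestration: mask -> spectra -> calibrate -> diagnose ->
bootstrap -> standardize -> unmix-compare.

``run_full_calibration`` drives the whole procedure on any dataset object
exposing the small duck-typed surface used throughout the package
(``sample_ids``, ``microscope_ids``, ``n_scan_repeats``, ``K``, ``scans``,
``iter_scan``): either a :class:`DiskDataset` wrapping an on-disk manifest
or an in-memory :class:`~mifcal.simulate.SimulatedDataset`.  The run is
deterministic given the dataset and configuration (the bootstrap is
exhaustive by default), and every output file carries the configuration
hash in a leading comment line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .bootstrap import BootstrapConfig, BootstrapSummary, run_bootstrap, tissue_homogenize
from .calibration import (
    AmplitudeFactors,
    MicroscopeProfile,
    TissueProfile,
    WmkDecomposition,
    apply_amplitude,
    apply_microscope_profile,
    apply_tissue_profile,
    decompose_microscope_profile,
    fit_amplitude_factors,
    fit_microscope_profile,
    fit_tissue_profile,
)
from .diagnostics import CovarianceReport, LayerStdReport, covariance_matrix, layer_std
from .io import DatasetManifest, ScanRecord, exposure_normalize, read_dataset_manifest
from .masking import compute_tissue_mask, mask_summary
from .spectra import (
    AmplitudeTable,
    SpectraTensor,
    amplitude_summary,
    build_xbar,
    grand_normalize,
    hpf_fraction_weight,
)
from .standardize import StandardizationFactors, reference_standardization_factors
from .unmix import ScenarioResult, SpectralLibrary, scenario_compare

__all__ = ["DiskDataset", "RunConfig", "RunReport", "run_full_calibration",
           "write_report"]


class DiskDataset:
    """Adapter exposing an on-disk manifest through the dataset surface.

    Masks are computed on the fly per HPF (Otsu on the mean over all
    exposure-normalized layers, plus per-layer saturation thresholds).
    """

    def __init__(self, manifest: DatasetManifest | str | Path,
                 thresholds=None, otsu_layers=None):
        if not isinstance(manifest, DatasetManifest):
            manifest = read_dataset_manifest(manifest)
        self.manifest = manifest
        self.thresholds = thresholds
        self.otsu_layers = otsu_layers

    @property
    def sample_ids(self):
        return self.manifest.sample_ids

    @property
    def microscope_ids(self):
        return self.manifest.microscope_ids

    @property
    def scans(self):
        return self.manifest.scans

    @property
    def layout(self):
        return self.manifest.layout

    @property
    def K(self) -> int:
        return self.manifest.K

    @property
    def n_scan_repeats(self) -> int:
        return max(s.scan_index for s in self.manifest.scans) + 1

    def iter_scan(self, scan: ScanRecord):
        for hpf in self.manifest.iter_hpfs(scan):
            flux = exposure_normalize(hpf, self.manifest.exposures, self.layout)
            mask = compute_tissue_mask(
                hpf, thresholds=self.thresholds, flux=flux, otsu_layers=self.otsu_layers
            )
            yield flux, mask


@dataclass
class RunConfig:
    """Options for a full calibration run."""

    reference_microscope: str | None = None  # default: first microscope
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    do_covariance: bool = True
    do_bootstrap: bool = True
    do_scenarios: bool = True  # requires libraries
    combine: str = "product_of_means"
    exclude_components: tuple[str, ...] = ("autofluorescence",)

    def hash(self) -> str:
        doc = {
            "reference_microscope": self.reference_microscope,
            "bootstrap": [self.bootstrap.n_fit, self.bootstrap.mode,
                          self.bootstrap.n_iterations, self.bootstrap.seed],
            "do_covariance": self.do_covariance,
            "do_bootstrap": self.do_bootstrap,
            "do_scenarios": self.do_scenarios,
            "combine": self.combine,
            "exclude_components": list(self.exclude_components),
        }
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Everything a full run produces."""

    stage_tensors: dict[str, SpectraTensor]
    stage_std: dict[str, LayerStdReport]
    amplitudes: AmplitudeTable
    amplitude_factors: AmplitudeFactors
    tissue_profile: TissueProfile
    microscope_profile: MicroscopeProfile
    wmk_decomposition: WmkDecomposition
    covariances: dict[str, CovarianceReport]
    beta_nk: np.ndarray | None
    bootstrap_summary: BootstrapSummary | None
    standardization: StandardizationFactors | None
    scenarios: dict[str, ScenarioResult] | None
    mask_qc: pd.DataFrame | None
    config_hash: str


def run_full_calibration(
    dataset,
    config: RunConfig | None = None,
    libraries: Mapping[str, SpectralLibrary] | None = None,
    collect_mask_qc: bool = False,
) -> RunReport:
    """Run the complete procedure on a dataset.

    Stages: reduce HPFs to the stage-X tensor; fit/apply amplitude, tissue-
    profile and microscope-profile corrections (X -> x -> y -> z) with a
    per-stage std report; decompose w_mk by broadband group; optionally
    compute stage covariances; homogenize tissue and run the exhaustive
    bootstrap (psi, fit/test stds); derive standardization factors to the
    reference microscope; and, when per-microscope libraries are supplied,
    run the three unmixing scenarios.
    """
    config = config or RunConfig()

    mask_qc = None
    if collect_mask_qc:
        masks = [m for scan in dataset.scans for _, m in dataset.iter_scan(scan)]
        mask_qc = mask_summary(masks)

    xbar, hmrn = build_xbar(dataset)
    X = grand_normalize(hpf_fraction_weight(xbar, hmrn))
    amps = amplitude_summary(X)
    f = fit_amplitude_factors(amps)
    x = apply_amplitude(X, f)
    tp = fit_tissue_profile(x)
    y = apply_tissue_profile(x, tp)
    mp = fit_microscope_profile(y)
    z = apply_microscope_profile(y, mp)
    decomp = decompose_microscope_profile(mp, dataset.layout)

    tensors = {"X": X, "x": x, "y": y, "z": z}
    stds = {stage: layer_std(t) for stage, t in tensors.items()}
    covs = (
        {stage: covariance_matrix(t) for stage, t in tensors.items()}
        if config.do_covariance
        else {}
    )

    beta_nk = None
    summary = None
    std_factors = None
    scenarios = None
    if config.do_bootstrap:
        _, beta_nk, psi = tissue_homogenize(X, f.B_n)
        tensors["psi"] = psi
        stds["psi"] = layer_std(psi)
        summary = run_bootstrap(psi, amps, config.bootstrap)
        ref = config.reference_microscope or dataset.microscope_ids[0]
        std_factors = reference_standardization_factors(
            summary, ref, tuple(dataset.microscope_ids), combine=config.combine
        )
        if config.do_scenarios and libraries is not None:
            scenarios = scenario_compare(
                dataset, libraries, std_factors, ref,
                exclude_components=config.exclude_components,
            )

    return RunReport(
        stage_tensors=tensors,
        stage_std=stds,
        amplitudes=amps,
        amplitude_factors=f,
        tissue_profile=tp,
        microscope_profile=mp,
        wmk_decomposition=decomp,
        covariances=covs,
        beta_nk=beta_nk,
        bootstrap_summary=summary,
        standardization=std_factors,
        scenarios=scenarios,
        mask_qc=mask_qc,
        config_hash=config.hash(),
    )


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def write_report(report: RunReport, outdir: Path | str) -> Path:
    """Write all report tables as CSV under ``outdir``; returns the directory.

    Files: stage std table (stage order X, x, y, z, psi plus bootstrap
    fit/test rows), amplitude factors, profiles with the w decomposition,
    bootstrap per-iteration table, standardization factors, scenario stds,
    covariance matrices, and the mask QC table when collected.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = report.config_hash

    rows = [
        {"stage": stage, "mean_std": rep.mean_sigma, "mean_std_percent": rep.mean_percent}
        for stage, rep in report.stage_std.items()
    ]
    if report.bootstrap_summary is not None:
        s = report.bootstrap_summary
        rows.append({"stage": "z_fit", "mean_std": s.mean_fit_std,
                     "mean_std_percent": 100 * s.mean_fit_std,
                     "std_over_iterations": s.std_fit_std})
        if s.mean_test_std is not None:
            rows.append({"stage": "z_test", "mean_std": s.mean_test_std,
                         "mean_std_percent": 100 * s.mean_test_std,
                         "std_over_iterations": s.std_test_std})
    if report.scenarios:
        for tag, res in sorted(report.scenarios.items()):
            rows.append({"stage": f"scenario_{tag}", "mean_std": res.report.mean_sigma,
                         "mean_std_percent": res.report.mean_percent})
    _write_csv(pd.DataFrame(rows), outdir / "stage_std.csv", h)

    per_layer = pd.concat([rep.to_frame() for rep in report.stage_std.values()])
    _write_csv(per_layer, outdir / "layer_std.csv", h)

    bs, cs = report.amplitude_factors.to_frames()
    _write_csv(bs, outdir / "factors_B.csv", h)
    _write_csv(cs, outdir / "factors_C.csv", h)

    N, K = report.tissue_profile.b_nk.shape
    ni, ki = np.meshgrid(np.arange(N), np.arange(K), indexing="ij")
    _write_csv(
        pd.DataFrame({"sample": ni.ravel(), "layer": ki.ravel(),
                      "T": report.tissue_profile.T_nk.ravel(),
                      "b": report.tissue_profile.b_nk.ravel()}),
        outdir / "factors_b.csv", h,
    )
    M, K = report.microscope_profile.w_mk.shape
    mi, ki = np.meshgrid(np.arange(M), np.arange(K), indexing="ij")
    d = report.wmk_decomposition
    _write_csv(
        pd.DataFrame({"microscope": mi.ravel(), "layer": ki.ravel(),
                      "w": report.microscope_profile.w_mk.ravel(),
                      "w_ill": np.repeat(d.w_ill, K),
                      "w_BB": d.w_bb.ravel(), "w_NB": d.w_nb.ravel()}),
        outdir / "factors_w.csv", h,
    )

    for stage, cov in report.covariances.items():
        _write_csv(pd.DataFrame(cov.matrix), outdir / f"covariance_{stage}.csv", h)

    if report.bootstrap_summary is not None:
        _write_csv(report.bootstrap_summary.to_frame(), outdir / "bootstrap.csv", h)
    if report.standardization is not None:
        _write_csv(report.standardization.to_frame(),
                   outdir / "standardization_factors.csv", h)
    if report.mask_qc is not None:
        _write_csv(report.mask_qc, outdir / "mask_qc.csv", h)
    return outdir
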