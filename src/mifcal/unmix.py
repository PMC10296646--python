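"""Linear spectral unmixing and the three-scenario comparison harness.

Each pixel's K-layer spectrum is decomposed into non-negative contributions
of K' components (fluorophore markers plus autofluorescence) by non-negative
least squares against a spectral library — the standard linear unmixing
formulation, standing in for proprietary vendor software whose algorithm is
not public.  A fast path solves the unconstrained least-squares problem for
all pixels at once and falls back to per-pixel active-set NNLS only where
the unconstrained optimum leaves the non-negative quadrant.

The scenario harness quantifies how microscope standardization affects
unmixed marker measurements by comparing residual variation when unmixing
(A) raw images with a single reference-microscope library, (B) raw images
with microscope-specific libraries, and (C) standardized images with the
reference library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .bootstrap import tissue_homogenize
from .calibration import fit_amplitude_factors
from .diagnostics import LayerStdReport, layer_std
from .io import FluxStack, ScanKey
from .spectra import (
    SpectraTensor,
    accumulate_mean_image,
    amplitude_summary,
    grand_normalize,
    hpf_fraction_weight,
    layer_mean_spectrum,
)
from .standardize import StandardizationFactors, standardize_stack

__all__ = [
    "SpectralLibrary",
    "UnmixedStack",
    "SpectralUnmixer",
    "unmix_stack",
    "ScenarioResult",
    "scenario_compare",
]

AUTOFLUORESCENCE = "autofluorescence"


@dataclass
class SpectralLibrary:
    """Pure-component spectra: K layers x K' components, non-negative."""

    matrix: np.ndarray  # (K, K')
    component_names: tuple[str, ...]
    microscope_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("library matrix must be K x K'")
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise ValueError("library spectra must be finite and non-negative")
        if len(self.component_names) != self.matrix.shape[1]:
            raise ValueError("one name per component column required")
        if len(set(self.component_names)) != len(self.component_names):
            raise ValueError("component names must be unique")
        zero = np.flatnonzero(self.matrix.sum(axis=0) == 0)
        if zero.size:
            raise ValueError(f"library column {self.component_names[zero[0]]!r} is all zero")

    @property
    def K(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_components(self) -> int:
        return self.matrix.shape[1]

    def normalized(self) -> "SpectralLibrary":
        """Columns scaled to unit sum, keeping only spectral shape."""
        return SpectralLibrary(
            matrix=self.matrix / self.matrix.sum(axis=0),
            component_names=self.component_names,
            microscope_id=self.microscope_id,
        )

    def to_frame(self) -> pd.DataFrame:
        K, Kp = self.matrix.shape
        ki, ci = np.meshgrid(np.arange(K), np.arange(Kp), indexing="ij")
        return pd.DataFrame(
            {
                "layer": ki.ravel(),
                "component": np.asarray(self.component_names)[ci.ravel()],
                "value": self.matrix.ravel(),
                "microscope_id": self.microscope_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectralLibrary":
        names = tuple(dict.fromkeys(df["component"]))
        K = int(df["layer"].max()) + 1
        matrix = np.zeros((K, len(names)))
        pos = {c: j for j, c in enumerate(names)}
        for _, row in df.iterrows():
            matrix[int(row["layer"]), pos[row["component"]]] = float(row["value"])
        mic = str(df["microscope_id"].iloc[0]) if "microscope_id" in df else ""
        return cls(matrix=matrix, component_names=names, microscope_id=mic)


@dataclass
class UnmixedStack:
    """Per-pixel component abundances: H x W x K' non-negative reals."""

    values: np.ndarray
    component_names: tuple[str, ...]
    scan: ScanKey
    tile_id: str
    scenario: str = ""
    library_microscope: str = ""


def _unmix_pixels(P: np.ndarray, L: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """NNLS coefficients for a (pixels, K) matrix against library L (K, K').

    Unconstrained least squares first; per-pixel active-set NNLS only where
    a coefficient is meaningfully negative.  Deterministic for fixed input.
    """
    coef, *_ = np.linalg.lstsq(L, P.T, rcond=None)  # (K', pixels)
    coef = coef.T
    scale = np.maximum(np.abs(P).max(axis=1), 1.0)
    bad = (coef < -tol * scale[:, None]).any(axis=1)
    for i in np.flatnonzero(bad):
        coef[i], _ = nnls(L, P[i])
    np.clip(coef, 0.0, None, out=coef)
    return coef


def unmix_stack(stack: FluxStack, library: SpectralLibrary, scenario: str = "") -> UnmixedStack:
    """Per-pixel non-negative least-squares decomposition of a flux stack."""
    H, W, K = stack.pixels.shape
    if K != library.K:
        raise ValueError(f"stack has {K} layers but library expects {library.K}")
    if np.linalg.matrix_rank(library.matrix) < library.n_components:
        warnings.warn(
            "spectral library is rank-deficient; unmixing coefficients are "
            "not unique and one optimum is returned",
            stacklevel=2,
        )
    coef = _unmix_pixels(stack.pixels.reshape(-1, K), library.matrix)
    return UnmixedStack(
        values=coef.reshape(H, W, library.n_components),
        component_names=library.component_names,
        scan=stack.scan,
        tile_id=stack.tile_id,
        scenario=scenario,
        library_microscope=library.microscope_id,
    )


class SpectralUnmixer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping per-pixel NNLS unmixing.

    Parameters: ``library``.  Fitted attributes: ``components_`` (the library
    matrix), ``component_names_``, ``rank_``.
    """

    def __init__(self, library: SpectralLibrary | None = None):
        self.library = library

    def fit(self, X=None, y=None):
        if self.library is None:
            raise ValueError("SpectralUnmixer requires a library")
        self.components_ = self.library.matrix
        self.component_names_ = self.library.component_names
        self.rank_ = int(np.linalg.matrix_rank(self.components_))
        return self

    def transform(self, X):
        """Unmix a FluxStack or a (..., K) array of pixel spectra."""
        if isinstance(X, FluxStack):
            return unmix_stack(X, self.library)
        arr = np.asarray(X, dtype=np.float64)
        coef = _unmix_pixels(arr.reshape(-1, arr.shape[-1]), self.components_)
        return coef.reshape(arr.shape[:-1] + (self.components_.shape[1],))


@dataclass
class ScenarioResult:
    """One unmixing scenario's homogenized spectra and residual-std report."""

    scenario: str
    psi: SpectraTensor  # stage 'psi_unmixed', K' layers
    report: LayerStdReport


def scenario_compare(
    dataset,
    libraries: Mapping[str, SpectralLibrary],
    std_factors: StandardizationFactors,
    reference_id: str,
    exclude_components=(AUTOFLUORESCENCE,),
) -> dict[str, ScenarioResult]:
    """Run the three unmixing scenarios and report layer-averaged stds.

    A: raw images, reference-microscope library for everything.
    B: raw images, each microscope's own library.
    C: images standardized to the reference microscope, reference library.

    Per scenario the masked unmixed stacks are reduced exactly like the raw
    spectra (mean image, per-layer means, HPF-fraction weighting, grand
    normalization at K' layers), sample effects are removed via the
    amplitude and sample-profile analogues, and the residual per-layer std
    is reported with the autofluorescence component excluded from the mean.
    """
    if reference_id not in libraries:
        raise ValueError(f"no library for reference microscope {reference_id!r}")
    for mid in dataset.microscope_ids:
        if mid not in libraries:
            raise ValueError(f"missing library for microscope {mid!r}")

    ref_only = {mid: libraries[reference_id] for mid in dataset.microscope_ids}
    runs = {
        "A": (ref_only, None),
        "B": (dict(libraries), None),
        "C": (ref_only, std_factors),
    }
    results: dict[str, ScenarioResult] = {}
    for tag, (lib_for, factors) in runs.items():
        results[tag] = _scenario_psi(dataset, lib_for, tag, factors, exclude_components)
    return results


def _scenario_psi(
    dataset,
    library_for: Mapping[str, SpectralLibrary],
    scenario: str,
    std_factors: StandardizationFactors | None,
    exclude_components,
) -> ScenarioResult:
    any_lib = next(iter(library_for.values()))
    names = any_lib.component_names
    Kp = any_lib.n_components
    N, M = len(dataset.sample_ids), len(dataset.microscope_ids)
    R = dataset.n_scan_repeats
    xbar = np.full((N, M, R, Kp), np.nan)
    hmrn = np.zeros((N, M, R), dtype=np.int64)

    for scan in dataset.scans:
        lib = library_for[scan.microscope_id]
        if lib.component_names != names:
            raise ValueError("libraries must share component names and order")

        def unmixed_pairs(scan=scan, lib=lib):
            for flux, mask in dataset.iter_scan(scan):
                if std_factors is not None:
                    flux = standardize_stack(flux, std_factors, scan.microscope_id)
                um = unmix_stack(flux, lib, scenario=scenario)
                yield (
                    FluxStack(pixels=um.values, scan=flux.scan, tile_id=flux.tile_id),
                    mask,
                )

        mi = accumulate_mean_image(unmixed_pairs())
        xbar[scan.n, scan.m, scan.r] = layer_mean_spectrum(mi)
        hmrn[scan.n, scan.m, scan.r] = scan.hmrn

    if np.isnan(xbar).any():
        raise ValueError("incomplete (n, m, r) grid in scenario comparison")

    tensor = SpectraTensor(
        values=xbar,
        stage="Xbar_unmixed",
        sample_ids=tuple(dataset.sample_ids),
        microscope_ids=tuple(dataset.microscope_ids),
    )
    X = grand_normalize(hpf_fraction_weight(tensor, hmrn))
    amps = amplitude_summary(X)
    B_n = fit_amplitude_factors(amps).B_n
    _, _, psi = tissue_homogenize(X, B_n)
    psi = psi.with_values(psi.values, "psi_unmixed")
    exclude = frozenset(names.index(c) for c in exclude_components if c in names)
    report = layer_std(psi, exclude_layers=exclude)
    return ScenarioResult(scenario=scenario, psi=psi, report=report)
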