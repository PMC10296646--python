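"""Reduction of masked flux stacks to average-tissue-flux spectra.

The pipeline per scan is: accumulate the masked per-pixel mean image M over
all HPFs of the scan; average M over pixels to a per-layer spectrum (one row
of the Xbar tensor); weight each scan's spectrum by the fraction of all HPFs
it contributes (Xtilde); and divide by the grand mean so the stage-X tensor
has grand mean exactly one.  The wavelength-independent amplitude table a
summarizes each scan's overall relative brightness.

The central container is :class:`SpectraTensor`, a stage-tagged (N, M, R, K)
array indexed by sample, microscope, scan repeat, and image layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import FluxStack, ScanKey
from .masking import TissueMask

__all__ = [
    "SpectraTensor",
    "AmplitudeTable",
    "MeanImage",
    "accumulate_mean_image",
    "layer_mean_spectrum",
    "hpf_fraction_weight",
    "grand_normalize",
    "amplitude_summary",
    "build_xbar",
]


def _default_ids(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(n))


@dataclass
class SpectraTensor:
    """Stage-tagged tensor of per-(sample, microscope, scan, layer) relative flux."""

    values: np.ndarray  # (N, M, R, K)
    stage: str
    sample_ids: tuple[str, ...] = ()
    microscope_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError(f"spectra tensor must be (N, M, R, K), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra tensor contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = _default_ids("sample", self.values.shape[0])
        if not self.microscope_ids:
            self.microscope_ids = _default_ids("scope", self.values.shape[1])

    # dimension shorthands
    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    @property
    def R(self) -> int:
        return self.values.shape[2]

    @property
    def K(self) -> int:
        return self.values.shape[3]

    def with_values(self, values: np.ndarray, stage: str) -> "SpectraTensor":
        return SpectraTensor(
            values=values,
            stage=stage,
            sample_ids=self.sample_ids,
            microscope_ids=self.microscope_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (sample_id, microscope_id, scan_index, layer, value, stage)."""
        n, m, r, k = np.meshgrid(
            np.arange(self.N), np.arange(self.M), np.arange(self.R), np.arange(self.K),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "sample_id": np.asarray(self.sample_ids)[n.ravel()],
                "microscope_id": np.asarray(self.microscope_ids)[m.ravel()],
                "scan_index": r.ravel(),
                "layer": k.ravel(),
                "value": self.values.ravel(),
                "stage": self.stage,
            }
        )


@dataclass
class AmplitudeTable:
    """Normalized average relative intensity a per (sample, microscope, scan)."""

    values: np.ndarray  # (N, M, R)
    sample_ids: tuple[str, ...] = ()
    microscope_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"amplitude table must be (N, M, R), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("amplitudes must be finite and positive")
        if not self.sample_ids:
            self.sample_ids = _default_ids("sample", self.values.shape[0])
        if not self.microscope_ids:
            self.microscope_ids = _default_ids("scope", self.values.shape[1])

    def to_frame(self) -> pd.DataFrame:
        n, m, r = np.meshgrid(
            np.arange(self.values.shape[0]),
            np.arange(self.values.shape[1]),
            np.arange(self.values.shape[2]),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "sample_id": np.asarray(self.sample_ids)[n.ravel()],
                "microscope_id": np.asarray(self.microscope_ids)[m.ravel()],
                "scan_index": r.ravel(),
                "value": self.values.ravel(),
            }
        )


@dataclass
class MeanImage:
    """Masked per-pixel mean flux of one scan, with per-pixel HPF coverage."""

    values: np.ndarray  # (H, W, K), counts/ms; 0 where coverage is 0
    coverage: np.ndarray  # (H, W) non-negative ints, sum of masks over HPFs
    scan: ScanKey


def accumulate_mean_image(
    pairs: Iterable[tuple[FluxStack, TissueMask]],
    warn_coverage_fraction: float = 0.5,
) -> MeanImage:
    """Masked mean image of a scan: M = sum_h(B_h I_h) / sum_h(B_h), per pixel.

    Single streaming pass with double-precision running sums; pixels never
    covered by any mask are set to 0 (and still count in downstream H*W
    averages).  A warning is emitted when more than ``warn_coverage_fraction``
    of pixels have zero coverage.
    """
    num: np.ndarray | None = None
    den: np.ndarray | None = None
    scan: ScanKey | None = None
    for stack, mask in pairs:
        if stack.pixels.shape[:2] != mask.mask.shape:
            raise ValueError(
                f"mask shape {mask.mask.shape} does not match stack {stack.pixels.shape[:2]}"
            )
        if num is None:
            num = np.zeros(stack.pixels.shape, dtype=np.float64)
            den = np.zeros(stack.pixels.shape[:2], dtype=np.int64)
            scan = stack.scan
        else:
            if stack.pixels.shape != num.shape:
                raise ValueError(
                    f"HPF shape {stack.pixels.shape} differs from first HPF {num.shape}"
                )
            if stack.scan != scan:
                raise ValueError(f"mixed scans in one accumulation: {stack.scan} vs {scan}")
        b = mask.mask.astype(np.float64)
        num += b[:, :, None] * stack.pixels
        den += mask.mask.astype(np.int64)
    if num is None or den is None or scan is None:
        raise ValueError("cannot accumulate a mean image from an empty HPF stream")
    covered = den > 0
    values = np.zeros_like(num)
    np.divide(num, den[:, :, None], out=values, where=covered[:, :, None])
    zero_frac = 1.0 - covered.mean()
    if zero_frac > warn_coverage_fraction:
        warnings.warn(
            f"scan {scan}: {zero_frac:.0%} of pixels have zero mask coverage",
            stacklevel=2,
        )
    return MeanImage(values=values, coverage=den, scan=scan)


def layer_mean_spectrum(mean_image: MeanImage) -> np.ndarray:
    """Per-layer pixel average of the mean image: one row of the Xbar tensor.

    The divisor is the full H*W including zero-coverage pixels, so a scan's
    spectrum scales with its tissue area on the tile frame.
    """
    return mean_image.values.mean(axis=(0, 1))


def hpf_fraction_weight(xbar: SpectraTensor, hmrn: np.ndarray) -> SpectraTensor:
    """Weight each scan's spectrum by its share of all HPFs in the dataset:
    Xtilde = Xbar * h_mrn / sum_{n,m,r} h_mrn."""
    h = np.asarray(hmrn, dtype=np.float64)
    if h.shape != xbar.values.shape[:3]:
        raise ValueError(f"hmrn shape {h.shape} does not match tensor {xbar.values.shape[:3]}")
    total = h.sum()
    if total <= 0:
        raise ValueError("all HPF counts are zero; cannot weight spectra")
    return xbar.with_values(xbar.values * (h / total)[..., None], stage="Xtilde")


def grand_normalize(xtilde: SpectraTensor) -> SpectraTensor:
    """Divide by the grand mean over (n, m, r, k); the result has grand mean 1."""
    gm = xtilde.values.mean()
    if not np.isfinite(gm) or gm <= 0:
        raise ValueError(f"grand mean must be positive, got {gm}")
    return xtilde.with_values(xtilde.values / gm, stage="X")


def amplitude_summary(x_spectra: SpectraTensor) -> AmplitudeTable:
    """Wavelength-independent amplitudes: per-(n,m,r) mean over layers divided
    by the grand mean, so the table has mean 1 (correct on any stage input)."""
    per_scan = x_spectra.values.mean(axis=3)
    grand = x_spectra.values.mean()
    return AmplitudeTable(
        values=per_scan / grand,
        sample_ids=x_spectra.sample_ids,
        microscope_ids=x_spectra.microscope_ids,
    )


def build_xbar(dataset) -> tuple[SpectraTensor, np.ndarray]:
    """Reduce a dataset (anything with ``sample_ids``, ``microscope_ids``,
    ``n_scan_repeats``, ``K``, ``scans`` and ``iter_scan(scan)`` yielding
    (FluxStack, TissueMask) pairs) to the Xbar tensor and the hmrn counts.

    Every (n, m, r) grid cell must be covered by exactly one scan record.
    """
    N = len(dataset.sample_ids)
    M = len(dataset.microscope_ids)
    R = dataset.n_scan_repeats
    K = dataset.K
    xbar = np.full((N, M, R, K), np.nan)
    hmrn = np.zeros((N, M, R), dtype=np.int64)
    for scan in dataset.scans:
        mi = accumulate_mean_image(dataset.iter_scan(scan))
        xbar[scan.n, scan.m, scan.r] = layer_mean_spectrum(mi)
        hmrn[scan.n, scan.m, scan.r] = scan.hmrn
    if np.isnan(xbar).any():
        missing = np.argwhere(np.isnan(xbar[..., 0]))[0]
        raise ValueError(f"no scan record for grid cell (n, m, r) = {tuple(missing)}")
    tensor = SpectraTensor(
        values=xbar,
        stage="Xbar",
        sample_ids=tuple(dataset.sample_ids),
        microscope_ids=tuple(dataset.microscope_ids),
    )
    return tensor, hmrn
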