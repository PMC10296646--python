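"""Tissue masks: exclude empty background and oversaturated pixels.

Each HPF gets one binary 2-D mask.  Background is separated from tissue by
Otsu's threshold computed on a per-HPF projection image (by default the
per-pixel mean over all exposure-normalized layers); a pixel saturated above
its layer threshold in *any* layer is removed from all layers, matching the
single-mask formulation used by the mean-image accumulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .io import FluxStack, HPFStack, ScanKey

__all__ = [
    "TissueMask",
    "saturation_thresholds",
    "otsu_threshold",
    "compute_tissue_mask",
    "apply_mask",
    "mask_summary",
]

#: Default near-full-scale saturation threshold (counts); the instrument's
#: hand-tuned per-layer values are site-specific, so near-saturation is the
#: safe shipped default.
DEFAULT_SATURATION = 65500.0


@dataclass
class TissueMask:
    """Binary mask for one HPF: 1 = well-imaged tissue, 0 = background/saturated."""

    mask: np.ndarray  # (H, W) uint8
    n_background: int
    n_saturated: int
    otsu_threshold: float | None
    degenerate: bool
    scan: ScanKey
    tile_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")

    @property
    def n_removed(self) -> int:
        return int(self.mask.size - self.mask.sum())

    @property
    def fraction_kept(self) -> float:
        return float(self.mask.mean())


def saturation_thresholds(K: int, value: float = DEFAULT_SATURATION) -> np.ndarray:
    """Per-layer saturation thresholds (counts), constant by default."""
    thr = np.full(K, float(value))
    if np.any(thr <= 0) or np.any(thr > 65535):
        raise ValueError("saturation thresholds must lie in (0, 65535]")
    return thr


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold of an image or value array.

    For integer inputs the histogram uses one bin per integer level (exact);
    float inputs use 256 bins, scikit-image's convention.  Raises
    ``ValueError`` on constant input (the threshold is undefined).
    """
    vals = np.asarray(values).ravel()
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        raise ValueError("Otsu threshold undefined for a constant image")
    if np.issubdtype(vals.dtype, np.integer):
        nbins = int(min(65536, int(hi) - int(lo) + 1))
    else:
        nbins = 256
    return float(threshold_otsu(vals, nbins=nbins))


def compute_tissue_mask(
    hpf: HPFStack,
    thresholds: np.ndarray | float | None = None,
    flux: FluxStack | None = None,
    otsu_layers: Sequence[int] | None = None,
) -> TissueMask:
    """Build the binary tissue mask for one HPF.

    A pixel is set to 0 iff (a) its projection value is not above the Otsu
    threshold computed on this HPF's projection image, or (b) its raw count
    exceeds the saturation threshold in any layer.  The projection is the
    per-pixel mean over ``otsu_layers`` (default: all layers) of the flux
    stack when given, else of the raw counts.  Saturated pixels are invalid
    measurements and are excluded from the Otsu histogram (their extreme
    values would otherwise dominate the between-class variance).

    If the projection is constant over non-saturated pixels, Otsu is
    undefined: the mask keeps everything except saturated pixels and a
    warning is emitted.
    """
    K = hpf.pixels.shape[2]
    if thresholds is None:
        thr = saturation_thresholds(K)
    else:
        thr = np.broadcast_to(np.asarray(thresholds, dtype=np.float64), (K,))
    if thr.shape[0] != K:
        raise ValueError(f"expected {K} saturation thresholds, got {thr.shape[0]}")

    saturated = (hpf.pixels.astype(np.float64) > thr).any(axis=2)

    source = flux.pixels if flux is not None else hpf.pixels.astype(np.float64)
    if otsu_layers is None:
        projection = source.mean(axis=2)
    else:
        projection = source[:, :, list(otsu_layers)].mean(axis=2)

    valid = projection[~saturated]
    if valid.size == 0 or valid.min() == valid.max():
        warnings.warn(
            f"constant projection in HPF {hpf.tile_id}: Otsu undefined, "
            "keeping all non-saturated pixels",
            stacklevel=2,
        )
        keep = ~saturated
        return TissueMask(
            mask=keep.astype(np.uint8),
            n_background=0,
            n_saturated=int(saturated.sum()),
            otsu_threshold=None,
            degenerate=True,
            scan=hpf.scan,
            tile_id=hpf.tile_id,
        )

    thresh = otsu_threshold(valid)
    tissue = projection > thresh
    keep = tissue & ~saturated
    return TissueMask(
        mask=keep.astype(np.uint8),
        n_background=int((~tissue).sum()),
        n_saturated=int(saturated.sum()),
        otsu_threshold=thresh,
        degenerate=False,
        scan=hpf.scan,
        tile_id=hpf.tile_id,
    )


def apply_mask(stack: FluxStack, mask: TissueMask) -> FluxStack:
    """Zero out masked pixels in every layer."""
    if stack.pixels.shape[:2] != mask.mask.shape:
        raise ValueError("mask and stack dimensions differ")
    return FluxStack(
        pixels=stack.pixels * mask.mask[:, :, None],
        scan=stack.scan,
        tile_id=stack.tile_id,
    )


def mask_summary(masks: Sequence[TissueMask]) -> pd.DataFrame:
    """Per-scan QC table: mean fraction of pixels kept and removal counts."""
    if len(masks) == 0:
        raise ValueError("mask_summary requires at least one mask")
    rows = [
        {
            "sample_id": m.scan[0],
            "microscope_id": m.scan[1],
            "scan_index": m.scan[2],
            "fraction_kept": m.fraction_kept,
            "n_background": m.n_background,
            "n_saturated": m.n_saturated,
            "n_removed": m.n_removed,
        }
        for m in masks
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["sample_id", "microscope_id", "scan_index"], sort=True)
        .agg(
            n_hpfs=("fraction_kept", "size"),
            fraction_kept=("fraction_kept", "mean"),
            n_background=("n_background", "sum"),
            n_saturated=("n_saturated", "sum"),
            n_removed=("n_removed", "sum"),
        )
        .reset_index()
    )
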