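"""Standardizing raw images to a reference microscope.

The bootstrap-aggregated microscope factors (mean C_ms and mean omega_mks)
combine into one positive scale per (microscope, layer).  Dividing by the
reference microscope's own scale yields standardization factors that leave
the reference microscope's data numerically unaltered and bring the other
microscopes onto its flux scale.  Because the factor is a per-layer scalar,
it can be applied equivalently to raw count stacks or flux stacks, and is
meant to be applied before spectral unmixing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bootstrap import BootstrapSummary
from .io import FluxStack, HPFStack

__all__ = ["StandardizationFactors", "reference_standardization_factors",
           "standardize_stack"]


@dataclass
class StandardizationFactors:
    """Per-(microscope, layer) divisors relative to a reference microscope."""

    reference_id: str
    microscope_ids: tuple[str, ...]
    factors: np.ndarray  # (M, K), positive; reference row identically 1

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=np.float64)
        if not np.all(np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise ValueError("standardization factors must be finite and positive")
        if self.reference_id not in self.microscope_ids:
            raise ValueError(f"reference {self.reference_id!r} not among microscopes")

    def row(self, microscope_id: str) -> np.ndarray:
        try:
            m = self.microscope_ids.index(microscope_id)
        except ValueError:
            raise KeyError(f"unknown microscope id {microscope_id!r}") from None
        return self.factors[m]

    def to_frame(self) -> pd.DataFrame:
        M, K = self.factors.shape
        mi, ki = np.meshgrid(np.arange(M), np.arange(K), indexing="ij")
        return pd.DataFrame(
            {
                "microscope_id": np.asarray(self.microscope_ids)[mi.ravel()],
                "layer": ki.ravel(),
                "factor": self.factors.ravel(),
                "reference_id": self.reference_id,
            }
        )


def reference_standardization_factors(
    summary: BootstrapSummary,
    reference_id: str,
    microscope_ids: tuple[str, ...],
    combine: str = "product_of_means",
) -> StandardizationFactors:
    """Combine the bootstrap factor means and divide by the reference row.

    ``combine`` selects how C and omega are merged: ``product_of_means``
    (mean_s C_ms * mean_s omega_mks, the default) or ``mean_of_products``
    (mean_s of C_ms * omega_mks); the two differ only at second order in the
    across-iteration spread.
    """
    if combine == "product_of_means":
        prod = summary.mean_C_ms[:, None] * summary.mean_omega_mks
    elif combine == "mean_of_products":
        prod = summary.mean_C_omega
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    try:
        ref = microscope_ids.index(reference_id)
    except ValueError:
        raise ValueError(f"reference {reference_id!r} not among {microscope_ids}") from None
    if np.any(prod[ref] == 0):
        raise ValueError("reference microscope has a zero factor")
    factors = prod / prod[ref]
    return StandardizationFactors(
        reference_id=reference_id, microscope_ids=tuple(microscope_ids), factors=factors
    )


def standardize_stack(
    stack: HPFStack | FluxStack,
    factors: StandardizationFactors,
    microscope_id: str,
    requantize: bool = False,
):
    """Divide each layer of a stack by its standardization factor.

    Returns a real-valued :class:`FluxStack`-shaped array wrapped in the
    input's class when possible; by default the output stays floating point
    to avoid quantization loss.  With ``requantize=True`` an
    :class:`HPFStack` input is rounded (half-to-even) and clipped back to
    unsigned 16-bit.
    """
    row = factors.row(microscope_id)
    values = np.asarray(stack.pixels, dtype=np.float64) / row
    if isinstance(stack, HPFStack):
        if requantize:
            q = np.clip(np.rint(values), 0, 65535).astype(np.uint16)
            return replace(stack, pixels=q)
        return FluxStack(pixels=values, scan=stack.scan, tile_id=stack.tile_id)
    return replace(stack, pixels=values)
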