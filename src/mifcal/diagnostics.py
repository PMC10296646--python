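"""Residual-variation diagnostics for spectra tensors.

Two summaries quantify what a correction stage leaves behind:

* the per-layer standard deviation of the N*M*R values at each layer
  (sample convention, divisor NMR-1), with its mean over a designated layer
  set — the headline "percent variation" statistic; and
* the image-layer-projected covariance matrix, where deviations are taken
  about each microscope's own per-layer mean, pooled over all (n, m, r) with
  divisor NMR (population convention, as the defining formula prints it).

Centering on the own-microscope mean makes the covariance blind to static
between-microscope offsets and sensitive to the correlated within-microscope
structure, which is dominated by the broadband filter groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectraTensor

__all__ = ["LayerStdReport", "CovarianceReport", "layer_std", "covariance_matrix",
           "plot_layer_std"]


@dataclass
class LayerStdReport:
    """Per-layer standard deviations with their mean over non-excluded layers."""

    sigma: np.ndarray  # (K,), fraction of normalized flux
    stage: str
    excluded_layers: frozenset[int] = field(default_factory=frozenset)
    ddof: int = 1

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        self.excluded_layers = frozenset(int(k) for k in self.excluded_layers)
        if np.any(self.sigma < 0):
            raise ValueError("standard deviations must be non-negative")

    @property
    def included_layers(self) -> np.ndarray:
        return np.array(
            [k for k in range(self.sigma.shape[0]) if k not in self.excluded_layers]
        )

    @property
    def mean_sigma(self) -> float:
        return float(self.sigma[self.included_layers].mean())

    @property
    def mean_percent(self) -> float:
        """Layer-averaged std as a percent of the normalized (about-one) flux."""
        return 100.0 * self.mean_sigma

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stage,
                "layer": np.arange(self.sigma.shape[0]),
                "sigma": self.sigma,
                "excluded": [k in self.excluded_layers for k in range(self.sigma.shape[0])],
            }
        )


@dataclass
class CovarianceReport:
    """Layer-projected covariance matrix and the per-(m, k) means it centers on."""

    matrix: np.ndarray  # (K, K)
    mu_mk: np.ndarray  # (M, K)
    stage: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12, rtol=0):
            raise ValueError("covariance matrix is not symmetric")

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))


def layer_std(
    spectra: SpectraTensor | np.ndarray,
    exclude_layers=None,
    ddof: int = 1,
) -> LayerStdReport:
    """Standard deviation across all (sample, microscope, scan) per layer.

    ``exclude_layers`` drops layers (e.g. the autofluorescence component of
    unmixed spectra) from the reported mean only; their sigmas are still
    computed.
    """
    v = spectra.values if isinstance(spectra, SpectraTensor) else np.asarray(spectra)
    if v.ndim != 4:
        raise ValueError(f"expected an (N, M, R, K) tensor, got shape {v.shape}")
    flat = v.reshape(-1, v.shape[3])
    if flat.shape[0] < 2:
        raise ValueError("need at least 2 observations per layer for a standard deviation")
    stage = spectra.stage if isinstance(spectra, SpectraTensor) else ""
    return LayerStdReport(
        sigma=flat.std(axis=0, ddof=ddof),
        stage=stage,
        excluded_layers=frozenset(exclude_layers or ()),
        ddof=ddof,
    )


def covariance_matrix(spectra: SpectraTensor | np.ndarray) -> CovarianceReport:
    """Layer-projected covariance with deviations about the own-microscope mean:

    mu_mk = mean over (n, r);  d = value - mu_mk;
    Sigma_{k1 k2} = (1 / NMR) * sum over (n, m, r) of d_{k1} d_{k2}.
    """
    v = spectra.values if isinstance(spectra, SpectraTensor) else np.asarray(spectra)
    if v.ndim != 4:
        raise ValueError(f"expected an (N, M, R, K) tensor, got shape {v.shape}")
    N, M, R, K = v.shape
    mu_mk = v.mean(axis=(0, 2))
    d = v - mu_mk[None, :, None, :]
    matrix = np.einsum("nmrk,nmrl->kl", d, d) / (N * M * R)
    matrix = 0.5 * (matrix + matrix.T)  # exact symmetry against float round-off
    stage = spectra.stage if isinstance(spectra, SpectraTensor) else ""
    return CovarianceReport(matrix=matrix, mu_mk=mu_mk, stage=stage)


def plot_layer_std(reports, path=None):
    """Per-layer std lines for each stage plus a bar chart of layer averages."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_top, ax_bot) = plt.subplots(2, 1, figsize=(8, 6))
    for rep in reports:
        ax_top.plot(100.0 * rep.sigma, label=rep.stage or "spectra")
    ax_top.set_xlabel("image layer")
    ax_top.set_ylabel("std (%)")
    ax_top.legend(fontsize=8)
    names = [rep.stage or str(i) for i, rep in enumerate(reports)]
    ax_bot.bar(names, [rep.mean_percent for rep in reports])
    ax_bot.set_ylabel("layer-averaged std (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
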