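"""Bootstrap assessment of how well microscope factors generalize.

Tissue effects are first homogenized on the full dataset: the stage-X
spectra are divided by the sample amplitudes B_n (giving chi) and by the
sample spectral factors beta_nk fit from chi (giving psi), so that the
variation left in psi is attributable to the microscopes.  Each bootstrap
iteration then picks a subset of "fit" samples, computes microscope
amplitude (C_ms) and profile (omega_mks) factors from those samples only,
and applies them both to the fit samples and to the held-out "test"
samples; comparing the residual layer-averaged stds of the two groups
measures generalization to tissue never used in the fit.

With the default exhaustive mode every one of the C(N, N') fit subsets is
used once, making the whole procedure deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import LayerStdReport, layer_std
from .spectra import AmplitudeTable, SpectraTensor

__all__ = [
    "BootstrapConfig",
    "BootstrapIteration",
    "BootstrapSummary",
    "tissue_homogenize",
    "enumerate_fit_subsets",
    "bootstrap_iteration",
    "aggregate_bootstrap",
    "run_bootstrap",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """How fit subsets are drawn: exhaustively (all C(N, n_fit) subsets, the
    default) or as seeded random draws without replacement."""

    n_fit: int = 5
    mode: str = "exhaustive"
    n_iterations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("exhaustive", "random"):
            raise ValueError(f"unknown bootstrap mode {self.mode!r}")
        if self.mode == "random" and self.n_iterations is None:
            raise ValueError("random mode requires n_iterations")


def tissue_homogenize(
    x_spectra: SpectraTensor, B_n: np.ndarray
) -> tuple[SpectraTensor, np.ndarray, SpectraTensor]:
    """Remove sample effects: chi = X / B_n, beta_nk from chi, psi = chi / beta_nk.

    Returns (chi, beta_nk, psi).  beta_nk has per-layer sample mean one.
    """
    B = np.asarray(B_n, dtype=np.float64)
    if np.any(B <= 0) or not np.all(np.isfinite(B)):
        raise ValueError("B_n must be finite and positive")
    chi_v = x_spectra.values / B[:, None, None, None]
    denom = chi_v.mean(axis=(0, 1, 2))
    if np.any(denom == 0):
        raise ValueError("zero per-layer mean in chi spectra")
    beta_nk = chi_v.mean(axis=(1, 2)) / denom
    psi_v = chi_v / beta_nk[:, None, None, :]
    chi = x_spectra.with_values(chi_v, "chi")
    psi = x_spectra.with_values(psi_v, "psi")
    return chi, beta_nk, psi


def enumerate_fit_subsets(
    N: int, n_fit: int, config: BootstrapConfig | None = None
) -> list[tuple[int, ...]]:
    """Fit-sample subsets per the config: all C(N, n_fit) combinations in
    lexicographic order (exhaustive) or seeded draws without replacement."""
    config = config or BootstrapConfig(n_fit=n_fit)
    if not 1 <= n_fit < N:
        raise ValueError(f"need 1 <= n_fit < N, got n_fit={n_fit}, N={N}")
    if config.mode == "exhaustive":
        return list(itertools.combinations(range(N), n_fit))
    rng = np.random.default_rng(config.seed)
    return [
        tuple(sorted(rng.choice(N, size=n_fit, replace=False).tolist()))
        for _ in range(int(config.n_iterations))
    ]


@dataclass
class BootstrapIteration:
    """Factors fit on one sample subset, with fit- and test-set residual stds."""

    fit_samples: tuple[int, ...]
    test_samples: tuple[int, ...]
    C_ms: np.ndarray  # (M,)
    omega_mks: np.ndarray  # (M, K)
    fit_report: LayerStdReport
    test_report: LayerStdReport | None


def bootstrap_iteration(
    psi: SpectraTensor,
    amps: AmplitudeTable,
    fit_set: Sequence[int],
    exclude_layers=None,
) -> BootstrapIteration:
    """One bootstrap iteration.

    C_ms is the mean of the amplitudes over the fit samples and scans.
    The amplitude correction is applied before the profile is fit, exactly
    as in the full-dataset model: omega_mks is the per-(m, k) mean of
    psi / C_ms over fit samples and scans, divided by its per-layer mean
    over fit samples, microscopes, and scans.  z = psi / (C_ms * omega_mks)
    is then formed for every sample, and residual layer-std reports are
    computed separately for the fit and test samples.
    """
    fit = tuple(sorted(int(i) for i in fit_set))
    if len(fit) == 0:
        raise ValueError("fit set is empty")
    if len(set(fit)) != len(fit) or fit[0] < 0 or fit[-1] >= psi.N:
        raise ValueError(f"invalid fit set {fit} for N={psi.N}")
    test = tuple(i for i in range(psi.N) if i not in fit)

    a_fit = amps.values[list(fit)]  # (N', M, R)
    C_ms = a_fit.mean(axis=(0, 2))
    if np.any(C_ms == 0):
        raise ValueError("zero amplitude factor in bootstrap fit")
    psi_fit = psi.values[list(fit)] / C_ms[None, :, None, None]  # (N', M, R, K)
    denom = psi_fit.mean(axis=(0, 1, 2))
    if np.any(denom == 0):
        raise ValueError("zero denominator in bootstrap factors")
    omega_mks = psi_fit.mean(axis=(0, 2)) / denom

    z = psi.values / (C_ms[None, :, None, None] * omega_mks[None, :, None, :])
    fit_report = layer_std(
        psi.with_values(z[list(fit)], "z_fit"), exclude_layers=exclude_layers
    )
    test_report = (
        layer_std(psi.with_values(z[list(test)], "z_test"), exclude_layers=exclude_layers)
        if test
        else None
    )
    return BootstrapIteration(
        fit_samples=fit,
        test_samples=test,
        C_ms=C_ms,
        omega_mks=omega_mks,
        fit_report=fit_report,
        test_report=test_report,
    )


@dataclass
class BootstrapSummary:
    """Across-iteration aggregation of the bootstrap."""

    iterations: list[BootstrapIteration]
    mean_fit_std: float
    std_fit_std: float
    mean_test_std: float | None
    std_test_std: float | None
    mean_C_ms: np.ndarray  # (M,)
    mean_omega_mks: np.ndarray  # (M, K)
    mean_C_omega: np.ndarray  # (M, K), mean over iterations of C_ms * omega_mks

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, it in enumerate(self.iterations):
            rows.append(
                {
                    "iteration": i,
                    "fit_samples": ";".join(map(str, it.fit_samples)),
                    "fit_std": it.fit_report.mean_sigma,
                    "test_std": it.test_report.mean_sigma if it.test_report else np.nan,
                }
            )
        return pd.DataFrame(rows)


def aggregate_bootstrap(iterations: Sequence[BootstrapIteration]) -> BootstrapSummary:
    """Mean and std over iterations of the layer-averaged fit/test stds, and
    elementwise means of the C_ms and omega_mks factors (both the separate
    means and the mean of their product, for standardization downstream)."""
    if len(iterations) == 0:
        raise ValueError("no bootstrap iterations to aggregate")
    fit_stds = np.array([it.fit_report.mean_sigma for it in iterations])
    test_stds = np.array(
        [it.test_report.mean_sigma for it in iterations if it.test_report is not None]
    )
    C = np.stack([it.C_ms for it in iterations])
    omega = np.stack([it.omega_mks for it in iterations])
    ddof = 1 if len(iterations) > 1 else 0
    return BootstrapSummary(
        iterations=list(iterations),
        mean_fit_std=float(fit_stds.mean()),
        std_fit_std=float(fit_stds.std(ddof=ddof)),
        mean_test_std=float(test_stds.mean()) if test_stds.size else None,
        std_test_std=float(test_stds.std(ddof=1 if test_stds.size > 1 else 0))
        if test_stds.size
        else None,
        mean_C_ms=C.mean(axis=0),
        mean_omega_mks=omega.mean(axis=0),
        mean_C_omega=(C[:, :, None] * omega).mean(axis=0),
    )


def run_bootstrap(
    psi: SpectraTensor,
    amps: AmplitudeTable,
    config: BootstrapConfig | None = None,
    exclude_layers=None,
) -> BootstrapSummary:
    """Enumerate fit subsets, run every iteration, and aggregate."""
    config = config or BootstrapConfig()
    subsets = enumerate_fit_subsets(psi.N, config.n_fit, config)
    iters = [
        bootstrap_iteration(psi, amps, s, exclude_layers=exclude_layers) for s in subsets
    ]
    return aggregate_bootstrap(iters)
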