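"""Sequential multiplicative correction model for cross-microscope spectra.

The stage-X tensor is modelled as a product of a sample amplitude B_n, a
microscope amplitude C_m, a sample spectral profile b_nk, and a microscope
spectral profile w_mk, times residual noise.  The corrections are fit and
applied sequentially — amplitudes first, then the tissue profile, then the
microscope profile — each factor being a ratio of arithmetic means over the
complete (N, M, R) design:

    x = X / (B_n C_m),   y = x / b_nk,   z = y / w_mk.

Fitted factors carry mean-one gauge conventions: mean_n B_n = mean_m C_m = 1,
and per layer mean_n b_nk = mean_m w_mk = 1 (when fit from stage-X input).
The microscope profile further decomposes into an overall illumination scale,
a broadband-filter part constant within each filter group, and a narrowband
remainder: w_mk = w_ill,m * w_BB,mk * w_NB,mk.

Each correction is exposed both as a plain function pair (fit_*/apply_*) and
as an sklearn-style transformer so the three stages compose in a
:class:`sklearn.pipeline.Pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import FilterLayout
from .spectra import AmplitudeTable, SpectraTensor, amplitude_summary

__all__ = [
    "AmplitudeFactors",
    "TissueProfile",
    "MicroscopeProfile",
    "WmkDecomposition",
    "fit_amplitude_factors",
    "apply_amplitude",
    "fit_tissue_profile",
    "apply_tissue_profile",
    "fit_microscope_profile",
    "apply_microscope_profile",
    "decompose_microscope_profile",
    "AmplitudeCorrection",
    "TissueProfileCorrection",
    "MicroscopeProfileCorrection",
    "make_calibration_pipeline",
]


def _tensor_values(x) -> np.ndarray:
    v = x.values if isinstance(x, SpectraTensor) else np.asarray(x, dtype=np.float64)
    if v.ndim != 4:
        raise ValueError(f"expected an (N, M, R, K) tensor, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("tensor contains non-finite values")
    return v


def _like(x, values: np.ndarray, stage: str):
    if isinstance(x, SpectraTensor):
        return x.with_values(values, stage)
    return values


@dataclass
class AmplitudeFactors:
    """Overall-brightness corrections: per-sample B_n and per-microscope C_m."""

    B_n: np.ndarray
    C_m: np.ndarray
    sample_ids: tuple[str, ...] = ()
    microscope_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.B_n = np.asarray(self.B_n, dtype=np.float64)
        self.C_m = np.asarray(self.C_m, dtype=np.float64)
        for name, v in (("B_n", self.B_n), ("C_m", self.C_m)):
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"{name} must be finite and positive")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        bs = pd.DataFrame({"sample_id": list(self.sample_ids) or range(len(self.B_n)),
                           "B": self.B_n})
        cs = pd.DataFrame({"microscope_id": list(self.microscope_ids) or range(len(self.C_m)),
                           "C": self.C_m})
        return bs, cs


@dataclass
class TissueProfile:
    """Sample spectral profiles: raw means T_nk and mean-one factors b_nk."""

    T_nk: np.ndarray
    b_nk: np.ndarray
    sample_ids: tuple[str, ...] = ()


@dataclass
class MicroscopeProfile:
    """Microscope spectral profiles: raw means P_mk and mean-one factors w_mk."""

    P_mk: np.ndarray
    w_mk: np.ndarray
    microscope_ids: tuple[str, ...] = ()


@dataclass
class WmkDecomposition:
    """w_mk split into illumination, broadband-filter, and narrowband parts.

    ``w_ill`` is each microscope's mean over all layers; ``w_bb`` is constant
    within each broadband group; ``w_nb`` averages to one within each group.
    The product reconstructs w_mk exactly.
    """

    w_ill: np.ndarray  # (M,)
    w_bb: np.ndarray  # (M, K)
    w_nb: np.ndarray  # (M, K)
    microscope_ids: tuple[str, ...] = ()

    def reconstruct(self) -> np.ndarray:
        return self.w_ill[:, None] * self.w_bb * self.w_nb


def fit_amplitude_factors(amps: AmplitudeTable) -> AmplitudeFactors:
    """B_n = mean over (m, r) of a; C_m = mean over (n, r) of a."""
    a = amps.values
    if not np.all(np.isfinite(a)):
        bad = tuple(np.argwhere(~np.isfinite(a))[0])
        raise ValueError(f"amplitude grid cell {bad} is not finite")
    return AmplitudeFactors(
        B_n=a.mean(axis=(1, 2)),
        C_m=a.mean(axis=(0, 2)),
        sample_ids=amps.sample_ids,
        microscope_ids=amps.microscope_ids,
    )


def apply_amplitude(x_spectra, factors: AmplitudeFactors):
    """x = X / (B_n * C_m); depends only on the product B_n C_m."""
    v = _tensor_values(x_spectra)
    out = v / (factors.B_n[:, None, None, None] * factors.C_m[None, :, None, None])
    return _like(x_spectra, out, "x")


def fit_tissue_profile(x_spectra) -> TissueProfile:
    """T_nk = mean over (m, r); b_nk = T_nk / per-layer mean over (n, m, r)."""
    v = _tensor_values(x_spectra)
    T_nk = v.mean(axis=(1, 2))
    denom = v.mean(axis=(0, 1, 2))
    if np.any(denom == 0):
        raise ValueError(f"zero per-layer mean at layer {int(np.argwhere(denom == 0)[0])}")
    ids = x_spectra.sample_ids if isinstance(x_spectra, SpectraTensor) else ()
    return TissueProfile(T_nk=T_nk, b_nk=T_nk / denom, sample_ids=ids)


def apply_tissue_profile(x_spectra, profile: TissueProfile):
    """y = x / b_nk."""
    v = _tensor_values(x_spectra)
    b = np.asarray(profile.b_nk, dtype=np.float64)
    if np.any(b <= 0):
        raise ValueError("tissue profile factors must be positive")
    return _like(x_spectra, v / b[:, None, None, :], "y")


def fit_microscope_profile(y_spectra) -> MicroscopeProfile:
    """P_mk = mean over (n, r); w_mk = P_mk / per-layer mean over (n, m, r)."""
    v = _tensor_values(y_spectra)
    P_mk = v.mean(axis=(0, 2))
    denom = v.mean(axis=(0, 1, 2))
    if np.any(denom == 0):
        raise ValueError(f"zero per-layer mean at layer {int(np.argwhere(denom == 0)[0])}")
    ids = y_spectra.microscope_ids if isinstance(y_spectra, SpectraTensor) else ()
    return MicroscopeProfile(P_mk=P_mk, w_mk=P_mk / denom, microscope_ids=ids)


def apply_microscope_profile(y_spectra, profile: MicroscopeProfile):
    """z = y / w_mk."""
    v = _tensor_values(y_spectra)
    w = np.asarray(profile.w_mk, dtype=np.float64)
    if np.any(w <= 0):
        raise ValueError("microscope profile factors must be positive")
    return _like(y_spectra, v / w[None, :, None, :], "z")


def decompose_microscope_profile(
    profile: MicroscopeProfile | np.ndarray, layout: FilterLayout
) -> WmkDecomposition:
    """Split w_mk into w_ill,m (mean over layers), w_BB,mk (within-group mean
    of w_mk / w_ill, broadcast to member layers) and the narrowband remainder
    w_NB,mk = w_mk / (w_ill w_BB)."""
    if isinstance(profile, MicroscopeProfile):
        w_mk = profile.w_mk
        ids = profile.microscope_ids
    else:
        w_mk = np.asarray(profile, dtype=np.float64)
        ids = ()
    M, K = w_mk.shape
    if layout.K != K:
        raise ValueError(f"layout covers {layout.K} layers but profile has {K}")
    w_ill = w_mk.mean(axis=1)
    if np.any(w_ill == 0):
        raise ValueError("zero illumination scale")
    rel = w_mk / w_ill[:, None]
    w_bb = np.empty_like(w_mk)
    for g in layout.groups:
        idx = list(g.layers)
        w_bb[:, idx] = rel[:, idx].mean(axis=1, keepdims=True)
    if np.any(w_bb == 0):
        raise ValueError("zero broadband factor")
    w_nb = rel / w_bb
    return WmkDecomposition(w_ill=w_ill, w_bb=w_bb, w_nb=w_nb, microscope_ids=ids)


# ---------------------------------------------------------------------------
# sklearn-style transformers
# ---------------------------------------------------------------------------


class _SpectraTransformer(TransformerMixin, BaseEstimator):
    """Base for the correction transformers; X is an (N, M, R, K) tensor."""

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X)


class AmplitudeCorrection(_SpectraTransformer):
    """Fit B_n and C_m from a spectra tensor and divide them out.

    Fitted attributes: ``amplitudes_`` (the a table), ``B_n_``, ``C_m_``,
    ``factors_``.
    """

    def fit(self, X, y=None):
        _tensor_values(X)  # validation
        tensor = X if isinstance(X, SpectraTensor) else SpectraTensor(X, stage="X")
        self.amplitudes_ = amplitude_summary(tensor)
        f = fit_amplitude_factors(self.amplitudes_)
        self.B_n_ = f.B_n
        self.C_m_ = f.C_m
        self.factors_ = f
        return self

    def transform(self, X):
        return apply_amplitude(X, self.factors_)


class TissueProfileCorrection(_SpectraTransformer):
    """Fit the per-sample spectral profile b_nk and divide it out.

    Fitted attributes: ``T_nk_``, ``b_nk_``, ``profile_``.
    """

    def fit(self, X, y=None):
        p = fit_tissue_profile(X)
        self.T_nk_ = p.T_nk
        self.b_nk_ = p.b_nk
        self.profile_ = p
        return self

    def transform(self, X):
        return apply_tissue_profile(X, self.profile_)


class MicroscopeProfileCorrection(_SpectraTransformer):
    """Fit the per-microscope spectral profile w_mk and divide it out.

    Fitted attributes: ``P_mk_``, ``w_mk_``, ``profile_``.
    """

    def fit(self, X, y=None):
        p = fit_microscope_profile(X)
        self.P_mk_ = p.P_mk
        self.w_mk_ = p.w_mk
        self.profile_ = p
        return self

    def transform(self, X):
        return apply_microscope_profile(X, self.profile_)


def make_calibration_pipeline():
    """The full sequential correction X -> x -> y -> z as an sklearn Pipeline.

    Each step is fit on the output of the previous step, exactly the
    sequential (no joint refit) procedure of the correction model.
    """
    from sklearn.pipeline import Pipeline

    return Pipeline(
        [
            ("amplitude", AmplitudeCorrection()),
            ("tissue_profile", TissueProfileCorrection()),
            ("microscope_profile", MicroscopeProfileCorrection()),
        ]
    )
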