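"""Synthetic multi-microscope, multi-scan HPF datasets with known ground truth.

The generator emulates the structure that the multiplicative correction
model assumes: each tile's expected flux is

    background + tissue(i, j) * A_n * g_m * t_nk * omega_mk * scene(i, j, k)

where A_n is a per-sample amplitude, g_m a per-microscope amplitude, t_nk a
per-sample spectral profile, and omega_mk a per-microscope spectral profile
built as (illumination scale) x (broadband-group offsets) x (smooth
narrowband ripple).  Counts are exposure-scaled, perturbed by multiplicative
Gaussian noise plus per-scan amplitude jitter, salted with saturated pixels,
rounded, and clipped to unsigned 16 bits.

The physical slide is what is re-scanned: each sample's tile scenes (tissue
region, texture or marker-abundance maps) are drawn once and shared across
all microscopes and scan repeats of that sample; only exposure, jitter,
noise, and saturation differ between scans.

``gauge_fix_truth`` re-expresses the planted factors in the estimators'
mean-one gauges by pushing the *noiseless* expected dataset through the
exact reduction and fit equations, which is the only gauge in which fitted
and true factors are directly comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .bootstrap import tissue_homogenize
from .calibration import (
    fit_amplitude_factors,
    fit_microscope_profile,
    fit_tissue_profile,
    apply_amplitude,
    apply_tissue_profile,
)
from .io import (
    ExposureTable,
    FilterGroup,
    FilterLayout,
    FluxStack,
    HPFStack,
    ScanRecord,
    exposure_normalize,
    validate_layout,
    write_dataset_manifest,
    write_hpf,
)
from .masking import TissueMask, compute_tissue_mask
from .spectra import (
    SpectraTensor,
    amplitude_summary,
    grand_normalize,
    hpf_fraction_weight,
)
from .unmix import AUTOFLUORESCENCE, SpectralLibrary

__all__ = [
    "SimulationConfig",
    "TruthModel",
    "GaugeFixedTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_to_disk",
    "gauge_fix_truth",
    "microscope_library",
]


def _contiguous_layout(K: int, n_groups: int) -> FilterLayout:
    sizes = [K // n_groups] * n_groups
    for i in range(K % n_groups):
        sizes[i] += 1
    groups, start = [], 0
    for i, s in enumerate(sizes):
        groups.append(FilterGroup(f"BB{i + 1}", tuple(range(start, start + s))))
        start += s
    return validate_layout(FilterLayout(tuple(groups)))


@dataclass
class SimulationConfig:
    """Desk-scale defaults mirror the study design: 8 samples scanned twice on
    each of 3 microscopes, with the layer count and tile size scaled down so a
    full pipeline run stays interactive."""

    n_samples: int = 8
    n_microscopes: int = 3
    n_scan_repeats: int = 2
    n_layers: int = 12
    n_groups: int = 3
    height: int = 64
    width: int = 64
    hpfs_per_scan: int | Sequence[int] = 4  # scalar or per-sample
    tissue_fraction: float = 0.6
    scene: str = "texture"  # "texture" | "markers"
    n_components: int = 5  # markers mode: 4 markers + autofluorescence

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_microscopes, self.n_scan_repeats,
               self.n_layers, self.height, self.width) <= 0:
            raise ValueError("all simulation dimensions must be positive")
        if self.scene not in ("texture", "markers"):
            raise ValueError(f"unknown scene mode {self.scene!r}")
        if not 0 < self.tissue_fraction <= 1:
            raise ValueError("tissue_fraction must be in (0, 1]")

    @property
    def layout(self) -> FilterLayout:
        return _contiguous_layout(self.n_layers, self.n_groups)

    def hpf_counts(self) -> np.ndarray:
        """Number of HPFs per sample (shared across microscopes and scans —
        the same slide is re-scanned)."""
        h = self.hpfs_per_scan
        if np.isscalar(h):
            return np.full(self.n_samples, int(h), dtype=np.int64)
        arr = np.asarray(h, dtype=np.int64)
        if arr.shape != (self.n_samples,):
            raise ValueError("hpfs_per_scan must be a scalar or one count per sample")
        return arr


def _smooth_field(rng: np.random.Generator, h: int, w: int, sigma_frac: float = 0.125):
    """Zero-mean, unit-std smooth Gaussian random field."""
    raw = gaussian_filter(rng.standard_normal((h, w)), sigma=sigma_frac * min(h, w))
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def _smooth_ripple(rng: np.random.Generator, K: int, amplitude: float) -> np.ndarray:
    """exp of a smoothed, centred random walk over layers, std ~= amplitude."""
    if amplitude == 0:
        return np.ones(K)
    walk = gaussian_filter(rng.standard_normal(K), sigma=max(1.0, K / 8), mode="nearest")
    walk -= walk.mean()
    sd = walk.std()
    if sd > 0:
        walk *= amplitude / sd
    return np.exp(walk)


def _reference_library(rng: np.random.Generator, K: int, Kp: int) -> np.ndarray:
    """Well-conditioned non-negative library: one Gaussian emission bump per
    component spread across the layer axis, plus a broad autofluorescence
    column, each on a small floor."""
    centers = np.linspace(0.15, 0.85, Kp - 1) * (K - 1)
    k = np.arange(K)
    cols = []
    for c in centers:
        width = K / (2.5 * Kp) * (1.0 + 0.3 * rng.random())
        cols.append(np.exp(-0.5 * ((k - c) / width) ** 2) + 0.02)
    cols.append(0.35 + 0.1 * np.sin(2 * np.pi * k / K + rng.random()))  # autofluorescence
    L = np.stack(cols, axis=1)
    return L / L.sum(axis=0)


@dataclass
class TruthModel:
    """Planted generative factors plus acquisition nuisance parameters."""

    A_n: np.ndarray  # (N,) sample amplitudes
    g_m: np.ndarray  # (M,) microscope amplitudes
    t_nk: np.ndarray  # (N, K) sample spectral profiles
    g_ill_m: np.ndarray  # (M,) microscope illumination scales
    bb_offset: np.ndarray  # (M, G) broadband-group offsets, |.| <= bb_max
    nb_ripple: np.ndarray  # (M, K) narrowband ripple
    exposures_ms: np.ndarray  # (M, R, G) exposure times
    noise_cv: float = 0.01
    scan_jitter: float = 0.005
    background_flux: float = 1.0
    signal_flux: float = 100.0
    saturation_fraction: float = 0.002
    texture_sigma: float = 0.25
    seed: int = 0
    reference_library: np.ndarray | None = None  # (K, K'), markers mode
    component_names: tuple[str, ...] = ()

    def omega_mk(self, layout: FilterLayout) -> np.ndarray:
        """Microscope spectral profile: illumination x broadband x narrowband."""
        gi = layout.layer_group_indices()
        return self.g_ill_m[:, None] * (1.0 + self.bb_offset[:, gi]) * self.nb_ripple

    @classmethod
    def random(
        cls,
        config: SimulationConfig,
        seed: int = 0,
        bb_max: float = 0.20,
        sample_amp_sigma: float = 0.15,
        scope_amp_sigma: float = 0.10,
        tissue_ripple: float = 0.08,
        illum_sigma: float = 0.05,
        nb_ripple_amp: float = 0.03,
        noise_cv: float = 0.01,
        scan_jitter: float = 0.005,
        saturation_fraction: float = 0.002,
    ) -> "TruthModel":
        """Draw a realistic truth: sample brightness spread ~15%, microscope
        amplitude spread ~10%, broadband offsets up to +/- ``bb_max`` (20%
        default, the scale at which broadband filter cubes have been observed
        to differ), smooth few-percent narrowband ripple."""
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11CE]))
        N, M, G, K = (config.n_samples, config.n_microscopes, config.n_groups,
                      config.n_layers)
        A_n = np.exp(rng.normal(0.0, sample_amp_sigma, N))
        g_m = np.exp(rng.normal(0.0, scope_amp_sigma, M))
        t_nk = np.stack([_smooth_ripple(rng, K, tissue_ripple) for _ in range(N)])
        g_ill = np.exp(rng.normal(0.0, illum_sigma, M))
        bb = rng.uniform(-bb_max, bb_max, (M, G))
        nb = np.stack([_smooth_ripple(rng, K, nb_ripple_amp) for _ in range(M)])
        base = rng.uniform(10.0, 40.0, (M, G))  # per-(microscope, group) protocol
        per_scan = 1.0 + rng.uniform(-0.05, 0.05, (M, config.n_scan_repeats, G))
        exposures = base[:, None, :] * per_scan
        lib = None
        names: tuple[str, ...] = ()
        if config.scene == "markers":
            lib = _reference_library(rng, K, config.n_components)
            names = tuple(
                f"marker{j + 1}" for j in range(config.n_components - 1)
            ) + (AUTOFLUORESCENCE,)
        return cls(
            A_n=A_n, g_m=g_m, t_nk=t_nk, g_ill_m=g_ill, bb_offset=bb, nb_ripple=nb,
            exposures_ms=exposures, noise_cv=noise_cv, scan_jitter=scan_jitter,
            saturation_fraction=saturation_fraction, seed=seed,
            reference_library=lib, component_names=names,
        )

    def to_json(self, path: Path | str) -> None:
        doc = {
            "A_n": self.A_n.tolist(),
            "g_m": self.g_m.tolist(),
            "t_nk": self.t_nk.tolist(),
            "g_ill_m": self.g_ill_m.tolist(),
            "bb_offset": self.bb_offset.tolist(),
            "nb_ripple": self.nb_ripple.tolist(),
            "exposures_ms": self.exposures_ms.tolist(),
            "noise_cv": self.noise_cv,
            "scan_jitter": self.scan_jitter,
            "background_flux": self.background_flux,
            "signal_flux": self.signal_flux,
            "saturation_fraction": self.saturation_fraction,
            "texture_sigma": self.texture_sigma,
            "seed": self.seed,
            "reference_library": None
            if self.reference_library is None
            else self.reference_library.tolist(),
            "component_names": list(self.component_names),
        }
        with open(path, "w") as f:
            json.dump(doc, f)

    @classmethod
    def from_json(cls, path: Path | str) -> "TruthModel":
        with open(path) as f:
            doc = json.load(f)
        lib = doc.pop("reference_library")
        names = tuple(doc.pop("component_names"))
        arrays = {
            k: np.asarray(doc.pop(k))
            for k in ("A_n", "g_m", "t_nk", "g_ill_m", "bb_offset", "nb_ripple",
                      "exposures_ms")
        }
        return cls(
            **arrays,
            reference_library=None if lib is None else np.asarray(lib),
            component_names=names,
            **doc,
        )


@dataclass
class TileScene:
    """Per-(sample, tile) physical content, shared across microscopes/scans."""

    region: np.ndarray  # (H, W) bool tissue region
    texture: np.ndarray  # (H, W) multiplicative texture (texture mode)
    abundances: np.ndarray | None = None  # (H, W, K') marker maps (markers mode)

    def scene_spectrum(self, truth: TruthModel, K: int) -> np.ndarray:
        """(H, W, K) layer-resolved scene content before sample/scope factors."""
        if self.abundances is None:
            return np.broadcast_to(self.texture[:, :, None], self.texture.shape + (K,))
        return self.abundances @ truth.reference_library.T


@dataclass
class SimulatedDataset:
    """In-memory dataset with the duck-typed surface ``build_xbar`` expects,
    plus the ground truth needed for parameter-recovery experiments."""

    config: SimulationConfig
    truth: TruthModel
    sample_ids: tuple[str, ...]
    microscope_ids: tuple[str, ...]
    scans: list[ScanRecord]
    exposures: ExposureTable
    counts: dict  # scan key -> list of (H, W, K) uint16 arrays
    scenes: list[list[TileScene]]  # [n][h]
    mask_kwargs: dict = field(default_factory=dict)

    @property
    def layout(self) -> FilterLayout:
        return self.config.layout

    @property
    def K(self) -> int:
        return self.config.n_layers

    @property
    def n_scan_repeats(self) -> int:
        return self.config.n_scan_repeats

    def iter_scan(self, scan: ScanRecord):
        """Yield (FluxStack, TissueMask) pairs, masking each HPF on the fly.

        Quantized (uint16) tiles get Otsu + saturation masks computed from
        the data, as a real run would.  Unquantized (float) tiles — the
        exact noise-free validation mode — are divided by exposure directly
        and paired with the generator's true tissue regions.
        """
        for h, pixels in enumerate(self.counts[scan.key]):
            if pixels.dtype == np.uint16:
                hpf = HPFStack(pixels=pixels, scan=scan.key, tile_id=f"hpf{h:03d}")
                flux = exposure_normalize(hpf, self.exposures, self.layout)
                mask = compute_tissue_mask(hpf, flux=flux, **self.mask_kwargs)
            else:
                exp_k = self.exposures.per_layer(scan.key, self.layout)
                flux = FluxStack(pixels=pixels / exp_k, scan=scan.key,
                                 tile_id=f"hpf{h:03d}")
                mask = self._truth_mask(scan, h)
            yield flux, mask

    def _truth_mask(self, scan: ScanRecord, h: int) -> TissueMask:
        region = self.scenes[scan.n][h].region
        return TissueMask(
            mask=region.astype(np.uint8), n_background=int((~region).sum()),
            n_saturated=0, otsu_threshold=None, degenerate=False,
            scan=scan.key, tile_id=f"hpf{h:03d}",
        )

    def iter_scan_truth_masked(self, scan: ScanRecord):
        """Like ``iter_scan`` but always using the generator's true regions."""
        for h, pixels in enumerate(self.counts[scan.key]):
            if pixels.dtype == np.uint16:
                hpf = HPFStack(pixels=pixels, scan=scan.key, tile_id=f"hpf{h:03d}")
                flux = exposure_normalize(hpf, self.exposures, self.layout)
            else:
                exp_k = self.exposures.per_layer(scan.key, self.layout)
                flux = FluxStack(pixels=pixels / exp_k, scan=scan.key,
                                 tile_id=f"hpf{h:03d}")
            yield flux, self._truth_mask(scan, h)


def _draw_scenes(config: SimulationConfig, truth: TruthModel,
                 rng: np.random.Generator) -> list[list[TileScene]]:
    scenes: list[list[TileScene]] = []
    counts = config.hpf_counts()
    for n in range(config.n_samples):
        tiles = []
        for _ in range(counts[n]):
            shape_field = _smooth_field(rng, config.height, config.width)
            cut = np.quantile(shape_field, 1.0 - config.tissue_fraction)
            region = shape_field > cut
            texture = np.exp(truth.texture_sigma * _smooth_field(rng, config.height,
                                                                 config.width))
            ab = None
            if config.scene == "markers":
                Kp = config.n_components
                ab = np.empty((config.height, config.width, Kp))
                for j in range(Kp - 1):
                    ab[:, :, j] = np.exp(
                        0.6 * _smooth_field(rng, config.height, config.width)
                    ) * rng.uniform(0.3, 1.0)
                ab[:, :, Kp - 1] = 0.5 * np.exp(
                    0.3 * _smooth_field(rng, config.height, config.width)
                )  # autofluorescence floor
                ab *= texture[:, :, None]
            tiles.append(TileScene(region=region, texture=texture, abundances=ab))
        scenes.append(tiles)
    return scenes


def _expected_flux(
    scene: TileScene, n: int, m: int, truth: TruthModel, layout: FilterLayout
) -> np.ndarray:
    """Noiseless expected flux of one tile on one microscope (counts/ms)."""
    K = layout.K
    omega = truth.omega_mk(layout)
    spectrum = scene.scene_spectrum(truth, K)  # (H, W, K)
    factors = truth.A_n[n] * truth.g_m[m] * truth.t_nk[n] * omega[m]  # (K,)
    signal = truth.signal_flux * spectrum * factors
    return truth.background_flux + scene.region[:, :, None] * signal


def simulate_dataset(
    config: SimulationConfig,
    truth: TruthModel | None = None,
    seed: int | None = None,
    quantize: bool = True,
    noise_seed: int | None = None,
) -> SimulatedDataset:
    """Generate the full synthetic dataset in memory.

    Deterministic: the same config/truth/seed always produce identical
    counts.  ``seed`` defaults to ``truth.seed``.  With ``quantize=False``
    the counts stay floating point (no rounding/clipping/saturation) and the
    dataset carries the true tissue regions as masks — the exact noise-free
    validation mode.  ``noise_seed`` redraws only the acquisition noise
    (counting noise, scan jitter, saturation placement) while keeping the
    physical slides — the scenes — fixed, as re-scanning would.
    """
    if truth is None:
        truth = TruthModel.random(config, seed=seed or 0)
    base_seed = truth.seed if seed is None else seed
    # scenes (the physical slides) and acquisition noise use separate streams
    # so repeated scans of the same slides can be simulated with fresh noise
    scenes = _draw_scenes(
        config, truth, np.random.default_rng(np.random.SeedSequence([base_seed, 0x5CE]))
    )
    rng = np.random.default_rng(
        np.random.SeedSequence([noise_seed if noise_seed is not None else base_seed,
                                0xDA7A])
    )
    layout = config.layout
    counts_per_sample = config.hpf_counts()

    sample_ids = tuple(f"sample{n}" for n in range(config.n_samples))
    microscope_ids = tuple(f"scope{m}" for m in range(config.n_microscopes))

    scans: list[ScanRecord] = []
    exposures: dict = {}
    counts: dict = {}
    group_names = layout.group_names
    gi = layout.layer_group_indices()
    H, W, K = config.height, config.width, config.n_layers
    n_sat = int(round(truth.saturation_fraction * H * W))

    for n in range(config.n_samples):
        for m in range(config.n_microscopes):
            for r in range(config.n_scan_repeats):
                key = (sample_ids[n], microscope_ids[m], r)
                rec = ScanRecord(
                    sample_id=key[0], microscope_id=key[1], scan_index=r,
                    n=n, m=m, r=r, hmrn=int(counts_per_sample[n]),
                )
                scans.append(rec)
                for g, name in enumerate(group_names):
                    exposures[(key, name)] = float(truth.exposures_ms[m, r, g])
                exp_k = truth.exposures_ms[m, r][gi]  # (K,)
                jitter = 1.0 + truth.scan_jitter * rng.standard_normal()
                tiles = []
                for h in range(counts_per_sample[n]):
                    flux = _expected_flux(scenes[n][h], n, m, truth, layout) * jitter
                    noisy = flux * (
                        1.0 + truth.noise_cv * rng.standard_normal((H, W, K))
                    )
                    c = exp_k * noisy
                    if not quantize:
                        tiles.append(c)
                        continue
                    if n_sat > 0:
                        idx = rng.choice(H * W, size=n_sat, replace=False)
                        lay = rng.integers(0, K, size=n_sat)
                        c.reshape(-1, K)[idx, lay] = 65535.0
                    tiles.append(
                        np.clip(np.rint(c), 0, 65535).astype(np.uint16)
                    )
                counts[key] = tiles

    ds = SimulatedDataset(
        config=config, truth=truth,
        sample_ids=sample_ids, microscope_ids=microscope_ids,
        scans=scans, exposures=ExposureTable(exposures),
        counts=counts, scenes=scenes,
    )
    sat_everywhere = all(
        (t >= 65535).all() for tiles in counts.values() for t in tiles
    )
    if sat_everywhere:
        raise ValueError("configuration saturates every pixel; reduce exposure or flux")
    return ds


def simulate_to_disk(
    dataset: SimulatedDataset, outdir: Path | str
) -> Path:
    """Write the dataset as TIFF tiles + YAML manifest + truth JSON.

    Returns the manifest path.  Same dataset -> byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for scan in dataset.scans:
        key = scan.key
        subdir = outdir / f"{key[0]}_{key[1]}_r{key[2]}"
        subdir.mkdir(exist_ok=True)
        for h, pixels in enumerate(dataset.counts[key]):
            write_hpf(subdir / f"hpf{h:03d}.tif",
                      HPFStack(pixels=pixels, scan=key, tile_id=f"hpf{h:03d}"))
        entries.append(
            {
                "sample": key[0],
                "microscope": key[1],
                "scan": key[2],
                "hpfs": f"{subdir.name}/hpf*.tif",
                "n_hpfs": len(dataset.counts[key]),
                "exposures_ms": {
                    g.name: dataset.exposures.exposure(key, g.name)
                    for g in dataset.layout.groups
                },
            }
        )
    manifest = outdir / "manifest.yaml"
    write_dataset_manifest(
        manifest, dataset.layout, dataset.sample_ids, dataset.microscope_ids,
        entries, height=dataset.config.height, width=dataset.config.width,
    )
    dataset.truth.to_json(outdir / "truth.json")
    if dataset.truth.reference_library is not None:
        SpectralLibrary(
            matrix=dataset.truth.reference_library,
            component_names=dataset.truth.component_names,
            microscope_id="reference",
        ).to_frame().to_csv(outdir / "library_reference.csv", index=False)
    return manifest


@dataclass
class GaugeFixedTruth:
    """Planted factors re-expressed in the estimators' mean-one gauges."""

    B_n: np.ndarray
    C_m: np.ndarray
    b_nk: np.ndarray
    w_mk: np.ndarray
    beta_nk: np.ndarray
    X: SpectraTensor  # noiseless expected stage-X tensor


def gauge_fix_truth(
    truth: TruthModel, config: SimulationConfig,
    scenes: list[list[TileScene]] | None = None,
) -> GaugeFixedTruth:
    """Push the noiseless expected dataset through the exact reduction and
    fit equations to express the planted factors in the fitted gauge.

    The multiplicative model identifies factors only up to the mean-one
    normalization conventions; on top of that, masked spatial averaging over
    each sample's own tiles enters the expected spectra.  Using the true tile
    scenes (drawn here with the dataset's seed when not supplied) makes the
    result the exact noise-free limit of the fitted factors.
    """
    if scenes is None:
        rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x5CE]))
        scenes = _draw_scenes(config, truth, rng)
    layout = config.layout
    N, M, R, K = (config.n_samples, config.n_microscopes, config.n_scan_repeats,
                  config.n_layers)
    HW = config.height * config.width
    counts = config.hpf_counts()
    xbar = np.empty((N, M, R, K))
    hmrn = np.zeros((N, M, R), dtype=np.int64)
    for n in range(N):
        for m in range(M):
            # Mean image over the sample's tiles with true-region masks;
            # Eq-style layer mean divides by the full H*W.
            num = np.zeros((config.height, config.width, K))
            den = np.zeros((config.height, config.width), dtype=np.int64)
            for h in range(counts[n]):
                sc = scenes[n][h]
                num += sc.region[:, :, None] * _expected_flux(sc, n, m, truth, layout)
                den += sc.region
            mean_img = np.zeros_like(num)
            np.divide(num, den[:, :, None], out=mean_img,
                      where=(den > 0)[:, :, None])
            spectrum = mean_img.sum(axis=(0, 1)) / HW
            for r in range(R):
                xbar[n, m, r] = spectrum
                hmrn[n, m, r] = counts[n]
    tensor = SpectraTensor(values=xbar, stage="Xbar")
    X = grand_normalize(hpf_fraction_weight(tensor, hmrn))
    amps = amplitude_summary(X)
    f = fit_amplitude_factors(amps)
    x = apply_amplitude(X, f)
    tp = fit_tissue_profile(x)
    y = apply_tissue_profile(x, tp)
    mp = fit_microscope_profile(y)
    _, beta_nk, _ = tissue_homogenize(X, f.B_n)
    return GaugeFixedTruth(
        B_n=f.B_n, C_m=f.C_m, b_nk=tp.b_nk, w_mk=mp.w_mk, beta_nk=beta_nk, X=X
    )


def microscope_library(
    truth: TruthModel, config: SimulationConfig, m: int, microscope_id: str = ""
) -> SpectralLibrary:
    """Per-microscope pure-spectra library: the reference library seen through
    microscope m's amplitude and spectral profile, then column-normalized.

    Pure-spectrum libraries are captured on each instrument and carry shape
    only (columns are normalized), so unmixing with its own library
    compensates a microscope's spectral shape but not its overall amplitude.
    """
    if truth.reference_library is None:
        raise ValueError("truth has no reference library (scene mode 'markers')")
    omega = truth.omega_mk(config.layout)
    projected = (truth.g_m[m] * omega[m])[:, None] * truth.reference_library
    return SpectralLibrary(
        matrix=projected,
        component_names=truth.component_names,
        microscope_id=microscope_id or f"scope{m}",
    ).normalized()
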