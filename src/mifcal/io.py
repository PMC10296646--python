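"""Reading and writing of HPF image stacks, filter layouts, and dataset manifests.

A whole-slide multispectral scan is stored as a collection of "high-power
field" (HPF) tiles, each an H x W x K stack of unsigned 16-bit counts, one
page per narrowband image layer in a multi-page TIFF.  Layers are grouped by
the static broadband filter cube through which they were acquired; exposure
times are set per (scan, broadband group) by the instrument's auto-exposure,
so exposure normalization broadcasts a group's exposure to its member layers.

A dataset is described by a YAML manifest listing samples, microscopes,
scans, HPF file globs, the filter layout, and the exposure table.
"""

from __future__ import annotations

import glob as _glob
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "LayoutError",
    "ManifestError",
    "FilterGroup",
    "FilterLayout",
    "validate_layout",
    "default_layout",
    "ExposureTable",
    "ScanRecord",
    "HPFStack",
    "FluxStack",
    "read_hpf",
    "write_hpf",
    "exposure_normalize",
    "DatasetManifest",
    "read_dataset_manifest",
    "write_dataset_manifest",
]

#: Scan identity: (sample_id, microscope_id, scan_index).
ScanKey = tuple[str, str, int]


class LayoutError(ValueError):
    """Raised when a filter layout does not partition the layer set."""


class ManifestError(ValueError):
    """Raised when a dataset manifest is inconsistent with what is on disk."""


@dataclass(frozen=True)
class FilterGroup:
    """One broadband filter cube and the narrowband layers acquired through it."""

    name: str
    layers: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(int(k) for k in self.layers))


@dataclass(frozen=True)
class FilterLayout:
    """Ordered partition of the K image layers into broadband filter groups.

    Layer indices are 0-based; the order of layers in the manifest defines
    the layer index k used everywhere downstream.
    """

    groups: tuple[FilterGroup, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "groups",
            tuple(g if isinstance(g, FilterGroup) else FilterGroup(*g) for g in self.groups),
        )

    @property
    def K(self) -> int:
        return sum(len(g.layers) for g in self.groups)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def layer_group_indices(self) -> np.ndarray:
        """Group index of every layer, shape (K,)."""
        out = np.empty(self.K, dtype=np.intp)
        for gi, g in enumerate(self.groups):
            out[list(g.layers)] = gi
        return out

    def group_of(self, k: int) -> str:
        for g in self.groups:
            if k in g.layers:
                return g.name
        raise LayoutError(f"layer {k} not present in layout")


def validate_layout(layout: FilterLayout) -> FilterLayout:
    """Check that the groups are non-empty and exactly partition {0..K-1}.

    Returns the layout unchanged when valid; raises :class:`LayoutError`
    naming the offending layer or group otherwise.
    """
    seen: dict[int, str] = {}
    for g in layout.groups:
        if len(g.layers) == 0:
            raise LayoutError(f"broadband group {g.name!r} has no layers")
        for k in g.layers:
            if k in seen:
                raise LayoutError(
                    f"layer {k} appears in both group {seen[k]!r} and group {g.name!r}"
                )
            seen[k] = g.name
    K = len(seen)
    missing = sorted(set(range(K)) - set(seen))
    if K == 0:
        raise LayoutError("layout has no layers")
    if missing or max(seen) != K - 1:
        bad = missing if missing else [max(seen)]
        raise LayoutError(f"layer indices do not form 0..{K - 1}: offending index {bad[0]}")
    return layout


def default_layout() -> FilterLayout:
    """Placeholder 43-layer layout: 7 contiguous broadband blocks.

    The true instrument mapping of narrowband layers to the seven broadband
    filter cubes is instrument documentation not shipped here; this default
    partitions the 43 layers into 7 contiguous blocks (7 + 6x6) and is meant
    to be replaced by the real mapping via the manifest.
    """
    sizes = (7, 6, 6, 6, 6, 6, 6)
    groups = []
    start = 0
    for i, s in enumerate(sizes):
        groups.append(FilterGroup(f"BB{i + 1}", tuple(range(start, start + s))))
        start += s
    return validate_layout(FilterLayout(tuple(groups)))


@dataclass
class ExposureTable:
    """Exposure times in milliseconds, keyed by (scan identity, broadband group)."""

    entries: dict[tuple[ScanKey, str], float]

    def __post_init__(self) -> None:
        for (scan, group), ms in self.entries.items():
            if not np.isfinite(ms) or ms <= 0:
                raise ManifestError(
                    f"exposure for scan {scan} group {group!r} must be positive, got {ms}"
                )

    def exposure(self, scan: ScanKey, group: str) -> float:
        try:
            return self.entries[(scan, group)]
        except KeyError:
            raise ManifestError(f"no exposure entry for scan {scan}, group {group!r}") from None

    def per_layer(self, scan: ScanKey, layout: FilterLayout) -> np.ndarray:
        """Broadcast group exposures to a (K,) per-layer vector."""
        out = np.empty(layout.K, dtype=np.float64)
        for g in layout.groups:
            out[list(g.layers)] = self.exposure(scan, g.name)
        return out


@dataclass
class ScanRecord:
    """One scan repeat of one sample on one microscope."""

    sample_id: str
    microscope_id: str
    scan_index: int
    n: int  # sample index 0..N-1
    m: int  # microscope index 0..M-1
    r: int  # scan-repeat index 0..R-1
    hmrn: int  # number of HPF tiles acquired in this scan
    hpf_paths: tuple[Path, ...] = ()

    def __post_init__(self) -> None:
        if self.hmrn < 0:
            raise ManifestError(f"scan {self.key} has negative HPF count {self.hmrn}")

    @property
    def key(self) -> ScanKey:
        return (self.sample_id, self.microscope_id, self.scan_index)


@dataclass
class HPFStack:
    """One high-power field: H x W x K unsigned 16-bit counts."""

    pixels: np.ndarray
    scan: ScanKey
    tile_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"HPF pixels must be H x W x K, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint16:
            if np.issubdtype(self.pixels.dtype, np.integer) and (
                self.pixels.min(initial=0) >= 0 and self.pixels.max(initial=0) <= 65535
            ):
                self.pixels = self.pixels.astype(np.uint16)
            else:
                raise ValueError("HPF pixel counts must be unsigned 16-bit integers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class FluxStack:
    """Exposure-normalized HPF: H x W x K non-negative reals in counts/ms."""

    pixels: np.ndarray
    scan: ScanKey
    tile_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError(f"flux pixels must be H x W x K, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("flux values must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def write_hpf(path: Path | str, hpf: HPFStack) -> None:
    """Write an HPF stack as a multi-page TIFF, one 16-bit grayscale page per layer."""
    pages = np.moveaxis(hpf.pixels, -1, 0)  # (K, H, W)
    tifffile.imwrite(str(path), pages, photometric="minisblack")


def read_hpf(path: Path | str, scan: ScanKey, tile_id: str | None = None) -> HPFStack:
    """Read a multi-page TIFF written by :func:`write_hpf` (page order = layer order)."""
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:  # single-layer stack
        pages = pages[None]
    pixels = np.moveaxis(pages, 0, -1)
    return HPFStack(pixels=pixels, scan=scan, tile_id=tile_id or Path(path).stem)


def exposure_normalize(
    hpf: HPFStack, exposures: ExposureTable, layout: FilterLayout
) -> FluxStack:
    """Convert raw counts to flux (counts/ms) by dividing each layer by its
    broadband group's exposure time for this scan."""
    per_layer = exposures.per_layer(hpf.scan, layout)
    flux = hpf.pixels.astype(np.float64) / per_layer
    return FluxStack(pixels=flux, scan=hpf.scan, tile_id=hpf.tile_id)


@dataclass
class DatasetManifest:
    """A resolved on-disk dataset: scans, layout, and exposure table."""

    root: Path
    layout: FilterLayout
    sample_ids: tuple[str, ...]
    microscope_ids: tuple[str, ...]
    scans: list[ScanRecord]
    exposures: ExposureTable
    height: int | None = None
    width: int | None = None

    @property
    def K(self) -> int:
        return self.layout.K

    def iter_hpfs(self, scan: ScanRecord) -> Iterator[HPFStack]:
        for p in scan.hpf_paths:
            yield read_hpf(p, scan.key)


def _layout_from_dict(d: Mapping) -> FilterLayout:
    groups = tuple(
        FilterGroup(str(g["name"]), tuple(int(k) for k in g["layers"])) for g in d["groups"]
    )
    return validate_layout(FilterLayout(groups))


def _layout_to_dict(layout: FilterLayout) -> dict:
    return {"groups": [{"name": g.name, "layers": list(g.layers)} for g in layout.groups]}


def read_dataset_manifest(path: Path | str) -> DatasetManifest:
    """Read and validate a YAML dataset manifest.

    Validations: the filter layout partitions the layers; every scan's HPF
    glob resolves to the declared number of files; each (scan, group) pair
    has exactly one positive exposure; (sample, microscope, scan) keys are
    unique.  A scan with zero HPFs is allowed but warned about.
    """
    path = Path(path)
    with open(path) as f:
        doc = yaml.safe_load(f)
    root = path.parent
    layout = _layout_from_dict(doc["layout"])

    sample_ids = tuple(str(s) for s in doc["samples"])
    microscope_ids = tuple(str(m) for m in doc["microscopes"])
    n_of = {s: i for i, s in enumerate(sample_ids)}
    m_of = {m: i for i, m in enumerate(microscope_ids)}

    scans: list[ScanRecord] = []
    exposures: dict[tuple[ScanKey, str], float] = {}
    seen: set[ScanKey] = set()
    for entry in doc["scans"]:
        key: ScanKey = (str(entry["sample"]), str(entry["microscope"]), int(entry["scan"]))
        if key in seen:
            raise ManifestError(f"duplicate scan entry {key}")
        seen.add(key)
        patterns = entry["hpfs"]
        if isinstance(patterns, str):
            patterns = [patterns]
        paths: list[Path] = []
        for pat in patterns:
            paths.extend(sorted(Path(p) for p in _glob.glob(str(root / pat))))
        declared = entry.get("n_hpfs")
        if declared is not None and int(declared) != len(paths):
            raise ManifestError(
                f"scan {key}: manifest declares {declared} HPFs but {len(paths)} found"
            )
        if len(paths) == 0:
            warnings.warn(f"scan {key} has zero HPF files", stacklevel=2)
        exp = entry.get("exposures_ms", {})
        for g in layout.groups:
            if g.name not in exp:
                raise ManifestError(f"missing exposure for scan {key}, group {g.name!r}")
            exposures[(key, g.name)] = float(exp[g.name])
        scans.append(
            ScanRecord(
                sample_id=key[0],
                microscope_id=key[1],
                scan_index=key[2],
                n=n_of[key[0]],
                m=m_of[key[1]],
                r=int(entry["scan"]),
                hmrn=len(paths),
                hpf_paths=tuple(paths),
            )
        )

    image = doc.get("image", {})
    return DatasetManifest(
        root=root,
        layout=layout,
        sample_ids=sample_ids,
        microscope_ids=microscope_ids,
        scans=scans,
        exposures=ExposureTable(exposures),
        height=image.get("height"),
        width=image.get("width"),
    )


def write_dataset_manifest(
    path: Path | str,
    layout: FilterLayout,
    sample_ids: Sequence[str],
    microscope_ids: Sequence[str],
    scan_entries: Sequence[dict],
    height: int | None = None,
    width: int | None = None,
) -> None:
    """Write a manifest YAML.  ``scan_entries`` items carry keys
    sample/microscope/scan/hpfs/n_hpfs/exposures_ms as produced by the simulator."""
    doc = {
        "layout": _layout_to_dict(layout),
        "samples": list(sample_ids),
        "microscopes": list(microscope_ids),
        "scans": list(scan_entries),
    }
    if height is not None:
        doc["image"] = {"height": int(height), "width": int(width)}
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)
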