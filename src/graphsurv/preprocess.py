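"""CT tumour-ROI preprocessing: windowing, standard crop, resize, 2D montage.

The pipeline turns a manually delineated 3D tumour volume into a fixed
384x384 2D montage (a 6x6 grid of 36 ordered axial slices) and then into a
fixed-length node-feature vector via a pluggable featurizer.  The default
featurizer computes per-tile summary statistics; adapters for learned
feature extractors can be registered behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
from skimage.transform import resize as _skimage_resize

CROP_SHAPE = (128, 128, 64)
RESIZE_SHAPE = (64, 64, 36)
TILE = 64
GRID = 6
N_TILES = GRID * GRID  # 36 ordered tiles, row-major, one axial slice each
MONTAGE_SIDE = TILE * GRID  # 384


class VolumeValidationError(ValueError):
    pass


class FeaturizerConfigError(KeyError):
    """Unknown featurizer name or invalid featurizer configuration."""


@dataclass
class TumorVolume:
    """A 3D intensity array (CT attenuation) with voxel spacing in mm."""

    intensities: np.ndarray
    voxel_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise VolumeValidationError(
                f"expected a non-empty 3D array, got shape {self.intensities.shape}"
            )
        if any(s <= 0 for s in self.voxel_spacing):
            raise VolumeValidationError(f"non-positive voxel spacing {self.voxel_spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class Montage2D:
    """384x384 image of 36 axial slices tiled row-major (slice k at row k//6, col k%6)."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (MONTAGE_SIDE, MONTAGE_SIDE):
            raise VolumeValidationError(
                f"montage must be {MONTAGE_SIDE}x{MONTAGE_SIDE}, got {self.pixels.shape}"
            )
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise VolumeValidationError("montage values must lie in [0, 1]")

    @staticmethod
    def tile_position(k: int) -> Tuple[int, int]:
        return divmod(k, GRID)


@dataclass
class FeatureVector:
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise VolumeValidationError("feature vector contains non-finite values")

    @property
    def d(self) -> int:
        return self.values.size


def normalize_volume(
    vol: TumorVolume,
    window_low: float = -1000.0,
    window_high: float = 400.0,
    bone_threshold: float = 400.0,
) -> TumorVolume:
    """Window the CT intensities to [0, 1] and zero out bone-bright voxels.

    Voxels strictly above ``bone_threshold`` (surrounding bone and other
    high-attenuation structures) are removed, i.e. mapped to 0 in the output;
    remaining intensities are clipped to ``[window_low, window_high]`` and
    rescaled linearly to [0, 1].
    """
    if not window_low < window_high:
        raise VolumeValidationError("window_low must be < window_high")
    x = vol.intensities
    out = (np.clip(x, window_low, window_high) - window_low) / (window_high - window_low)
    out[x > bone_threshold] = 0.0
    return TumorVolume(out, vol.voxel_spacing)


def standardize_crop(vol: TumorVolume, target: Tuple[int, int, int] = CROP_SHAPE) -> TumorVolume:
    """Fix the segment to 128x128x64: centre zero-pad small axes, centre-crop large ones."""
    x = vol.intensities
    out = np.zeros(target, dtype=x.dtype)
    src_slices, dst_slices = [], []
    for size, tgt in zip(x.shape, target):
        if size <= tgt:
            off = (tgt - size) // 2
            src_slices.append(slice(0, size))
            dst_slices.append(slice(off, off + size))
        else:
            off = (size - tgt) // 2
            src_slices.append(slice(off, off + tgt))
            dst_slices.append(slice(0, tgt))
    out[tuple(dst_slices)] = x[tuple(src_slices)]
    return TumorVolume(out, vol.voxel_spacing)


def resize_volume(vol: TumorVolume, target: Tuple[int, int, int] = RESIZE_SHAPE) -> TumorVolume:
    """Trilinear downsample of the standardized 128x128x64 segment to 64x64x36."""
    if vol.shape != CROP_SHAPE:
        raise VolumeValidationError(f"expected {CROP_SHAPE} input, got {vol.shape}")
    out = _skimage_resize(
        vol.intensities, target, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return TumorVolume(out, vol.voxel_spacing)


def make_montage(vol: TumorVolume) -> Montage2D:
    """Tile the 36 axial slices of a 64x64x36 volume into a 384x384 image.

    Slices are taken along the third axis in ascending order; slice k lands
    at grid position (k // 6, k % 6), six slices per row.
    """
    if vol.shape != RESIZE_SHAPE:
        raise VolumeValidationError(f"expected {RESIZE_SHAPE} input, got {vol.shape}")
    pixels = np.zeros((MONTAGE_SIDE, MONTAGE_SIDE), dtype=float)
    for k in range(N_TILES):
        r, c = divmod(k, GRID)
        pixels[r * TILE:(r + 1) * TILE, c * TILE:(c + 1) * TILE] = vol.intensities[:, :, k]
    return Montage2D(pixels)


def split_montage(m: Montage2D) -> np.ndarray:
    """Return the 36 ordered 64x64 tiles of a montage, shape (36, 64, 64)."""
    tiles = np.empty((N_TILES, TILE, TILE), dtype=float)
    for k in range(N_TILES):
        r, c = divmod(k, GRID)
        tiles[k] = m.pixels[r * TILE:(r + 1) * TILE, c * TILE:(c + 1) * TILE]
    return tiles


# --------------------------------------------------------------------------
# Featurizers

@dataclass
class FeaturizerConfig:
    """Selects and parameterizes the montage-to-vector featurizer.

    ``dim`` is the output length (default 768, the width of the learned
    feature extractor the adapter hook is designed for); the default
    tile-stats featurizer zero-pads or truncates its raw statistics to it.
    """

    name: str = "tile-stats"
    dim: int = 768
    quantiles: Tuple[float, ...] = (0.25, 0.5, 0.75)
    extra: dict = field(default_factory=dict)


def _tile_stats_featurizer(m: Montage2D, cfg: FeaturizerConfig) -> np.ndarray:
    tiles = split_montage(m)
    stats = [tiles.mean(axis=(1, 2)), tiles.std(axis=(1, 2))]
    for q in cfg.quantiles:
        stats.append(np.quantile(tiles, q, axis=(1, 2)))
    # per-tile blocks [mean, sd, q...] concatenated in tile order
    return np.stack(stats, axis=1).ravel()


_FEATURIZERS: Dict[str, Callable[[Montage2D, FeaturizerConfig], np.ndarray]] = {
    "tile-stats": _tile_stats_featurizer,
}


def register_featurizer(name: str, fn: Callable[[Montage2D, FeaturizerConfig], np.ndarray]) -> None:
    """Register an external featurizer adapter under ``name``."""
    _FEATURIZERS[name] = fn


def featurize(m: Montage2D, cfg: Optional[FeaturizerConfig] = None) -> FeatureVector:
    """Map a montage to a deterministic fixed-length feature vector."""
    cfg = cfg or FeaturizerConfig()
    try:
        fn = _FEATURIZERS[cfg.name]
    except KeyError:
        raise FeaturizerConfigError(
            f"unknown featurizer {cfg.name!r}; available: {sorted(_FEATURIZERS)}"
        ) from None
    raw = np.asarray(fn(m, cfg), dtype=float).ravel()
    if raw.size >= cfg.dim:
        out = raw[:cfg.dim]
    else:
        out = np.zeros(cfg.dim)
        out[:raw.size] = raw
    return FeatureVector(out)


def preprocess_volume(
    vol: TumorVolume,
    window_low: float = -1000.0,
    window_high: float = 400.0,
    bone_threshold: float = 400.0,
) -> Montage2D:
    """Full normalize -> crop -> resize -> montage chain."""
    v = normalize_volume(vol, window_low, window_high, bone_threshold)
    v = standardize_crop(v)
    v = resize_volume(v)
    return make_montage(v)


# --------------------------------------------------------------------------
# I/O

def read_nifti(path) -> TumorVolume:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TumorVolume(np.asanyarray(img.dataobj, dtype=float), spacing)


def write_nifti(vol: TumorVolume, path) -> None:
    import nibabel as nib

    affine = np.diag(list(vol.voxel_spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine), str(path))


def write_montage_png(m: Montage2D, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.clip(m.pixels, 0, 1) * 255).astype(np.uint8))
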