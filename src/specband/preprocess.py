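"""Plant-image preprocessing: reflectance conversion, capping, mask
application, edge-band trimming and tiling with a coverage filter.

The pipeline turns a whole-plant cube into model-ready 64×64 samples:

1. ratio the radiance cube against the mean spectrum of a calibrated
   reflectance panel (simplified flat-field conversion),
2. cap reflectance into [0, 1] (saturated pixels),
3. zero the background using the segmentation mask,
4. drop the first and last few channels of each sensor block (noisy band
   edges; 5 per edge turns 160 VNIR + 288 SWIR bands into 428),
5. slice the image into a non-overlapping 64×64 grid and keep only tiles whose
   plant-pixel fraction reaches the coverage threshold (default 90%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import HyperCube, PlantImage, Sample


@dataclass
class TileSpec:
    """Tiling and filtering parameters."""

    tile_hw: tuple = (64, 64)
    coverage_threshold: float = 0.90
    stride: int | None = None  # defaults to tile height (non-overlapping grid)
    n_edge_trim: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")
        if self.stride is None:
            self.stride = self.tile_hw[0]
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def to_reflectance(radiance: HyperCube, panel_pixels, panel_reflectance: float = 0.20
                   ) -> HyperCube:
    """Ratio-convert radiance to reflectance against a reference panel.

    ``out[c,i,j] = radiance[c,i,j] / mean_panel_radiance[c] * panel_reflectance``
    where the panel mean spectrum is taken over ``panel_pixels`` (a sequence of
    ``(row, col)`` indices on the panel).
    """
    pix = list(panel_pixels)
    if not pix:
        raise ValueError("panel_pixels must be non-empty")
    rows = np.array([p[0] for p in pix])
    cols = np.array([p[1] for p in pix])
    panel_mean = radiance.values[:, rows, cols].mean(axis=1)
    bad = np.flatnonzero(panel_mean <= 0)
    if bad.size:
        raise ValueError(
            f"panel mean radiance non-positive in channel(s) {bad.tolist()}")
    values = radiance.values / panel_mean[:, None, None] * panel_reflectance
    return HyperCube(values, radiance.wavelengths_nm, radiance.sensor_boundary)


def cap_reflectance(cube: HyperCube) -> HyperCube:
    """Clip all values into [0, 1]; values already inside are unchanged."""
    return HyperCube(np.clip(cube.values, 0.0, 1.0),
                     cube.wavelengths_nm, cube.sensor_boundary)


def trim_edge_bands(cube: HyperCube, n_edge_trim: int = 5) -> HyperCube:
    """Remove ``n_edge_trim`` channels from both ends of the VNIR block and of
    the SWIR block, updating wavelengths and the sensor boundary."""
    if n_edge_trim == 0:
        return cube
    if n_edge_trim < 0:
        raise ValueError("n_edge_trim must be >= 0")
    c, b = cube.n_channels, cube.sensor_boundary
    n_vnir, n_swir = b, c - b
    if n_vnir <= 2 * n_edge_trim or n_swir <= 2 * n_edge_trim:
        raise ValueError(
            f"sensor blocks ({n_vnir} VNIR, {n_swir} SWIR) too small to trim "
            f"{n_edge_trim} channels from each end")
    keep = np.r_[n_edge_trim:b - n_edge_trim, b + n_edge_trim:c - n_edge_trim]
    return HyperCube(cube.values[keep], cube.wavelengths_nm[keep],
                     n_vnir - 2 * n_edge_trim)


def apply_mask(cube: HyperCube, mask: np.ndarray) -> HyperCube:
    """Zero background pixels (mask False) in all channels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.spatial_shape:
        raise ValueError(f"mask shape {mask.shape} does not match cube spatial "
                         f"shape {cube.spatial_shape}")
    values = cube.values.copy()
    values[:, ~mask] = 0
    return HyperCube(values, cube.wavelengths_nm, cube.sensor_boundary)


def slice_samples(cube: HyperCube, mask: np.ndarray, spec: TileSpec,
                  meta: dict) -> list[Sample]:
    """Cut the image into grid tiles and keep those with enough plant coverage.

    Tiles are anchored at (0, 0) on a non-overlapping grid (stride = tile
    size by default); remainder rows/columns that cannot fit a full tile are
    discarded. A tile is kept iff the fraction of mask-true pixels inside it is
    ``>= coverage_threshold``. Each kept sample gets the deterministic id
    ``{identifier}_s{imaging}_r{row}_c{col}``.
    """
    mask = np.asarray(mask, dtype=bool)
    th, tw = spec.tile_hw
    h, w = cube.spatial_shape
    samples: list[Sample] = []
    for r in range(0, h - th + 1, spec.stride):
        for c in range(0, w - tw + 1, spec.stride):
            tile_mask = mask[r:r + th, c:c + tw]
            if tile_mask.mean() >= spec.coverage_threshold:
                samples.append(Sample(
                    data=cube.values[:, r:r + th, c:c + tw],
                    sample_id=f"{meta['identifier']}_s{meta['imaging']}_r{r}_c{c}",
                    imaging=int(meta["imaging"]),
                    identifier=str(meta["identifier"]),
                    treatment=str(meta["treatment"]),
                    variety=str(meta["variety"]),
                    wavelengths_nm=cube.wavelengths_nm,
                    mask=tile_mask,
                ))
    return samples


def ndvi_mask(cube: HyperCube, threshold: float = 0.3) -> np.ndarray:
    """NDVI-threshold vegetation mask, ``(R_800 - R_670)/(R_800 + R_670) > t``.

    A convenience segmenter for real imports; the synthetic generator carries
    its own ground-truth mask.
    """
    wl = cube.wavelengths_nm
    i800 = int(np.argmin(np.abs(wl - 800.0)))
    i670 = int(np.argmin(np.abs(wl - 670.0)))
    r800, r670 = cube.values[i800], cube.values[i670]
    denom = r800 + r670
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom > 0, (r800 - r670) / denom, 0.0)
    return ndvi > threshold


def preprocess_plant_image(img: PlantImage, spec: TileSpec | None = None) -> list[Sample]:
    """Full pipeline on an already-reflectance plant image: cap → mask → trim →
    slice. (Reflectance conversion is applied upstream when starting from
    radiance.)"""
    spec = spec or TileSpec()
    cube = cap_reflectance(img.cube)
    cube = apply_mask(cube, img.mask)
    cube = trim_edge_bands(cube, spec.n_edge_trim)
    meta = {"imaging": img.imaging, "identifier": img.identifier,
            "treatment": img.treatment, "variety": img.variety}
    return slice_samples(cube, img.mask, spec, meta)
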