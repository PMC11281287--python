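"""Synthetic dual-sensor hyperspectral experiments with planted ground truth.

The generator emulates a greenhouse drought trial: a cohort of plants, half
well-watered (treatment ``C``) and half water-deficient (``D``), imaged weekly
over several sessions with a VNIR camera (400–988 nm) and a SWIR camera
(950–2500 nm) whose band axes are concatenated into one cube. Three signal
components are planted:

* a treatment effect confined to configurable wavelength *windows* (the water
  absorption features are the natural choice) whose magnitude grows across
  imaging sessions, mimicking progressing stress;
* a per-plant random spectral offset plus smooth low-frequency spatial fields
  per image (one shared across channels, one varying per channel) — the
  plant-identity "fingerprint" and acquisition nuisance that a random
  (non-stratified) train/test split lets a flexible classifier exploit;
* iid pixel noise.

Every image comes with a filled-ellipse plant mask with a ragged edge, so the
downstream tiling step produces both full-coverage and partial-coverage tiles.
Background pixels are zero. Everything is deterministic given the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import MANIFEST_COLUMNS, HyperCube, PlantImage


@dataclass
class SimConfig:
    """Parameters of a synthetic drought-imaging experiment.

    Defaults follow the emulated trial: five weekly imaging sessions, a
    160-band VNIR axis over 400–988 nm concatenated with a 288-band SWIR axis
    over 950–2500 nm, and a treatment effect in the water-absorption windows
    whose magnitude grows linearly over sessions.
    """

    n_plants_per_group: int = 9
    n_sessions: int = 5
    vnir_bands: int = 160
    swir_bands: int = 288
    wavelength_ranges: tuple = ((400.0, 988.0), (950.0, 2500.0))
    effect_windows: tuple = ((940.0, 1000.0), (1420.0, 1520.0), (1870.0, 2000.0))
    effect_magnitude_per_session: tuple = (0.01, 0.02, 0.03, 0.04, 0.05)
    plant_sigma: float = 0.02
    pixel_sigma: float = 0.01
    image_hw: tuple = (256, 256)
    variety: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.plant_sigma < 0 or self.pixel_sigma < 0:
            raise ValueError("noise SDs must be >= 0")
        if len(self.effect_magnitude_per_session) != self.n_sessions:
            raise ValueError(
                f"effect_magnitude_per_session must have length n_sessions="
                f"{self.n_sessions}, got {len(self.effect_magnitude_per_session)}")
        if any(m < 0 for m in self.effect_magnitude_per_session):
            raise ValueError("effect magnitudes must be >= 0")
        (v_lo, v_hi), (s_lo, s_hi) = self.wavelength_ranges
        for a, b in self.effect_windows:
            if not (v_lo <= a <= v_hi or s_lo <= a <= s_hi) or \
               not (v_lo <= b <= v_hi or s_lo <= b <= s_hi):
                raise ValueError(
                    f"effect window ({a}, {b}) lies outside the sensor ranges")

    def wavelengths(self) -> tuple[np.ndarray, int]:
        """Concatenated VNIR+SWIR wavelength axis and the SWIR start index.

        Overlapping wavelengths in the 950–988 nm region are kept as distinct
        channels, matching the concatenation of the two physical sensors.
        """
        (v_lo, v_hi), (s_lo, s_hi) = self.wavelength_ranges
        vnir = np.linspace(v_lo, v_hi, self.vnir_bands)
        swir = np.linspace(s_lo, s_hi, self.swir_bands)
        return np.concatenate([vnir, swir]), self.vnir_bands


# Gaussian bump/notch centres (nm) of the closed-form leaf spectrum: chlorophyll
# absorption keeps blue/red low, the green bump sits near 550 nm, the red edge
# lifts reflectance onto the NIR plateau, and water notches sit near 1450/1900.
_GREEN_PEAK = (550.0, 30.0, 0.06)
_NOTCHES = (  # (centre, width, depth) carved out of the NIR/SWIR plateau
    (970.0, 25.0, 0.06),
    (1200.0, 35.0, 0.08),
    (1450.0, 45.0, 0.55),
    (1940.0, 65.0, 0.75),
    (2500.0, 180.0, 0.55),
)


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def vegetation_spectrum(wavelengths_nm: np.ndarray, plant_offset: float = 0.0,
                        rng: np.random.Generator | None = None,
                        wiggle_sd: float = 0.005) -> np.ndarray:
    """Closed-form vegetation-like reflectance curve.

    Low in blue/red, a small green peak, a plateau around 0.4–0.6 over
    750–1300 nm, and local minima near the 1450 nm and 1900 nm water features.
    ``plant_offset`` shifts the whole curve additively (before the final clip
    to [0, 1]); passing ``rng`` adds a smooth random spectral wiggle of
    roughly ``wiggle_sd`` standard deviation — a per-plant spectral
    "fingerprint" when one rng is drawn per plant.
    """
    wl = np.asarray(wavelengths_nm, dtype=np.float64)
    if wl.size == 0:
        return np.empty(0)
    if not np.all(np.isfinite(wl)):
        raise ValueError("wavelengths must be finite")
    if np.any(wl < 350) or np.any(wl > 2600):
        raise ValueError("wavelengths must lie within 350-2600 nm")

    base = 0.05 + _GREEN_PEAK[2] * _gauss(wl, _GREEN_PEAK[0], _GREEN_PEAK[1])
    # red edge: logistic rise onto the NIR plateau
    plateau = 0.50 / (1.0 + np.exp(-(wl - 715.0) / 18.0))
    for mu, sigma, depth in _NOTCHES:
        plateau = plateau * (1.0 - depth * _gauss(wl, mu, sigma))
    curve = base + plateau
    if rng is not None and wiggle_sd > 0:
        # smooth wiggle: random low-frequency cosines; per-harmonic SD chosen
        # so the curve-level SD is approximately wiggle_sd
        n_harm = 8
        phases = rng.uniform(0, 2 * np.pi, size=n_harm)
        amps = rng.normal(0.0, wiggle_sd / 2.0, size=n_harm)
        for k, (ph, am) in enumerate(zip(phases, amps), start=1):
            curve = curve + am * np.cos(2 * np.pi * k * (wl - 350) / 2250 + ph)
    return np.clip(curve + plant_offset, 0.0, 1.0)


def apply_treatment_effect(spectrum: np.ndarray, wavelengths_nm: np.ndarray,
                           windows, magnitude: float) -> np.ndarray:
    """Perturb a spectrum inside the informative wavelength windows only.

    Water deficit reduces leaf water content, which *raises* reflectance in the
    water-absorption features; the effect is modelled as an additive shift of
    ``+magnitude`` at every channel whose wavelength falls inside a window
    (closed intervals). Channels outside all windows are returned unchanged.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    spectrum = np.asarray(spectrum, dtype=np.float64)
    wl = np.asarray(wavelengths_nm, dtype=np.float64)
    out = spectrum.copy()
    if magnitude == 0:
        return out
    for a, b in windows:
        inside = (wl >= a) & (wl <= b)
        if not inside.any():
            warnings.warn(f"effect window ({a}, {b}) covers no channel; ignored",
                          stacklevel=2)
            continue
        out[inside] += magnitude
    return out


def informative_channels(config: SimConfig) -> np.ndarray:
    """Indices of channels (on the full, untrimmed axis) inside any effect window."""
    wl, _ = config.wavelengths()
    inside = np.zeros(wl.size, dtype=bool)
    for a, b in config.effect_windows:
        inside |= (wl >= a) & (wl <= b)
    return np.flatnonzero(inside)


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  coarse: int = 6) -> np.ndarray:
    """Zero-mean spatially smooth field with unit-ish SD (low-frequency)."""
    grid = rng.normal(size=(coarse, coarse))
    zoom = (shape[0] / coarse, shape[1] / coarse)
    f = ndimage.zoom(grid, zoom, order=3)[: shape[0], : shape[1]]
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _ragged_ellipse_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Filled ellipse with a ragged (angularly perturbed) boundary."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.46 * h, 0.44 * w
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.arctan2(yy - cy, xx - cx)
    # ragged edge: radius modulated by a few random harmonics (up to ~8%)
    mod = np.ones_like(theta)
    for k in (3, 5, 7):
        mod += rng.uniform(-0.04, 0.04) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    r2 = ((yy - cy) / (ry * mod)) ** 2 + ((xx - cx) / (rx * mod)) ** 2
    return r2 <= 1.0


def generate_experiment(config: SimConfig) -> tuple[list[PlantImage], pd.DataFrame]:
    """Simulate the full experiment: plants × sessions × treatments.

    Each plant keeps a fixed identifier and a fixed random spectral offset
    across all sessions; drought plants additionally carry the window-localized
    treatment effect with the session-indexed magnitude. Returns the images
    plus an image-level manifest (one row per plant image; the ``path`` column
    is empty until images are written to disk).
    """
    images = []
    rows = []
    for img, meta in iter_experiment(config):
        images.append(img)
        rows.append(meta)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return images, manifest


def iter_experiment(config: SimConfig):
    """Yield ``(PlantImage, manifest_row)`` one at a time (memory-friendly)."""
    wl, boundary = config.wavelengths()
    root = np.random.SeedSequence(config.seed)
    plant_seeds = root.spawn(2 * config.n_plants_per_group)
    plants = []
    for g, treatment in enumerate(("C", "D")):
        for i in range(config.n_plants_per_group):
            ss = plant_seeds[g * config.n_plants_per_group + i]
            rng = np.random.default_rng(ss)
            offset = rng.normal(0.0, config.plant_sigma)
            identifier = f"{config.variety}-{treatment}-{i + 1:02d}"
            plants.append((identifier, treatment, offset, ss))

    for identifier, treatment, offset, ss in plants:
        session_seeds = ss.spawn(config.n_sessions + 1)
        # the smooth spectral wiggle is part of the per-plant nuisance, so it is
        # present only when plant_sigma > 0 (zero nuisance => identical plants)
        spec_rng = (np.random.default_rng(session_seeds[0])
                    if config.plant_sigma > 0 else None)
        base = vegetation_spectrum(wl, plant_offset=offset, rng=spec_rng,
                                   wiggle_sd=0.5 * config.plant_sigma)
        for s in range(1, config.n_sessions + 1):
            rng = np.random.default_rng(session_seeds[s])
            spectrum = base
            if treatment == "D":
                spectrum = apply_treatment_effect(
                    base, wl, config.effect_windows,
                    config.effect_magnitude_per_session[s - 1])
            cube = np.broadcast_to(
                spectrum[:, None, None].astype(np.float32),
                (wl.size, *config.image_hw)).copy()
            if config.plant_sigma > 0:
                # plant/image brightness nuisance: a smooth low-frequency
                # field shared across channels
                field = _smooth_field(config.image_hw, rng)
                cube += (config.plant_sigma * field)[None, :, :].astype(np.float32)
            if config.pixel_sigma > 0:
                # acquisition noise: iid pixel noise plus its spatially smooth,
                # spectrally varying component (illumination/canopy structure)
                # that spatial pooling cannot average away
                coarse = rng.normal(size=(wl.size, 4, 4))
                per_chan = ndimage.zoom(
                    coarse, (1, config.image_hw[0] / 4, config.image_hw[1] / 4),
                    order=1)[:, :config.image_hw[0], :config.image_hw[1]]
                cube += (config.pixel_sigma * per_chan).astype(np.float32)
                cube += rng.normal(0.0, config.pixel_sigma,
                                   size=cube.shape).astype(np.float32)
            np.clip(cube, 0.0, 1.0, out=cube)
            mask = _ragged_ellipse_mask(config.image_hw, rng)
            cube[:, ~mask] = 0.0
            img = PlantImage(
                cube=HyperCube(cube, wl, boundary), mask=mask,
                imaging=s, identifier=identifier, treatment=treatment,
                variety=config.variety)
            row = {"sample_id": f"{identifier}_s{s}", "imaging": s,
                   "identifier": identifier, "treatment": treatment,
                   "variety": config.variety, "path": ""}
            yield img, row
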