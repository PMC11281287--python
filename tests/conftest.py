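import numpy as np
import pandas as pd
import pytest

from specband.containers import MANIFEST_COLUMNS, HyperCube
from specband.pipeline import simulate_tiled_samples
from specband.simulate import SimConfig


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small but full-structure experiment: 2 plants/group, 2 sessions,
    8 channels after trimming, 4 tiles per image."""
    return SimConfig(
        n_plants_per_group=2, n_sessions=2, vnir_bands=14, swir_bands=14,
        effect_windows=((1500.0, 1900.0),),
        effect_magnitude_per_session=(0.05, 0.10),
        plant_sigma=0.02, pixel_sigma=0.01, image_hw=(256, 256), seed=11)


@pytest.fixture(scope="session")
def tiny_samples(tiny_config):
    samples, manifest = simulate_tiled_samples(tiny_config)
    return samples, manifest


def make_manifest(cells: dict) -> pd.DataFrame:
    """Build a manifest from {(session, treatment): n_samples}; each sample
    gets its own plant unless ``plants_per_cell`` dictates otherwise."""
    rows = []
    for (session, treatment), n in cells.items():
        for i in range(n):
            ident = f"P-{treatment}-{i % max(n // 4, 1):03d}"
            rows.append({"sample_id": f"s{session}{treatment}{i:04d}",
                         "imaging": session, "identifier": ident,
                         "treatment": treatment, "variety": "SYN", "path": ""})
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def make_plant_manifest(n_plants_per_group: int, tiles_per_plant,
                        n_sessions: int = 2) -> pd.DataFrame:
    """Manifest with whole plants: tiles_per_plant may be int or a callable
    of the plant index (to vary per-plant sample counts)."""
    rows = []
    for treatment in ("C", "D"):
        for p in range(n_plants_per_group):
            ident = f"P-{treatment}-{p:02d}"
            k = tiles_per_plant(p) if callable(tiles_per_plant) else tiles_per_plant
            for s in range(1, n_sessions + 1):
                for t in range(k):
                    rows.append({"sample_id": f"{ident}_s{s}_t{t}",
                                 "imaging": s, "identifier": ident,
                                 "treatment": treatment, "variety": "SYN",
                                 "path": ""})
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def toy_cube(c=6, h=4, w=4, boundary=3, seed=0) -> HyperCube:
    rng = np.random.default_rng(seed)
    wl = np.concatenate([np.linspace(400, 900, boundary),
                         np.linspace(950, 2500, c - boundary)])
    return HyperCube(rng.uniform(0.05, 0.9, size=(c, h, w)).astype(np.float32),
                     wl, boundary)
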