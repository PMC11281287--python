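"""End-to-end glue: simulate an experiment, preprocess every plant image into
tiles, and carry a tile-level manifest alongside the in-memory samples."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MANIFEST_COLUMNS, Sample
from .preprocess import TileSpec, preprocess_plant_image
from .sampling import Split
from .simulate import SimConfig, iter_experiment


def simulate_tiled_samples(config: SimConfig, spec: TileSpec | None = None
                           ) -> tuple[list[Sample], pd.DataFrame]:
    """Generate the experiment and run the preprocessing pipeline image by
    image (memory-friendly). Returns all kept tiles plus a tile manifest."""
    spec = spec or TileSpec()
    samples: list[Sample] = []
    rows = []
    for img, _ in iter_experiment(config):
        for tile in preprocess_plant_image(img, spec):
            samples.append(tile)
            rows.append({"sample_id": tile.sample_id, "imaging": tile.imaging,
                         "identifier": tile.identifier, "treatment": tile.treatment,
                         "variety": tile.variety, "path": ""})
    return samples, pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def select_samples(samples: list[Sample], sample_ids) -> list[Sample]:
    """Subset a sample list by id, preserving the order of ``sample_ids``."""
    by_id = {s.sample_id: s for s in samples}
    return [by_id[sid] for sid in sample_ids]


def split_samples(samples: list[Sample], split: Split) -> dict:
    """Materialise a Split into the three sample lists."""
    return {"train": select_samples(samples, split.train),
            "test": select_samples(samples, split.test),
            "validation": select_samples(samples, split.validation)}


def informative_trimmed_channels(samples: list[Sample], windows) -> np.ndarray:
    """Indices (on the trimmed channel axis) whose wavelength falls inside any
    effect window — the planted ground truth for band-recovery checks."""
    wl = samples[0].wavelengths_nm
    if wl is None:
        raise ValueError("samples carry no wavelength axis")
    inside = np.zeros(len(wl), dtype=bool)
    for a, b in windows:
        inside |= (wl >= a) & (wl <= b)
    return np.flatnonzero(inside)
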