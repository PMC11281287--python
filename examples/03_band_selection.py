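"""Rank spectral bands by attention significance and check the ranking
against the planted ground truth.

The significance of channel c is the training-set mean of the sigmoid-squashed
average-pool attention branch, r_c; channels inside the planted effect windows
should rise in the ranking as training progresses.
"""

import numpy as np

from specband import TrainConfig, WaterDeficitClassifier, fit
from specband.band_selection import band_significance, select_top_b
from specband.experiments import recovery_config
from specband.model import TINY_WIDTHS
from specband.pipeline import (informative_trimmed_channels,
                               simulate_tiled_samples, split_samples)
from specband.sampling import build_dataset

config = recovery_config(seed=0)
samples, manifest = simulate_tiled_samples(config)
_, split = build_dataset(manifest, "UD-SS", seed=0)
sets = split_samples(samples, split)
truth = informative_trimmed_channels(samples, config.effect_windows)
print(f"{samples[0].data.shape[0]} channels, "
      f"{truth.size} planted informative: {truth}")

model = WaterDeficitClassifier(samples[0].data.shape[0],
                               widths=TINY_WIDTHS, seed=1)
cfg = TrainConfig(max_epochs=15, patience=15, lr_step=15, seed=0)
# keep the final-epoch weights: the ranking accumulates over the whole run
model, _ = fit(model, sets["train"], sets["validation"], cfg,
               restore_best=False)

sig = band_significance(model, sets["train"])
top = select_top_b(sig, 10)
overlap = np.intersect1d(top, truth)
wl = sig.wavelengths_nm
print(f"top-10 channels by significance: {top}")
print(f"their wavelengths (nm): {np.round(wl[top]).astype(int)}")
print(f"{overlap.size} of 10 fall inside the planted effect windows "
      f"(chance expectation {10 * truth.size / sig.r.size:.1f})")
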