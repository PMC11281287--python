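"""Attention-derived spectral band significance, top-b selection, and
retraining on the reduced spectrum.

The significance of channel c is the mean over training samples of the
sigmoid-processed average-pool attention branch, r_c = (1/N) Σ_k s^avg_{c,k},
computed in inference mode (centre crop, no flips). Only the average branch
enters the score — the forward pass uses both branches, but the ranking
formula deliberately does not. Bands with larger r_c are considered more
informative; the top-b set can then back a smaller model whose attention
bottleneck shrinks to ⌊b/2⌋.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import Sample
from .model import WaterDeficitClassifier, attention_forward
from .training import TrainConfig, augment, fit


@dataclass
class BandSignificance:
    """Per-channel relevance in (0,1) plus the descending-relevance ranking
    (ties broken toward the lower channel index)."""

    r: np.ndarray
    n_samples_used: int
    ranking: np.ndarray
    wavelengths_nm: np.ndarray | None = None


def band_significance(model: WaterDeficitClassifier, train_samples,
                      crop_to: int = 50) -> BandSignificance:
    """Average the s_avg attention branch over the training set."""
    if not len(train_samples):
        raise ValueError("band significance needs at least one training sample")
    params = model.attention.export_params()
    acc = np.zeros(model.n_channels, dtype=np.float64)
    wavelengths = None
    for s in train_samples:
        arr = s.data if isinstance(s, Sample) else np.asarray(s)
        if isinstance(s, Sample) and s.wavelengths_nm is not None:
            wavelengths = np.asarray(s.wavelengths_nm)
        h = augment(arr, "eval", crop_to=crop_to)
        acc += attention_forward(h, params).s_avg
    r = acc / len(train_samples)
    # stable sort on -r => ties resolve to the lower channel index
    ranking = np.argsort(-r, kind="stable")
    return BandSignificance(r=r, n_samples_used=len(train_samples),
                            ranking=ranking, wavelengths_nm=wavelengths)


def select_top_b(sig: BandSignificance, b: int) -> np.ndarray:
    """The b most significant channel indices, sorted ascending."""
    c = sig.r.shape[0]
    if not 1 <= b <= c:
        raise ValueError(f"b must be in [1, {c}], got {b}")
    return np.sort(sig.ranking[:b])


def subset_channels(samples, bands: np.ndarray) -> list:
    """Restrict every sample to the given channel indices."""
    bands = np.asarray(bands)
    out = []
    for s in samples:
        wl = None if s.wavelengths_nm is None else s.wavelengths_nm[bands]
        out.append(replace(s, data=s.data[bands], wavelengths_nm=wl))
    return out


def reduce_and_retrain(train_set, val_set, test_set, bands,
                       train_cfg: TrainConfig | None = None,
                       widths=(8, 16, 32, 64), model_seed: int = 0,
                       n_resamples: int = 1000):
    """Retrain and evaluate on the selected band subset.

    Returns ``(model, report)`` where the model's channel count is ``len(bands)``
    (attention bottleneck ⌊b/2⌋) and the report is the usual metrics report on
    the reduced test set; the pooled AUC is the point for a bands-vs-AUC sweep.
    """
    from .evaluation import evaluate

    bands = np.asarray(bands)
    if bands.size < 2:
        raise ValueError("need at least 2 bands (attention bottleneck degenerates)")
    n_channels = train_set[0].data.shape[0]
    if bands.min() < 0 or bands.max() >= n_channels:
        raise ValueError(f"band indices outside [0, {n_channels})")
    reduced = [subset_channels(s, bands) for s in (train_set, val_set, test_set)]
    model = WaterDeficitClassifier(bands.size, widths=widths, seed=model_seed)
    model, _ = fit(model, reduced[0], reduced[1], train_cfg)
    report = evaluate(model, reduced[2], n_resamples=n_resamples,
                      seed=(train_cfg.seed if train_cfg else 0))
    return model, report
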