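"""Train the band-attention classifier on a separable synthetic dataset and
evaluate it with bootstrap confidence intervals and per-plant majority votes.

Uses the leakage-free plant-stratified dataset schema (UD-SS): per-session
class counts equalized, and no plant contributes tiles to both train and
test.
"""

from specband import TrainConfig, WaterDeficitClassifier, evaluate, fit
from specband.experiments import separable_config
from specband.model import TINY_WIDTHS
from specband.pipeline import simulate_tiled_samples, split_samples
from specband.sampling import build_dataset

samples, manifest = simulate_tiled_samples(separable_config(seed=0))
_, split = build_dataset(manifest, "UD-SS", seed=0)
sets = split_samples(samples, split)
print(f"{len(sets['train'])} train / {len(sets['test'])} test / "
      f"{len(sets['validation'])} validation tiles")

model = WaterDeficitClassifier(samples[0].data.shape[0],
                               widths=TINY_WIDTHS, seed=1)
cfg = TrainConfig(max_epochs=10, patience=10, lr_step=10, seed=0)
model, history = fit(model, sets["train"], sets["validation"], cfg)
print(f"trained {len(history)} epochs; best validation loss "
      f"{min(history.val_loss):.3f} at epoch {history.best_epoch}")

report = evaluate(model, sets["test"], seed=0)
pooled = report.pooled
print(f"pooled test AUC-ROC {pooled.auc_roc:.2f} "
      f"(95% CI {pooled.auc_ci[0]:.2f}-{pooled.auc_ci[1]:.2f}), "
      f"F1 {pooled.f1:.2f}")
# per-plant majority vote aggregates tile predictions to whole plants
print(f"plant-level: AUC {report.plant_auc:.2f}, "
      f"sensitivity {report.plant_sensitivity:.2f}, "
      f"specificity {report.plant_specificity:.2f} "
      f"over {len(report.plant_votes)} plants")
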