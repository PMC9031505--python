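"""Train the indirect (2D slice-wise) path on a compact phantom cohort.

Builds 40 compact phantoms (64x64, 12 slices), splits them per patient
8:1:1, trains the three-channel 2D encoder-decoder on Dice loss, and
reports segmentation and volume metrics on the held-out test patients.
Runs in a couple of minutes on one CPU; the acceptance script additionally
trains the direct (patch-based 3D) path on the same cohort for comparison.
"""

import strokevol as sv
from strokevol.seg import TrainConfig
from strokevol.unet import UNetConfig

cohort = sv.make_cohort(40, sv.CohortRanges.compact(), seed=11)

model, history, (train_idx, val_idx, test_idx) = sv.train(
    UNetConfig(dimensionality=2, depth=3, base_channels=8, input_channels=3, seed=0),
    TrainConfig(epochs=15, batch_size=8, learning_rate=1e-3, seed=0),
    cohort,
)
print(f"split sizes (train/val/test): {len(train_idx)}/{len(val_idx)}/{len(test_idx)}")
print(f"validation Dice loss: {history.val_loss[0]:.3f} (init) -> "
      f"{min(history.val_loss[1:]):.3f} (best, epoch {history.best_epoch})")

preds, labels, studies = [], [], []
for i in test_idx:
    study, label = cohort[i]
    preds.append(sv.predict_indirect(model, study, threshold=0.5))
    labels.append(label)
    studies.append(study)
report = sv.evaluate_cohort(preds, labels, studies)
for key, value in report.as_percent_dict().items():
    print(f"  {key}: {value}")
# Jaccard/F1 measure per-pixel overlap with the ground-truth lesion; VS and
# MAE measure how well the predicted lesion VOLUME matches the truth.
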