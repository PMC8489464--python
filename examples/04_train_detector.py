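"""Train a small landmark detector on short-axis phantoms (CPU, ~1 minute).

This is a miniature of the reference study (fewer samples, a shallower
net, fewer epochs) to show the training API end to end.  For the full
reference run — 180 phantoms at 96x96, the 4-level base-8 U-Net, 16
epochs — use ``cardiomark.reference.run_reference_training(seed)``, which
reaches a ~100% detection rate with sub-pixel mean error.
"""

import numpy as np

import cardiomark as cm
from cardiomark.heatmap import DecodeConfig
from cardiomark.measure import detection_rate, mean_landmark_error
from cardiomark.train import evaluate_on_samples

cfg = cm.PhantomConfig(view="SAX").scaled_to((48, 48))
pool = cm.generate_dataset(cfg, 60, rng=np.random.default_rng(0))
train, val = cm.split_by_patient(pool, val_fraction=0.10, seed=0)
test = cm.generate_dataset(cfg, 30, rng=np.random.default_rng(1))

model = cm.UNet(
    cm.ModelConfig(n_levels=3, blocks_per_level=2, base_channels=8,
                   out_channels=4, input_size=(48, 48)),
    rng=0,
)
best, history = cm.fit(model, train, val,
                       cm.TrainConfig(n_epochs=8, batch_size=4, seed=0, sigma=4.0))
print(f"validation loss: first {history.val_loss[0]:.3f} -> "
      f"best {min(history.val_loss):.3f} (epoch {history.best_epoch})")

results = evaluate_on_samples(best, test, DecodeConfig(sigma=4.0))
report = detection_rate(results, spacing=cfg.pixel_spacing)
print(f"held-out detection rate: {report.detection_rate:.1f}% "
      f"({report.n_all_detected} of {report.n_images} images), "
      f"false positives: {report.false_positives}")
print(f"mean landmark error: {mean_landmark_error(results):.2f} mm")
print(report.per_landmark.to_string(index=False))
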