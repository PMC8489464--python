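"""The package's reference desk-scale experiment.

One place defines the phantom, model and training configuration used by the
worked examples and the verification scripts, so every entry point runs the
same study: short-axis phantoms on a 96x96 grid at 1 mm, a 4-level base-8
U-Net (2 blocks per level), 16 epochs of Adam at the default recipe with
minibatches of 4, heatmap sigma 4 px, evaluated on an independently seeded
held-out set of phantoms.  The 96 px frame keeps landmark separations well
above the largest heatmap kernel (sigma 6 px), which smaller frames do not.

These sizes are the package's CPU-friendly reference configuration; every
piece (phantom frame, network depth/width, dataset size) is configurable up
to the full 400x400 clinical-scale setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heatmap import DecodeConfig
from .measure import EvalReport, detection_rate, mean_landmark_error
from .nn import ModelConfig, UNet
from .phantom import PhantomConfig, PhantomSample, generate_dataset, invert_contrast
from .train import TrainConfig, TrainHistory, evaluate_on_samples, fine_tune, fit, split_by_patient

REFERENCE_IMAGE_SIZE = (96, 96)
REFERENCE_N_TRAIN = 180  # split 90/10 patient-wise into train/validation
REFERENCE_N_TEST = 100
REFERENCE_EPOCHS = 16
REFERENCE_BATCH_SIZE = 4


def reference_phantom_config(view: str = "SAX", **overrides) -> PhantomConfig:
    """The default phantom anatomy proportionally scaled to the 64x64 frame."""
    cfg = PhantomConfig(view=view, **overrides)
    return cfg.scaled_to(REFERENCE_IMAGE_SIZE)


def reference_model_config() -> ModelConfig:
    return ModelConfig(
        n_levels=4,
        blocks_per_level=2,
        base_channels=8,
        in_channels=1,
        out_channels=4,
        input_size=REFERENCE_IMAGE_SIZE,
    )


def reference_train_config(seed: int, sigma: float = 4.0, n_epochs: int = REFERENCE_EPOCHS) -> TrainConfig:
    return TrainConfig(n_epochs=n_epochs, batch_size=REFERENCE_BATCH_SIZE, seed=seed, sigma=sigma)


@dataclass
class ReferenceRun:
    """Everything produced by one reference training + evaluation."""

    model: UNet
    history: TrainHistory
    report: EvalReport
    mean_error_px: float
    sigma: float
    seed: int
    train_samples: list[PhantomSample] = field(default_factory=list)
    val_samples: list[PhantomSample] = field(default_factory=list)
    test_samples: list[PhantomSample] = field(default_factory=list)

    @property
    def detection_rate(self) -> float:
        return self.report.detection_rate


def reference_datasets(
    seed: int, view: str = "SAX", n_train: int = REFERENCE_N_TRAIN, n_test: int = REFERENCE_N_TEST
) -> tuple[list[PhantomSample], list[PhantomSample], list[PhantomSample]]:
    """(train, validation, held-out test) phantom sets, patient-disjoint."""
    cfg = reference_phantom_config(view)
    pool = generate_dataset(cfg, n_train, rng=np.random.default_rng(seed))
    train, val = split_by_patient(pool, val_fraction=0.10, seed=seed)
    test = generate_dataset(cfg, n_test, rng=np.random.default_rng(seed + 500_009))
    return train, val, test


def run_reference_training(
    seed: int,
    sigma: float = 4.0,
    n_epochs: int = REFERENCE_EPOCHS,
    view: str = "SAX",
    n_train: int = REFERENCE_N_TRAIN,
    n_test: int = REFERENCE_N_TEST,
) -> ReferenceRun:
    """Train the reference detector and evaluate it on held-out phantoms."""
    train_s, val_s, test_s = reference_datasets(seed, view, n_train, n_test)
    model = UNet(reference_model_config(), rng=seed)
    best, history = fit(model, train_s, val_s, reference_train_config(seed, sigma, n_epochs))
    results = evaluate_on_samples(best, test_s, DecodeConfig(sigma=sigma))
    spacing = test_s[0].image.spacing
    report = detection_rate(results, spacing)
    err = mean_landmark_error(results, spacing) / spacing  # px on the 1 mm grid
    return ReferenceRun(best, history, report, err, sigma, seed, train_s, val_s, test_s)


def run_transfer_comparison(
    pretrained: UNet, seed: int, n_samples: int = 90
) -> tuple[TrainHistory, TrainHistory]:
    """Fine-tune vs scratch on contrast-inverted phantoms, same data and seed.

    Returns ``(fine_tune_history, scratch_history)``; both runs get the same
    10-epoch budget, fine-tuning at the reduced transfer learning rate.
    """
    cfg = reference_phantom_config("SAX")
    inverted = [
        invert_contrast(s)
        for s in generate_dataset(cfg, n_samples, rng=np.random.default_rng(seed + 77_003))
    ]
    tr, vl = split_by_patient(inverted, 0.10, seed=seed)
    tconfig = reference_train_config(seed, sigma=4.0, n_epochs=10)
    _, ft_hist = fine_tune(pretrained, tr, vl, tconfig)
    scratch = UNet(reference_model_config(), rng=seed + 1)
    _, sc_hist = fit(scratch, tr, vl, tconfig)
    return ft_hist, sc_hist
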