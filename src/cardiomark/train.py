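"""Training: patient-wise splits, multitask batches, Adam + plateau schedule.

The optimization recipe: Adam (lr 0.001, betas 0.9/0.999, eps 1e-8), with
the learning rate divided by 2 whenever the validation loss plateaus, and
the returned model is the checkpoint with the lowest validation loss.
Long-axis training is multitask: the two-, three- and four-chamber views
share one model and minibatches mix views at the pooled proportions (no
rebalancing).  Transfer learning reuses the same loop from pretrained
weights at a reduced learning rate (0.0005) for 10 epochs, all layers
trainable.

Every source of randomness (split, batch order, augmentation, weight init)
derives from one master seed, so a run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .core import ConfigurationError, DetectionResult, Image2D, LandmarkSet
from .heatmap import DecodeConfig, decode, encode
from .losses import combined_loss, loss_grad_scores, softmax_probs
from .nn import Adam, UNet
from .phantom import PhantomSample
from .preprocess import PreprocessConfig, augment, normalize_intensity


@dataclass
class TrainConfig:
    """Optimization hyperparameters; defaults follow the reference recipe."""

    lr: float = 0.001
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    plateau_factor: float = 2.0
    plateau_patience: int = 5
    plateau_rel_threshold: float = 1e-3
    n_epochs: int = 50
    batch_size: int = 8
    val_fraction: float = 0.10
    seed: int = 0
    fine_tune_lr: float = 0.0005
    fine_tune_epochs: int = 10
    sigma: float = 4.0
    augment: bool = False

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.fine_tune_lr <= 0:
            raise ConfigurationError("learning rates must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigurationError("val_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.plateau_factor <= 1.0:
            raise ConfigurationError("plateau_factor must be > 1")


@dataclass
class TrainHistory:
    """Per-epoch training/validation loss and learning rate."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        if not self.val_loss:
            raise ValueError("history is empty")
        return int(np.argmin(self.val_loss))


def _patient_of(sample) -> str:
    if isinstance(sample, PhantomSample):
        return str(sample.image.meta.get("patient_id", sample.image.meta.get("sample_id")))
    if isinstance(sample, tuple):
        return str(sample[-1])
    meta = getattr(sample, "meta", {})
    return str(meta.get("patient_id"))


def split_by_patient(
    samples: Sequence, val_fraction: float = 0.10, seed: int = 0,
    patient_ids: Sequence[str] | None = None,
) -> tuple[list, list]:
    """Partition samples into train/validation with no patient in both sets.

    The number of validation patients is ``round(val_fraction * n_patients)``
    (kept within [1, n - 1]); the partition is deterministic given the seed.
    """
    if patient_ids is None:
        patient_ids = [_patient_of(s) for s in samples]
    if len(patient_ids) != len(samples):
        raise ValueError("one patient id per sample required")
    patients = sorted(set(patient_ids))
    if len(patients) < 2:
        raise ValueError("need at least 2 patients for a patient-wise split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_val = int(round(val_fraction * len(patients)))
    n_val = min(max(n_val, 1), len(patients) - 1)
    val_patients = {patients[i] for i in order[:n_val]}
    train, val = [], []
    for s, pid in zip(samples, patient_ids):
        (val if pid in val_patients else train).append(s)
    return train, val


def multitask_batches(
    view_datasets: dict[str, Sequence],
    batch_size: int,
    rng: np.random.Generator,
) -> Iterator[list]:
    """One epoch of minibatches over the pooled per-view datasets.

    Samples from all views are pooled and visited exactly once in random
    order, so views mix within batches at their pooled proportions.
    """
    if batch_size < 1:
        raise ConfigurationError("batch_size must be >= 1")
    pool = [s for ds in view_datasets.values() for s in ds]
    if not pool:
        raise ValueError("at least one non-empty view dataset required")
    order = rng.permutation(len(pool))
    for start in range(0, len(pool), batch_size):
        yield [pool[i] for i in order[start : start + batch_size]]


# ---------------------------------------------------------------------------
# sample -> tensor plumbing


def sample_to_tensors(
    sample: PhantomSample, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized input (1,H,W) and target heatmap (C,H,W) for one sample."""
    x = normalize_intensity(sample.image.pixels)[None]
    hm = encode(sample.landmarks, sample.image.shape, sigma)
    return x.astype(np.float32), hm.probs.transpose(2, 0, 1).astype(np.float32)


def _batch_tensors(
    batch: Sequence[PhantomSample],
    sigma: float,
    aug_cfg: PreprocessConfig | None,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ts = [], []
    for s in batch:
        if aug_cfg is not None and rng is not None:
            img, lms = augment(s.image, s.landmarks, aug_cfg, rng)
            s = PhantomSample(img, lms, s.view)
        x, t = sample_to_tensors(s, sigma)
        xs.append(x)
        ts.append(t)
    return np.stack(xs), np.stack(ts)


def _epoch_eval(model: UNet, X: np.ndarray, T: np.ndarray, batch_size: int) -> float:
    total, n = 0.0, 0
    for start in range(0, len(X), batch_size):
        xb, tb = X[start : start + batch_size], T[start : start + batch_size]
        scores = model.forward(xb)
        total += combined_loss(tb, softmax_probs(scores)).total * len(xb)
        n += len(xb)
    return total / n


def fit(
    model: UNet,
    train_samples: Sequence[PhantomSample],
    val_samples: Sequence[PhantomSample],
    config: TrainConfig,
    aug_cfg: PreprocessConfig | None = None,
) -> tuple[UNet, TrainHistory]:
    """Train with Adam and a divide-on-plateau LR schedule.

    Returns the checkpoint with the minimum validation loss and the full
    per-epoch history.  Reproducible given ``config.seed``.
    """
    if not train_samples:
        raise ValueError("training set is empty")
    if not val_samples:
        raise ValueError("validation set is empty")
    rng = np.random.default_rng(config.seed + 1)
    if config.augment and aug_cfg is None:
        aug_cfg = PreprocessConfig(target_size=train_samples[0].image.shape)
    use_aug = config.augment

    Xval, Tval = _batch_tensors(val_samples, config.sigma, None, None)
    if not use_aug:
        Xtr, Ttr = _batch_tensors(train_samples, config.sigma, None, None)

    optimizer = Adam(model.params(), lr=config.lr, betas=config.betas, eps=config.eps)
    history = TrainHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    stall = 0
    n_train = len(train_samples)
    for epoch in range(config.n_epochs):
        order = rng.permutation(n_train)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            if use_aug:
                xb, tb = _batch_tensors([train_samples[i] for i in idx], config.sigma, aug_cfg, rng)
            else:
                xb, tb = Xtr[idx], Ttr[idx]
            scores = model.forward(xb)
            loss = combined_loss(tb, softmax_probs(scores))
            model.zero_grad()
            model.backward(loss_grad_scores(tb, scores))
            optimizer.step()
            epoch_loss += loss.total * len(idx)
            seen += len(idx)
        val_loss = _epoch_eval(model, Xval, Tval, config.batch_size)
        history.train_loss.append(epoch_loss / seen)
        history.val_loss.append(val_loss)
        history.lr.append(optimizer.lr)
        if val_loss < best_val * (1.0 - config.plateau_rel_threshold):
            stall = 0
        else:
            stall += 1
            if stall >= config.plateau_patience:
                optimizer.lr /= config.plateau_factor
                stall = 0
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
    best_model = UNet(model.config, rng=0)
    best_model.set_weights(best_weights)
    return best_model, history


def fine_tune(
    pretrained: UNet,
    train_samples: Sequence[PhantomSample],
    val_samples: Sequence[PhantomSample],
    config: TrainConfig,
    aug_cfg: PreprocessConfig | None = None,
) -> tuple[UNet, TrainHistory]:
    """Transfer learning: continue from pretrained weights at reduced LR.

    All layers remain trainable; only the learning rate (``fine_tune_lr``)
    and epoch budget (``fine_tune_epochs``) differ from scratch training.
    Zero fine-tune epochs returns the pretrained model unchanged.
    """
    if train_samples:
        h, w = train_samples[0].image.shape
        if (h, w) != tuple(pretrained.config.input_size):
            raise ValueError(
                f"architecture mismatch: model expects {pretrained.config.input_size}, data is {(h, w)}"
            )
    if config.fine_tune_epochs == 0:
        return pretrained.clone(), TrainHistory()
    ft_config = replace(config, lr=config.fine_tune_lr, n_epochs=config.fine_tune_epochs)
    model = pretrained.clone()
    return fit(model, train_samples, val_samples, ft_config, aug_cfg)


# ---------------------------------------------------------------------------
# inference


def predict_probs(model: UNet, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Softmax probability stacks (N, C, H, W) for a batch of inputs."""
    out = []
    for start in range(0, len(images), batch_size):
        scores = model.forward(images[start : start + batch_size])
        out.append(softmax_probs(scores))
    return np.concatenate(out, axis=0)


def detect_sample(
    model: UNet,
    image: Image2D,
    view: str,
    decode_config: DecodeConfig | None = None,
) -> DetectionResult:
    """Run the detector on one already-gridded image and decode landmarks."""
    x = normalize_intensity(image.pixels)[None, None].astype(np.float32)
    probs = predict_probs(model, x)[0].transpose(1, 2, 0)
    return decode(probs, view, decode_config)


def evaluate_on_samples(
    model: UNet,
    samples: Sequence[PhantomSample],
    decode_config: DecodeConfig | None = None,
) -> list[tuple[DetectionResult, LandmarkSet]]:
    """Detections paired with ground truth for a list of phantom samples."""
    return [
        (detect_sample(model, s.image, s.view, decode_config), s.landmarks)
        for s in samples
    ]
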