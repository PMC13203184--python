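"""Pluggable frame classifiers emitting class-probability vectors.

Two trainable models share one interface: a classical HOG + SVM baseline
(gradient-orientation descriptor on grayscale frames, RBF support vector
machine with Platt-calibrated probabilities) and a small from-scratch CNN
(see :mod:`echorobust.nnet`) trained with the AdamW / label-smoothing /
weighted-sampling recipe.  A frozen-features + logistic-regression path is
provided for externally supplied embeddings.

Every trained model records its class order, preprocessing signature and
training seed, and its ``predict_proba`` rows are finite, non-negative and
sum to one.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd
from skimage import transform as sktransform
from skimage.feature import hog

from echorobust.data import preprocess
from echorobust.metrics import make_table
from echorobust.nnet import SmallCnn, fit_small_cnn
from echorobust.phantom import Frame


@dataclass
class HOGConfig:
    resize: int = 128
    orientations: int = 9
    pixels_per_cell: tuple[int, int] = (16, 16)
    cells_per_block: tuple[int, int] = (2, 2)
    kernel: str = "rbf"
    C: float = 10.0
    gamma: str | float = "scale"
    class_weight: str | None = "balanced"


@dataclass
class TrainConfig:
    """Training recipe of the small CNN (the study's fixed configuration)."""

    lr_backbone: float = 1e-4
    lr_head: float = 5e-4
    weight_decay: float = 1e-4
    dropout: float = 0.3
    label_smoothing: float = 0.05
    batch_size: int = 32
    max_epochs: int = 30
    early_stopping_patience: int = 5
    input_size: int = 64
    channels: tuple[int, int, int] = (8, 16, 32)

    def validate(self) -> None:
        if min(self.lr_backbone, self.lr_head) <= 0:
            raise ValueError("learning rates must be > 0")
        if self.early_stopping_patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


class TrainedClassifier:
    """Fitted model + class order + preprocessing signature + seed."""

    def __init__(self, classes: list[str], preprocessing: str, seed: int,
                 metadata: dict | None = None):
        self.classes = list(classes)
        self.preprocessing = preprocessing
        self.seed = seed
        self.metadata = metadata or {}

    def featurize(self, frames: TypingSequence[Frame]) -> np.ndarray:
        raise NotImplementedError

    def predict_proba(self, frames: TypingSequence[Frame]) -> np.ndarray:
        raise NotImplementedError


class HogSvmClassifier(TrainedClassifier):
    def __init__(self, svm, config: HOGConfig, classes, seed):
        super().__init__(
            classes,
            preprocessing=f"gray-resize{config.resize}-hog",
            seed=seed,
            metadata={"config": asdict(config)},
        )
        self.svm = svm
        self.config = config

    def featurize(self, frames):
        cfg = self.config
        feats = []
        for fr in frames:
            img = np.asarray(fr.pixels, dtype=np.float64)
            if img.shape != (cfg.resize, cfg.resize):
                img = sktransform.resize(
                    img, (cfg.resize, cfg.resize), order=1, mode="edge",
                    anti_aliasing=True,
                )
            feats.append(
                hog(
                    img,
                    orientations=cfg.orientations,
                    pixels_per_cell=cfg.pixels_per_cell,
                    cells_per_block=cfg.cells_per_block,
                    block_norm="L2-Hys",
                    feature_vector=True,
                )
            )
        return np.asarray(feats)

    def predict_proba(self, frames):
        proba = self.svm.predict_proba(self.featurize(frames))
        # svm classes_ are indices into self.classes by construction
        return proba


def train_hog_svm(
    frames: TypingSequence[Frame],
    labels: TypingSequence[str],
    config: HOGConfig | None = None,
    seed: int = 0,
) -> HogSvmClassifier:
    """Grayscale -> resize -> HOG -> RBF SVM with Platt-calibrated
    probabilities (sigmoid fit on internal held-out folds)."""
    from sklearn.calibration import CalibratedClassifierCV
    from sklearn.svm import SVC

    config = config or HOGConfig()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    model = HogSvmClassifier(svm=None, config=config, classes=classes, seed=seed)
    x = model.featurize(frames)
    y = np.array([classes.index(l) for l in labels])
    svm = SVC(
        C=config.C,
        kernel=config.kernel,
        gamma=config.gamma,
        class_weight=config.class_weight,
        random_state=seed,
        cache_size=500,
    )
    counts = np.bincount(y)
    cv = max(2, min(5, int(counts.min())))
    calibrated = CalibratedClassifierCV(svm, method="sigmoid", cv=cv, ensemble=False)
    calibrated.fit(x, y)
    model.svm = calibrated
    return model


class SmallCnnClassifier(TrainedClassifier):
    def __init__(self, net: SmallCnn, config: TrainConfig, classes, seed, history):
        super().__init__(
            classes,
            preprocessing=f"gray-resize{config.input_size}-center",
            seed=seed,
            metadata={"config": asdict(config)},
        )
        self.net = net
        self.config = config
        self.history = history

    def featurize(self, frames):
        return np.stack(
            [
                preprocess(fr.pixels, size=self.config.input_size, channels=1,
                           normalize="center")
                for fr in frames
            ]
        )

    def predict_proba(self, frames):
        return self.net.predict_proba(self.featurize(frames))


def train_small_cnn(
    frames: TypingSequence[Frame],
    labels: TypingSequence[str],
    val_frames: TypingSequence[Frame],
    val_labels: TypingSequence[str],
    config: TrainConfig | None = None,
    seed: int = 0,
    augment_training: bool = False,
) -> SmallCnnClassifier:
    """Train the small CNN with the fixed study recipe.

    Early stopping monitors validation loss (patience epochs past the
    minimum); the best-validation-loss weights are retained.  With
    ``augment_training`` each training frame additionally contributes one
    randomly rotated/flipped copy (validation and test are never augmented).
    """
    config = config or TrainConfig()
    config.validate()
    if len(val_frames) == 0:
        raise ValueError("validation set must be non-empty")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    net = SmallCnn(
        input_size=config.input_size,
        n_classes=len(classes),
        channels=config.channels,
        dropout=config.dropout,
        seed=seed,
    )
    model = SmallCnnClassifier(net, config, classes, seed, history=None)
    train_frames = list(frames)
    train_labels = list(labels)
    if augment_training:
        from dataclasses import replace as dc_replace

        from echorobust.data import augment as augment_frame

        aug_rng = np.random.default_rng([seed, 0xA06])
        for fr, lab in zip(list(frames), list(labels)):
            train_frames.append(
                dc_replace(fr, pixels=augment_frame(fr.pixels, aug_rng),
                           frame_id=fr.frame_id + "_aug")
            )
            train_labels.append(lab)
    x_train = model.featurize(train_frames)
    y_train = np.array([classes.index(l) for l in train_labels])
    x_val = model.featurize(val_frames)
    y_val = np.array([classes.index(l) for l in val_labels])
    history = fit_small_cnn(
        net,
        x_train,
        y_train,
        x_val,
        y_val,
        lr_backbone=config.lr_backbone,
        lr_head=config.lr_head,
        weight_decay=config.weight_decay,
        label_smoothing=config.label_smoothing,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.early_stopping_patience,
        seed=seed,
    )
    model.history = history
    return model


class FrozenFeatureClassifier(TrainedClassifier):
    def __init__(self, lr_model, extractor, classes, seed, metadata):
        super().__init__(classes, preprocessing="frozen-features", seed=seed,
                         metadata=metadata)
        self.lr_model = lr_model
        self.extractor = extractor

    def featurize(self, frames):
        return np.asarray(self.extractor(frames))

    def predict_proba(self, frames):
        return self.lr_model.predict_proba(self.featurize(frames))


def train_frozen_features_lr(
    frames,
    labels,
    extractor,
    val_frames,
    val_labels,
    seed: int = 0,
    Cs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0),
) -> FrozenFeatureClassifier:
    """Multinomial logistic regression on frozen embeddings; the inverse
    regularization strength is chosen on the validation set and recorded in
    the model metadata."""
    from sklearn.linear_model import LogisticRegression

    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    x = np.asarray(extractor(frames), dtype=float)
    if x.ndim != 2:
        raise ValueError("extractor must produce fixed-length vectors")
    if np.allclose(x.std(axis=0), 0.0):
        raise ValueError("degenerate (constant) features")
    y = np.array([classes.index(l) for l in labels])
    xv = np.asarray(extractor(val_frames), dtype=float)
    yv = np.array([classes.index(l) for l in val_labels])
    best = None
    for C in Cs:
        lr = LogisticRegression(C=C, max_iter=2000, random_state=seed)
        lr.fit(x, y)
        acc = float((lr.predict(xv) == yv).mean())
        if best is None or acc > best[0]:
            best = (acc, C, lr)
    acc, C, lr = best
    return FrozenFeatureClassifier(
        lr, extractor, classes, seed,
        metadata={"selected_C": C, "validation_accuracy": acc, "C_grid": list(Cs)},
    )


def predict_table(
    model: TrainedClassifier,
    frames: TypingSequence[Frame],
    labels: TypingSequence[str] | None = None,
) -> pd.DataFrame:
    """Run a model over frames and assemble the prediction table."""
    proba = np.asarray(model.predict_proba(frames), dtype=float)
    if not np.isfinite(proba).all() or (proba < 0).any():
        raise ValueError("model produced invalid probabilities")
    return make_table(
        frame_ids=[f.frame_id for f in frames],
        sequence_ids=[f.sequence_id for f in frames],
        true_labels=list(labels) if labels is not None else [None] * len(frames),
        proba=proba,
        classes=model.classes,
    )
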