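"""Manifest handling, leakage-safe splitting, preprocessing, augmentation.

Splitting follows the study protocol: the train/test split is performed at
the *sequence* level (all frames of a clip land on the same side, stratified
by view class), while the validation split is a *frame-level* stratified 20%
hold-out of the training frames.  The frame-level validation split is leaky
by construction — frames of one clip may appear on both sides — and is kept
because it is the protocol being emulated; a sequence-level validation
option is available for users who want a clean one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import transform as sktransform

MANIFEST_COLUMNS = ["frame_id", "sequence_id", "label", "frame_index", "path"]

# Standard ImageNet channel statistics, used as configuration data for the
# CNN input normalization convention (RGB order).
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


def validate_manifest(manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns and c != "path"]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if manifest["frame_id"].duplicated().any():
        raise ValueError("manifest frame_id values must be unique")
    labels_per_seq = manifest.groupby("sequence_id")["label"].nunique()
    if (labels_per_seq > 1).any():
        bad = labels_per_seq[labels_per_seq > 1].index.tolist()
        raise ValueError(f"sequences with inconsistent labels: {bad}")


def read_manifest(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        manifest = pd.read_json(path)
    else:
        manifest = pd.read_csv(path)
    validate_manifest(manifest)
    return manifest


@dataclass
class SplitAssignment:
    """Sequence-level train/test membership plus the frame-level
    train_fit/validation partition of the training side."""

    sequence_split: dict[str, str]  # sequence_id -> "train" | "test"
    frame_split: dict[str, str]  # frame_id (training side) -> "train_fit" | "validation"
    seeds: dict[str, int] = field(default_factory=dict)

    def test_sequences(self) -> list[str]:
        return sorted(s for s, p in self.sequence_split.items() if p == "test")

    def train_sequences(self) -> list[str]:
        return sorted(s for s, p in self.sequence_split.items() if p == "train")

    def frames(self, manifest: pd.DataFrame, part: str) -> pd.DataFrame:
        if part == "test":
            seqs = set(self.test_sequences())
            return manifest[manifest["sequence_id"].isin(seqs)]
        if part == "train":
            seqs = set(self.train_sequences())
            return manifest[manifest["sequence_id"].isin(seqs)]
        if part in ("train_fit", "validation"):
            ids = {f for f, p in self.frame_split.items() if p == part}
            return manifest[manifest["frame_id"].isin(ids)]
        raise ValueError(f"unknown part {part!r}")

    def to_json(self, path: Path | str) -> None:
        payload = {
            "sequence_split": self.sequence_split,
            "frame_split": self.frame_split,
            "seeds": self.seeds,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Path | str) -> "SplitAssignment":
        payload = json.loads(Path(path).read_text())
        return cls(
            sequence_split=payload["sequence_split"],
            frame_split=payload["frame_split"],
            seeds={k: int(v) for k, v in payload.get("seeds", {}).items()},
        )


def _largest_remainder_counts(class_sizes: dict[str, int], fraction: float) -> dict[str, int]:
    """Per-class test counts: floor the quotas, then hand out the remaining
    seats by largest fractional part (ties broken by class order), enforcing
    at least one test sequence per class."""
    labels = list(class_sizes)
    quotas = {k: fraction * class_sizes[k] for k in labels}
    counts = {k: int(np.floor(quotas[k])) for k in labels}
    target = int(round(fraction * sum(class_sizes.values())))
    remainder_order = sorted(
        labels, key=lambda k: (-(quotas[k] - counts[k]), labels.index(k))
    )
    i = 0
    while sum(counts.values()) < target and i < len(labels):
        counts[remainder_order[i]] += 1
        i += 1
    for k in labels:
        counts[k] = max(1, min(counts[k], class_sizes[k] - 1))
    return counts


def split_sequences(
    manifest: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> SplitAssignment:
    """Stratified sequence-level train/test split.

    Test counts per class are allocated by largest remainder so the global
    test share hits ``round(test_fraction * n_sequences)`` exactly where the
    per-class minimum of one allows.  Deterministic given ``seed``.
    """
    validate_manifest(manifest)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    seq_labels = (
        manifest.drop_duplicates("sequence_id").set_index("sequence_id")["label"]
    )
    class_sizes = seq_labels.value_counts().to_dict()
    if any(n < 2 for n in class_sizes.values()):
        bad = [k for k, n in class_sizes.items() if n < 2]
        raise ValueError(f"classes with < 2 sequences cannot be split: {bad}")
    counts = _largest_remainder_counts(class_sizes, test_fraction)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in sorted(class_sizes):
        seqs = sorted(seq_labels[seq_labels == label].index)
        order = rng.permutation(len(seqs))
        test_set = {seqs[i] for i in order[: counts[label]]}
        for s in seqs:
            assignment[s] = "test" if s in test_set else "train"
    return SplitAssignment(sequence_split=assignment, frame_split={}, seeds={"sequence": seed})


def split_validation_frames(
    training_frames: pd.DataFrame, fraction: float = 0.2, seed: int = 0
) -> dict[str, str]:
    """Frame-level stratified hold-out of the training frames.

    Returns ``frame_id -> "train_fit" | "validation"``.  Frames from one
    sequence may land on both sides — this mirrors the emulated protocol and
    is flagged in the docs.
    """
    from sklearn.model_selection import train_test_split

    if not 0.0 < fraction < 1.0:
        raise ValueError("validation fraction must be in (0, 1)")
    counts = training_frames["label"].value_counts()
    if (counts < 2).any() or counts.empty:
        raise ValueError("every class needs >= 2 training frames to stratify")
    frames = training_frames.sort_values("frame_id")
    fit_ids, val_ids = train_test_split(
        frames["frame_id"].to_numpy(),
        test_size=fraction,
        stratify=frames["label"].to_numpy(),
        random_state=seed,
    )
    out = {fid: "train_fit" for fid in fit_ids}
    out.update({fid: "validation" for fid in val_ids})
    return out


def split_validation_sequences(
    training_frames: pd.DataFrame, fraction: float = 0.2, seed: int = 0
) -> dict[str, str]:
    """Leak-free alternative: hold out whole training sequences (off by
    default; the frame-level split above is the emulated protocol)."""
    sub = split_sequences(training_frames, test_fraction=fraction, seed=seed)
    out = {}
    val_seqs = set(sub.test_sequences())
    for fid, sid in zip(training_frames["frame_id"], training_frames["sequence_id"]):
        out[fid] = "validation" if sid in val_seqs else "train_fit"
    return out


def make_split(
    manifest: pd.DataFrame,
    test_fraction: float = 0.2,
    validation_fraction: float = 0.2,
    seed: int = 0,
    sequence_level_validation: bool = False,
) -> SplitAssignment:
    """Full split: sequence-level train/test + validation hold-out."""
    assignment = split_sequences(manifest, test_fraction, seed)
    training = assignment.frames(manifest, "train")
    splitter = (
        split_validation_sequences if sequence_level_validation else split_validation_frames
    )
    assignment.frame_split = splitter(training, validation_fraction, seed + 1)
    assignment.seeds["validation"] = seed + 1
    return assignment


def preprocess(
    pixels: np.ndarray,
    size: int = 256,
    channels: int = 3,
    normalize: str = "imagenet",
) -> np.ndarray:
    """Resize (bilinear) to ``size x size``, replicate to ``channels``
    channels, standardize.  Returns a (channels, size, size) float32 array.

    ``normalize="imagenet"`` uses the published ImageNet channel statistics;
    ``"center"`` uses mean 0.5 / std 0.5; ``"none"`` leaves values in [0, 1].
    """
    if pixels.size == 0:
        raise ValueError("empty image")
    img = np.asarray(pixels, dtype=np.float64)
    if img.shape != (size, size):
        img = sktransform.resize(
            img, (size, size), order=1, mode="edge", anti_aliasing=False
        )
    stack = np.repeat(img[None, :, :], channels, axis=0)
    if normalize == "imagenet":
        mean = np.asarray(IMAGENET_MEAN[:channels]).reshape(-1, 1, 1)
        std = np.asarray(IMAGENET_STD[:channels]).reshape(-1, 1, 1)
        stack = (stack - mean) / std
    elif normalize == "center":
        stack = (stack - 0.5) / 0.5
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    return stack.astype(np.float32)


def augment(
    pixels: np.ndarray,
    rng: np.random.Generator,
    max_rotation_deg: float = 10.0,
    flip_probability: float = 0.5,
) -> np.ndarray:
    """Training-time augmentation: rotation uniform in +/-10 degrees
    (bilinear, zero fill) and horizontal flip with probability 1/2."""
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    out = np.asarray(pixels, dtype=np.float64)
    if angle != 0.0:
        out = sktransform.rotate(out, angle, order=1, mode="constant", cval=0.0)
    if rng.uniform() < flip_probability:
        out = out[:, ::-1]
    return np.ascontiguousarray(out, dtype=np.float32)
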