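"""Run configuration: a single validated document driving the whole pipeline.

One global seed fans out to per-stage seeds by hashing the stage name, so
any stage can be re-run independently yet the full run is reproducible from
(config, seed) alone.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from echorobust.models import HOGConfig, TrainConfig
from echorobust.phantom import PhantomConfig


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2**31)."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


class BootstrapSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    B: int = 1000
    alpha: float = 0.05


class LearningCurveSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fractions: list[float] = [0.25, 0.5, 0.75, 1.0]
    n_seeds: int = 3


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "results/run"
    phantom: dict = Field(default_factory=dict)  # PhantomConfig overrides
    test_fraction: float = 0.2
    validation_fraction: float = 0.2
    sequence_level_validation: bool = False
    classifier: str = "hog_svm"  # "hog_svm" | "small_cnn"
    hog: dict = Field(default_factory=dict)  # HOGConfig overrides
    cnn: dict = Field(default_factory=dict)  # TrainConfig overrides
    bootstrap: BootstrapSettings = Field(default_factory=BootstrapSettings)
    artifacts: list[str] = ["motion_blur", "acoustic_shadow", "speckle"]
    grids: dict[str, list[float]] = Field(default_factory=dict)
    failure_threshold: float = 0.8
    learning_curve: LearningCurveSettings | None = None
    save_frames: bool = False

    def phantom_config(self) -> PhantomConfig:
        cfg = PhantomConfig(**self.phantom)
        cfg.validate()
        return cfg

    def hog_config(self) -> HOGConfig:
        raw = dict(self.hog)
        for key in ("pixels_per_cell", "cells_per_block"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return HOGConfig(**raw)

    def cnn_config(self) -> TrainConfig:
        raw = dict(self.cnn)
        if "channels" in raw:
            raw["channels"] = tuple(raw["channels"])
        cfg = TrainConfig(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def study(cls, classifier: str = "small_cnn", seed: int = 0,
              out_dir: str = "results/run") -> "RunConfig":
        """The default phantom-study configuration: the emulated study's dataset composition,
        full severity grids, B = 1000 clustered bootstrap.

        The small CNN is trained from scratch, so it uses a larger learning
        rate than the fine-tuning recipe, 96-px inputs (close to the native
        256-px protocol while trainable on one CPU) and a short cosine
        schedule.
        """
        return cls(
            seed=seed,
            out_dir=out_dir,
            classifier=classifier,
            cnn={
                "lr_backbone": 1e-3,
                "lr_head": 1e-3,
                "max_epochs": 15,
                "early_stopping_patience": 6,
                "input_size": 96,
            },
        )

    @classmethod
    def from_file(cls, path: Path | str) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(payload or {})

    def dump(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=1, sort_keys=True))
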