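import numpy as np
import pandas as pd
import pytest

from echorobust.metrics import make_table
from echorobust.phantom import PhantomConfig, iter_sequences


@pytest.fixture(scope="session")
def small_config():
    """Half-resolution, ~40-clip phantom study used across the suite."""
    return PhantomConfig(
        image_height=128,
        image_width=128,
        frames_per_sequence=4,
        sequences_per_class={"A2C": 5, "A3C": 4, "A4C": 6, "A5C": 4},
        frames_per_class=None,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(frames, labels, manifest) for the small phantom study."""
    frames, labels, rows = [], [], []
    for seq in iter_sequences(small_config, seed=1234):
        for fr in seq.frames:
            frames.append(fr)
            labels.append(seq.view.label)
            rows.append(
                {
                    "frame_id": fr.frame_id,
                    "sequence_id": fr.sequence_id,
                    "label": seq.view.label,
                    "frame_index": fr.frame_index,
                    "path": "",
                }
            )
    return frames, labels, pd.DataFrame(rows)


def table_from_predictions(y_true, y_pred, classes, sequence_ids=None, confidence=0.9):
    """Build a prediction table whose argmax equals ``y_pred``."""
    n = len(y_true)
    k = len(classes)
    proba = np.full((n, k), (1 - confidence) / (k - 1))
    for i, p in enumerate(y_pred):
        proba[i, classes.index(p)] = confidence
    if sequence_ids is None:
        sequence_ids = [f"s{i:03d}" for i in range(n)]
    return make_table(
        frame_ids=[f"f{i:04d}" for i in range(n)],
        sequence_ids=sequence_ids,
        true_labels=list(y_true),
        proba=proba,
        classes=classes,
    )


@pytest.fixture
def prediction_table_factory():
    return table_from_predictions
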