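"""Feed-forward neural-network comparator.

A rectangular multilayer perceptron — six hidden layers of 100 rectifier
units — classifies windows directly into the full multiclass label set,
including an explicit outlier class.  Unlike the elimination cascade, this
baseline therefore needs labelled outlier examples at training time.
Training runs for at most 100 epochs with batches of 40 and stops early
when a held-out validation split stops improving for two consecutive
epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import FeatureDataset

__all__ = ["MLPConfig", "relu", "train_mlp", "predict_mlp"]


def relu(x):
    """Rectified linear activation, f(x) = max(0, x); works elementwise."""
    return np.maximum(0, x)


@dataclass(frozen=True)
class MLPConfig:
    """Network architecture and training schedule."""

    hidden_layers: int = 6
    units_per_layer: int = 100
    max_epochs: int = 100
    batch_size: int = 40
    patience: int = 2
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if min(
            self.hidden_layers, self.units_per_layer, self.max_epochs,
            self.batch_size, self.patience,
        ) < 1:
            raise ValueError("all MLP config integers must be positive")


def train_mlp(
    train: FeatureDataset, config: MLPConfig | None = None, seed: int = 0
) -> tuple[Pipeline, pd.DataFrame]:
    """Fit the rectangular MLP; returns (model, per-epoch curves).

    The curves frame has one row per completed epoch with the training
    loss and, where early stopping is active, the validation accuracy.
    Features are standardized inside the returned pipeline.
    """
    config = config or MLPConfig()
    classes = set(train.labels)
    if len(classes) < 2:
        raise ValueError("MLP training needs at least 2 classes")

    clf = MLPClassifier(
        hidden_layer_sizes=(config.units_per_layer,) * config.hidden_layers,
        activation="relu",
        solver="adam",
        batch_size=config.batch_size,
        max_iter=config.max_epochs,
        early_stopping=True,
        n_iter_no_change=config.patience,
        validation_fraction=config.validation_fraction,
        random_state=seed,
    )
    model = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    model.fit(train.features, train.labels.to_numpy())

    fitted = model.named_steps["clf"]
    curves = pd.DataFrame(
        {
            "epoch": np.arange(1, fitted.n_iter_ + 1),
            "train_loss": fitted.loss_curve_[: fitted.n_iter_],
            "validation_accuracy": fitted.validation_scores_[: fitted.n_iter_],
        }
    )
    return model, curves


def predict_mlp(model: Pipeline, test: FeatureDataset) -> np.ndarray:
    """Predict one label per test record from the training label set."""
    if len(test) == 0:
        return np.array([], dtype=object)
    trained_cols = list(model.named_steps["scale"].feature_names_in_)
    if list(test.features.columns) != trained_cols:
        raise ValueError("test feature schema does not match the training schema")
    return np.asarray(model.predict(test.features), dtype=object)
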