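"""The four model families and their hyperparameter spaces.

KNN and SVR wrap scikit-learn; the CNN and LSTM are the package's compact
numpy implementations.  ``train_predict`` is the single entry point used by
optimizers, scenarios and ensembles: fit on train only, predict the test
arrays, deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from .datasets import MLDataset
from .nets import CNNRegressor, LSTMRegressor

__all__ = ["MODEL_KINDS", "default_space", "validate_config", "make_model",
           "train_predict"]

MODEL_KINDS = ("KNN", "SVR", "CNN", "LSTM")

#: hyperparameter spaces: name -> {"type": int|float|logfloat|choice, ...}
_SPACES = {
    "KNN": {
        "n_neighbors": {"type": "int", "bounds": (1, 20)},
        "weights": {"type": "choice", "choices": ["uniform", "distance"]},
    },
    "SVR": {
        "C": {"type": "logfloat", "bounds": (1e-2, 1e2)},
        "epsilon": {"type": "logfloat", "bounds": (1e-3, 1.0)},
        "kernel": {"type": "choice", "choices": ["rbf", "linear"]},
    },
    "CNN": {
        "n_filters": {"type": "choice", "choices": [4, 8, 16]},
        "kernel_size": {"type": "choice", "choices": [3, 5, 7]},
        "lr": {"type": "logfloat", "bounds": (1e-3, 3e-2)},
        "epochs": {"type": "int", "bounds": (30, 80)},
    },
    "LSTM": {
        "hidden_size": {"type": "choice", "choices": [8, 16, 32]},
        "chunk_size": {"type": "choice", "choices": [8, 16]},
        "lr": {"type": "logfloat", "bounds": (1e-3, 3e-2)},
        "epochs": {"type": "int", "bounds": (30, 80)},
    },
}


def default_space(kind: str) -> dict:
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    return {k: dict(v) for k, v in _SPACES[kind].items()}


def validate_config(kind: str, config: dict) -> None:
    space = default_space(kind)
    for name, value in config.items():
        if name not in space:
            raise ValueError(f"{kind}: unknown hyperparameter {name!r}")
        spec = space[name]
        if spec["type"] == "choice":
            if value not in spec["choices"]:
                raise ValueError(f"{kind}: {name}={value!r} not in {spec['choices']}")
        else:
            lo, hi = spec["bounds"]
            if not lo <= value <= hi:
                raise ValueError(f"{kind}: {name}={value} outside [{lo}, {hi}]")


def make_model(kind: str, config: dict, seed: int = 0, validate: bool = True):
    # optimizers searching a custom space skip the default-space check
    if validate:
        validate_config(kind, config)
    if kind == "KNN":
        return KNeighborsRegressor(
            n_neighbors=int(config.get("n_neighbors", 5)),
            weights=config.get("weights", "uniform"),
        )
    if kind == "SVR":
        return SVR(
            C=float(config.get("C", 1.0)),
            epsilon=float(config.get("epsilon", 0.1)),
            kernel=config.get("kernel", "rbf"),
        )
    if kind == "CNN":
        return CNNRegressor(
            n_filters=config.get("n_filters", 8),
            kernel_size=config.get("kernel_size", 5),
            lr=config.get("lr", 1e-2),
            epochs=config.get("epochs", 60),
            seed=seed,
        )
    if kind == "LSTM":
        return LSTMRegressor(
            hidden_size=config.get("hidden_size", 16),
            chunk_size=config.get("chunk_size", 16),
            lr=config.get("lr", 1e-2),
            epochs=config.get("epochs", 60),
            seed=seed,
        )
    raise ValueError(f"unknown model kind {kind!r}")


def train_predict(
    kind: str,
    config: dict,
    train: MLDataset,
    test: MLDataset,
    seed: int = 0,
) -> np.ndarray:
    """Fit on the training split only and predict the test arrays."""
    model = make_model(kind, config, seed=seed)
    model.fit(train.X.to_numpy(), train.y.to_numpy())
    return np.asarray(model.predict(test.X.to_numpy()), dtype=float)
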