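"""ML dataset container and train/test splitting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MLDataset", "split_dataset"]

VIEWS = ("transcription", "translation")
ORIGINS = ("experimental", "simulated")


@dataclass
class MLDataset:
    """Arrays × features matrix with a growth-rate target.

    ``view`` records whether features are transcript- or protein-level
    expression; ``origin`` flags each array as experimental or simulated
    (ME-model-generated).
    """

    X: pd.DataFrame  # arrays × features, no missing values
    y: pd.Series  # growth rate per array, 1/h
    view: str = "transcription"
    origin: pd.Series | None = None

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if not self.X.index.equals(self.y.index):
            raise ValueError("X rows and y are not aligned")
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("dataset contains missing values")
        if self.origin is None:
            self.origin = pd.Series("experimental", index=self.X.index)
        bad = ~self.origin.isin(ORIGINS)
        if bad.any():
            raise ValueError(f"invalid origin flags: {self.origin[bad].unique()}")

    @property
    def n_arrays(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, index) -> "MLDataset":
        return MLDataset(
            self.X.loc[index], self.y.loc[index], self.view, self.origin.loc[index]
        )


def split_dataset(
    ds: MLDataset, train_frac: float = 0.8, seed: int = 0
) -> tuple[MLDataset, MLDataset]:
    """Reproducible random split into disjoint, exhaustive train/test sets."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0,1), got {train_frac}")
    if ds.n_arrays < 5:
        raise ValueError("need at least 5 arrays to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_arrays)
    n_train = int(round(train_frac * ds.n_arrays))
    n_train = min(max(n_train, 1), ds.n_arrays - 1)
    train_idx = ds.X.index[np.sort(perm[:n_train])]
    test_idx = ds.X.index[np.sort(perm[n_train:])]
    return ds.subset(train_idx), ds.subset(test_idx)
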