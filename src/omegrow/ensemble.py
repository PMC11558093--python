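"""Two-view ensembles: combine transcription- and translation-view
predictors with a stacked least-squares combiner.

The named ensembles follow the optimizer-prefix convention of the scenario
matrix: AB = ACOCNN on the translation view + BOLSTM on the transcription
view, BB = BOLSTM on both, AA = ACOCNN on both.  The baseline is a single
SVR on the two views' concatenated features.  The combiner is ordinary
least squares on *out-of-fold* member predictions, so no member's training
targets leak into the stacking fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .compendium import ExpressionCompendium
from .ml.datasets import MLDataset, split_dataset
from .ml.metrics import Metrics, compute_metrics
from .ml.models import make_model, train_predict
from .ml.scenarios import Scenario, repeated_evaluation

__all__ = ["EnsembleSpec", "FittedEnsemble", "NAMED_ENSEMBLES", "build_ensemble",
           "predict_growth_profiles", "compare_ensembles"]


@dataclass(frozen=True)
class EnsembleSpec:
    label: str  # AB | BB | AA | SVR-baseline | custom
    transcription_member: tuple[str, dict]  # (model kind, config)
    translation_member: tuple[str, dict]


#: the three named two-member ensembles (member = model kind; the optimizer
#: that produced each config is historical — configs are passed explicitly)
NAMED_ENSEMBLES = {
    "AB": ("LSTM", "CNN"),  # BOLSTM on transcription, ACOCNN on translation
    "BB": ("LSTM", "LSTM"),
    "AA": ("CNN", "CNN"),
}


@dataclass
class FittedEnsemble:
    spec: EnsembleSpec
    members: dict = field(default_factory=dict)  # view -> fitted model
    coef: np.ndarray | None = None  # (w_transcription, w_translation)
    intercept: float = 0.0
    feature_columns: dict = field(default_factory=dict)  # view -> columns
    feature_means: dict = field(default_factory=dict)  # view -> train means

    def predict_members(self, X_tx: pd.DataFrame, X_tl: pd.DataFrame) -> np.ndarray:
        p_tx = self.members["transcription"].predict(X_tx.to_numpy())
        p_tl = self.members["translation"].predict(X_tl.to_numpy())
        return np.column_stack([p_tx, p_tl])

    def predict(self, X_tx: pd.DataFrame, X_tl: pd.DataFrame) -> np.ndarray:
        P = self.predict_members(X_tx, X_tl)
        return P @ self.coef + self.intercept


def build_ensemble(
    spec: EnsembleSpec,
    transcription_ds: MLDataset,
    translation_ds: MLDataset,
    seed: int = 0,
    n_folds: int = 5,
) -> FittedEnsemble:
    """Train both members and fit the OLS combiner on out-of-fold predictions."""
    if not transcription_ds.X.index.equals(translation_ds.X.index):
        a = set(transcription_ds.X.index)
        b = set(translation_ds.X.index)
        raise ValueError(
            f"array ids differ between views: only-transcription={sorted(a - b)[:5]}, "
            f"only-translation={sorted(b - a)[:5]}"
        )
    fitted = FittedEnsemble(spec=spec)
    datasets = {"transcription": transcription_ds, "translation": translation_ds}
    configs = {
        "transcription": spec.transcription_member,
        "translation": spec.translation_member,
    }
    n = transcription_ds.n_arrays
    oof = np.full((n, 2), np.nan)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for col, view in enumerate(("transcription", "translation")):
        kind, config = configs[view]
        ds = datasets[view]
        X, y = ds.X.to_numpy(), ds.y.to_numpy()
        for tr, va in kf.split(X):
            model = make_model(kind, config, seed=seed)
            model.fit(X[tr], y[tr])
            oof[va, col] = model.predict(X[va])
        final = make_model(kind, config, seed=seed)
        final.fit(X, y)
        fitted.members[view] = final
        fitted.feature_columns[view] = list(ds.X.columns)
        fitted.feature_means[view] = ds.X.mean()
    y = transcription_ds.y.to_numpy()
    A = np.column_stack([oof, np.ones(n)])
    coefs, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted.coef = coefs[:2]
    fitted.intercept = float(coefs[2])
    return fitted


def predict_growth_profiles(
    ensemble: FittedEnsemble,
    comp: ExpressionCompendium,
) -> tuple[pd.Series, int]:
    """Growth-rate prediction for every compendium array.

    Compendium genes are mapped onto each view's training features;
    unmappable features are imputed with training means (counted and
    returned); more than 50% unmappable in either view is an error.
    """
    profiles = comp.values.T  # arrays × genes
    view_X = {}
    n_imputed_features = 0
    for view in ("transcription", "translation"):
        cols = ensemble.feature_columns[view]
        missing = [c for c in cols if c not in profiles.columns]
        if len(missing) > 0.5 * len(cols):
            raise ValueError(
                f"{view} view: {len(missing)}/{len(cols)} features unmappable"
            )
        n_imputed_features += len(missing)
        X = pd.DataFrame(index=profiles.index, columns=cols, dtype=float)
        present = [c for c in cols if c in profiles.columns]
        X[present] = profiles[present]
        for c in missing:
            X[c] = ensemble.feature_means[view][c]
        X = X.fillna(pd.Series(ensemble.feature_means[view]))
        view_X[view] = X
    preds = ensemble.predict(view_X["transcription"], view_X["translation"])
    return pd.Series(preds, index=profiles.index, name="mu_pred"), n_imputed_features


def compare_ensembles(
    specs: list[EnsembleSpec],
    transcription_ds: MLDataset,
    translation_ds: MLDataset,
    n_repeats: int = 10,
    seed0: int = 0,
    train_frac: float = 0.8,
) -> pd.DataFrame:
    """Repeatedly re-split, refit and test each spec; rank by mean test R².

    The SVR-baseline label is handled specially: one SVR on concatenated
    views.  Returns a DataFrame sorted by ``r2_mean`` (descending).
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 ensemble specs to compare")
    rows = []
    for spec in specs:
        r2s, rmses = [], []
        for rep in range(n_repeats):
            seed = seed0 + rep
            tx_train, tx_test = split_dataset(transcription_ds, train_frac, seed)
            tl_train, tl_test = split_dataset(translation_ds, train_frac, seed)
            if spec.label == "SVR-baseline":
                Xtr = pd.concat([tx_train.X, tl_train.X], axis=1)
                Xte = pd.concat([tx_test.X, tl_test.X], axis=1)
                both_tr = MLDataset(Xtr, tx_train.y, "transcription",
                                    tx_train.origin)
                both_te = MLDataset(Xte, tx_test.y, "transcription",
                                    tx_test.origin)
                kind, config = spec.transcription_member
                y_pred = train_predict(kind, config, both_tr, both_te, seed=seed)
            else:
                fitted = build_ensemble(spec, tx_train, tl_train, seed=seed)
                y_pred = fitted.predict(tx_test.X, tl_test.X)
            m = compute_metrics(tx_test.y.to_numpy(), y_pred)
            r2s.append(m.r2)
            rmses.append(m.rmse)
        rows.append(
            {
                "label": spec.label,
                "r2_mean": float(np.mean(r2s)),
                "r2_sd": float(np.std(r2s)),
                "rmse_mean": float(np.mean(rmses)),
                "n_repeats": n_repeats,
            }
        )
    df = pd.DataFrame(rows).sort_values("r2_mean", ascending=False)
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)
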