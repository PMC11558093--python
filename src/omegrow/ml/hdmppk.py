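"""HDMPPK feature engineering: a six-stage chain named for its algorithms.

H — histogram gradient-boosted tree importance ranking (keep top-m);
D — density-based spatial clustering (DBSCAN) to drop outlier arrays;
M — min–max rescaling of the surviving features;
P — principal-component projection keeping a variance fraction;
P — particle-swarm search over binary component inclusion;
K — k-nearest-neighbor cross-validated fitness of the final subset.

The report maps the retained components back to the original features that
load on them, so planted-informative-feature recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.model_selection import KFold, cross_val_score
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import MinMaxScaler

from .datasets import MLDataset

__all__ = ["hdmppk", "FeatureReport", "pso_subset_search"]


@dataclass
class FeatureReport:
    ranked_features: list[str] = field(default_factory=list)  # top-m after stage 1
    n_arrays_dropped: int = 0
    n_components: int = 0
    selected_components: list[int] = field(default_factory=list)
    selected_features: list[str] = field(default_factory=list)
    cv_fitness: float = float("nan")
    stage_order: tuple = (
        "hgbr_importance", "dbscan_outliers", "minmax", "pca", "pso", "knn_fitness",
    )


def _knn_cv_fitness(X: np.ndarray, y: np.ndarray, n_folds: int = 5,
                    n_neighbors: int = 5) -> float:
    """Cross-validated R² of a k-NN regressor; the PSO fitness function."""
    if X.ndim != 2 or X.shape[1] == 0:
        return -1.0
    n_folds = min(n_folds, len(y))
    knn = KNeighborsRegressor(n_neighbors=min(n_neighbors, len(y) - 1))
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=0)
    return float(np.mean(cross_val_score(knn, X, y, cv=cv, scoring="r2")))


def pso_subset_search(
    X: np.ndarray,
    y: np.ndarray,
    n_particles: int = 30,
    n_iters: int = 50,
    inertia: float = 0.72,
    cognitive: float = 1.49,
    social: float = 1.49,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Binary particle swarm over column inclusion, k-NN CV R² as fitness.

    Velocities are continuous; inclusion probabilities pass through a
    sigmoid (standard binary-PSO transfer).  Returns (best mask, fitness).
    """
    rng = np.random.default_rng(seed)
    d = X.shape[1]
    vel = rng.normal(0, 1, size=(n_particles, d))
    pos = rng.random((n_particles, d)) < 0.5
    pos[:, :] |= ~pos.any(axis=1, keepdims=True)  # no empty subsets
    pbest = pos.copy()
    pbest_fit = np.array([_knn_cv_fitness(X[:, p], y) for p in pos])
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    for _ in range(n_iters):
        r1 = rng.random((n_particles, d))
        r2 = rng.random((n_particles, d))
        vel = (
            inertia * vel
            + cognitive * r1 * (pbest.astype(float) - pos.astype(float))
            + social * r2 * (gbest.astype(float) - pos.astype(float))
        )
        prob = 1.0 / (1.0 + np.exp(-np.clip(vel, -10, 10)))
        pos = rng.random((n_particles, d)) < prob
        empty = ~pos.any(axis=1)
        if empty.any():
            pos[empty, rng.integers(0, d, size=int(empty.sum()))] = True
        fits = np.array([_knn_cv_fitness(X[:, p], y) for p in pos])
        better = fits > pbest_fit
        pbest[better] = pos[better]
        pbest_fit[better] = fits[better]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    return gbest, gbest_fit


def hdmppk(
    ds: MLDataset,
    top_m: int | None = None,
    dbscan_eps_factor: float = 2.5,
    dbscan_min_samples: int = 5,
    pca_variance: float = 0.95,
    n_particles: int = 30,
    n_iters: int = 50,
    seed: int = 0,
) -> tuple[MLDataset, FeatureReport]:
    """Run the six HDMPPK stages on a dataset; deterministic given ``seed``.

    ``top_m`` defaults to min(200, n_features).  DBSCAN operates on the
    standardized top-m feature space with eps scaled by √dims; arrays
    labeled noise are removed.  The returned dataset holds the PSO-selected
    principal-component scores; because components mix features, the
    report's ``selected_features`` attribution comes from the supervised
    importance stage (features scoring above the mean importance).
    """
    report = FeatureReport()
    X, y = ds.X, ds.y

    # 1. importance ranking (permutation importance of an HGBR fit)
    m = top_m if top_m is not None else min(200, ds.n_features)
    if ds.n_features < m:
        import warnings

        warnings.warn("fewer features than top_m; importance ranking skipped")
        ranked = list(X.columns)
        report.selected_features = ranked
    else:
        # shallow trees suit additive expression->growth signals and make the
        # permutation importances far less noisy than deep overfit ensembles
        hgbr = HistGradientBoostingRegressor(
            random_state=seed, max_iter=300, max_depth=2
        )
        hgbr.fit(X.to_numpy(), y.to_numpy())
        from sklearn.inspection import permutation_importance

        imp = permutation_importance(
            hgbr, X.to_numpy(), y.to_numpy(), n_repeats=5, random_state=seed
        ).importances_mean
        order = np.argsort(-imp, kind="stable")
        ranked = [X.columns[i] for i in order[:m]]
        report.selected_features = [
            X.columns[i] for i in np.flatnonzero(imp > max(imp.mean(), 0.0))
        ]
    report.ranked_features = ranked
    Xr = X[ranked]

    # 2. DBSCAN outlier arrays
    mu, sd = Xr.mean(), Xr.std().replace(0, 1.0)
    Z = (Xr - mu) / sd
    labels = DBSCAN(eps=dbscan_eps_factor * np.sqrt(Xr.shape[1]),
                    min_samples=dbscan_min_samples).fit_predict(Z.to_numpy())
    keep = labels != -1
    if keep.sum() < 5:  # degenerate clustering: keep everything
        keep = np.ones(len(Xr), dtype=bool)
    report.n_arrays_dropped = int((~keep).sum())
    Xr, yk = Xr.loc[keep], y.loc[keep]

    # 3. min–max rescale
    scaler = MinMaxScaler()
    Xs = scaler.fit_transform(Xr.to_numpy())

    # 4. PCA keeping a variance fraction
    n_comp_max = min(Xs.shape) - 1
    pca = PCA(n_components=min(pca_variance, 0.9999), random_state=seed) \
        if n_comp_max > 1 else PCA(n_components=n_comp_max)
    scores = pca.fit_transform(Xs)
    report.n_components = scores.shape[1]

    # 5. PSO over component inclusion
    mask, fitness = pso_subset_search(
        scores, yk.to_numpy(), n_particles=n_particles, n_iters=n_iters, seed=seed
    )
    report.selected_components = [int(i) for i in np.flatnonzero(mask)]

    # 6. final k-NN fitness
    report.cv_fitness = _knn_cv_fitness(scores[:, mask], yk.to_numpy())

    out = MLDataset(
        pd.DataFrame(
            scores[:, mask],
            index=Xr.index,
            columns=[f"PC{i + 1}" for i in report.selected_components],
        ),
        yk,
        ds.view,
        ds.origin.loc[Xr.index],
    )
    return out, report
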