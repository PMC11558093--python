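"""Five hyperparameter search strategies over a declared space.

grid      — exhaustive over a lattice (choices × discretized numeric dims);
random    — uniform draws from the space;
ACO       — ant colony optimization: each dimension discretized into levels
            carrying pheromone; ants sample levels pheromone-proportionally,
            pheromone evaporates and the iteration's best ants deposit;
HHO       — Harris Hawks optimization over the unit box encoding of the
            space (soft/hard besiege phases driven by escaping energy);
Bayes     — Gaussian-process surrogate with expected-improvement
            acquisition over random candidate pools.

Every evaluation is recorded in the trace; the default fitness is k-fold
cross-validated R² of the model kind on the training split.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as _stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import KFold

from .datasets import MLDataset
from .metrics import compute_metrics
from .models import make_model

__all__ = ["OPTIMIZERS", "optimize_hyperparams"]

OPTIMIZERS = ("grid", "random", "ACO", "HHO", "Bayes")


# -- space encoding ---------------------------------------------------------


def _decode(space: dict, u: np.ndarray) -> dict:
    """Map a point of the unit box to a concrete configuration."""
    config = {}
    for x, (name, spec) in zip(u, sorted(space.items())):
        x = float(min(max(x, 0.0), 1.0))
        if spec["type"] == "choice":
            k = len(spec["choices"])
            config[name] = spec["choices"][min(int(x * k), k - 1)]
        elif spec["type"] == "int":
            lo, hi = spec["bounds"]
            config[name] = int(round(lo + x * (hi - lo)))
        elif spec["type"] == "float":
            lo, hi = spec["bounds"]
            config[name] = lo + x * (hi - lo)
        elif spec["type"] == "logfloat":
            lo, hi = spec["bounds"]
            config[name] = float(10 ** (math.log10(lo) + x * (math.log10(hi) - math.log10(lo))))
        else:
            raise ValueError(f"unknown hyperparameter type {spec['type']!r}")
    return config


def _dim_levels(spec: dict, n_levels: int) -> list:
    if spec["type"] == "choice":
        return list(spec["choices"])
    if spec["type"] == "int":
        lo, hi = spec["bounds"]
        step = max(1, (hi - lo) // (n_levels - 1)) if n_levels > 1 else 1
        vals = sorted(set(list(range(lo, hi + 1, step)) + [hi]))
        return vals[:n_levels] if len(vals) > n_levels else vals
    lo, hi = spec["bounds"]
    if spec["type"] == "logfloat":
        return list(np.logspace(math.log10(lo), math.log10(hi), n_levels))
    return list(np.linspace(lo, hi, n_levels))


# -- strategies -------------------------------------------------------------


def _grid(space, budget, fitness, rng, grid_points=4):
    axes = [
        [(name, v) for v in _dim_levels(spec, grid_points)]
        for name, spec in sorted(space.items())
    ]
    trace = []
    for combo in itertools.product(*axes):
        if len(trace) >= budget:
            break
        config = dict(combo)
        trace.append((config, fitness(config)))
    return trace


def _random(space, budget, fitness, rng):
    d = len(space)
    trace = []
    for _ in range(budget):
        config = _decode(space, rng.random(d))
        trace.append((config, fitness(config)))
    return trace


def _aco(space, budget, fitness, rng, n_levels=16, n_ants=10, evaporation=0.1):
    names = sorted(space)
    levels = {n: _dim_levels(space[n], n_levels) for n in names}
    pher = {n: np.ones(len(levels[n])) for n in names}
    trace = []
    n_iters = max(1, budget // n_ants)
    spent = 0
    for _ in range(n_iters):
        ants = []
        for _ in range(n_ants):
            if spent >= budget:
                break
            idx = {
                n: rng.choice(len(levels[n]), p=pher[n] / pher[n].sum())
                for n in names
            }
            config = {n: levels[n][idx[n]] for n in names}
            score = fitness(config)
            trace.append((config, score))
            ants.append((idx, score))
            spent += 1
        if not ants:
            break
        for n in names:
            pher[n] *= 1.0 - evaporation
        ants.sort(key=lambda a: a[1], reverse=True)
        for rank, (idx, score) in enumerate(ants[: max(1, n_ants // 3)]):
            deposit = 1.0 / (1.0 + rank)
            for n in names:
                pher[n][idx[n]] += deposit
    return trace


def _hho(space, budget, fitness, rng, pop_size=10):
    """Harris Hawks: exploration vs soft/hard besiege, unit-box encoded."""
    d = len(space)
    pop_size = min(pop_size, budget)
    X = rng.random((pop_size, d))
    trace = []

    def evaluate(x):
        config = _decode(space, x)
        s = fitness(config)
        trace.append((config, s))
        return s

    scores = np.array([evaluate(x) for x in X])
    n_iters = max(0, (budget - pop_size) // pop_size)
    for it in range(n_iters):
        best = X[np.argmax(scores)].copy()
        E1 = 2.0 * (1.0 - (it + 1) / max(n_iters, 1))
        for i in range(pop_size):
            E = E1 * (2.0 * rng.random() - 1.0)
            r = rng.random()
            if abs(E) >= 1:  # exploration
                if r < 0.5:
                    j = rng.integers(pop_size)
                    x_new = X[j] - rng.random() * np.abs(
                        X[j] - 2.0 * rng.random() * X[i]
                    )
                else:
                    x_new = (best - X.mean(axis=0)) - rng.random() * rng.random(d)
            else:  # exploitation around the best (rabbit)
                if r >= 0.5 and abs(E) >= 0.5:  # soft besiege
                    x_new = (best - X[i]) - E * np.abs(
                        2.0 * (1.0 - rng.random()) * best - X[i]
                    )
                elif r >= 0.5:  # hard besiege
                    x_new = best - E * np.abs(best - X[i])
                else:  # besiege with progressive rapid dives
                    y = best - E * np.abs(2.0 * (1.0 - rng.random()) * best - X[i])
                    x_new = y + 0.01 * rng.standard_normal(d)
            x_new = np.clip(x_new, 0.0, 1.0)
            s = evaluate(x_new)
            if s > scores[i]:
                X[i], scores[i] = x_new, s
            if len(trace) >= budget:
                return trace
    return trace


def _bayes(space, budget, fitness, rng, n_init=5, n_candidates=256):
    d = len(space)
    n_init = min(n_init, budget)
    U = rng.random((n_init, d))
    trace = []

    def evaluate(u):
        config = _decode(space, u)
        s = fitness(config)
        trace.append((config, s))
        return s

    ys = [evaluate(u) for u in U]
    U = list(U)
    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-6, random_state=0
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    while len(trace) < budget:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.array(U), np.array(ys))
        cand = rng.random((n_candidates, d))
        mu, sd = gp.predict(cand, return_std=True)
        best = max(ys)
        sd = np.maximum(sd, 1e-12)
        z = (mu - best) / sd
        ei = (mu - best) * _stats.norm.cdf(z) + sd * _stats.norm.pdf(z)
        u = cand[int(np.argmax(ei))]
        ys.append(evaluate(u))
        U.append(u)
    return trace


# -- entry point ------------------------------------------------------------


def _cv_fitness(kind: str, train: MLDataset, seed: int, n_folds: int = 5):
    X = train.X.to_numpy()
    y = train.y.to_numpy()
    cv = KFold(n_splits=min(n_folds, len(y)), shuffle=True, random_state=seed)

    def fitness(config: dict) -> float:
        scores = []
        for tr, va in cv.split(X):
            model = make_model(kind, config, seed=seed, validate=False)
            model.fit(X[tr], y[tr])
            m = compute_metrics(y[va], model.predict(X[va]))
            scores.append(m.r2)
        return float(np.mean(scores))

    return fitness


def optimize_hyperparams(
    kind: str | None,
    method: str,
    space: dict,
    budget: int,
    train: MLDataset | None = None,
    seed: int = 0,
    cv: int = 5,
    fitness=None,
    grid_points: int = 4,
) -> tuple[dict, float, list]:
    """Search ``space`` with one of the five strategies.

    Returns (best config, best score, trace).  ``fitness`` defaults to
    ``cv``-fold cross-validated R² of ``kind`` on ``train``; pass a callable
    to optimize an arbitrary objective (e.g. a surrogate in tests).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space:
        raise ValueError("empty hyperparameter space")
    if method not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {method!r}; choose from {OPTIMIZERS}")
    if fitness is None:
        if kind is None or train is None:
            raise ValueError("need kind and train data for the default CV fitness")
        fitness = _cv_fitness(kind, train, seed, cv)
    rng = np.random.default_rng(seed)
    if method == "grid":
        trace = _grid(space, budget, fitness, rng, grid_points=grid_points)
    elif method == "random":
        trace = _random(space, budget, fitness, rng)
    elif method == "ACO":
        trace = _aco(space, budget, fitness, rng)
    elif method == "HHO":
        trace = _hho(space, budget, fitness, rng)
    else:
        trace = _bayes(space, budget, fitness, rng)
    best_config, best_score = max(trace, key=lambda t: t[1])
    return dict(best_config), float(best_score), trace
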