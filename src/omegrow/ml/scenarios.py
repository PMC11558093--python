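"""The scenario matrix and repeated train/test evaluation.

Per data view (transcription, translation): KNN is paired only with grid
and random search, while SVR, CNN and LSTM each run under all five
optimizers — 2 + 3×5 = 17 scenarios per view, 34 in total.  Scenario names
follow the optimizer-prefix convention (GSKNN, RSKNN, ACOSVR, BOLSTM, …).

``repeated_evaluation`` re-draws the 80/20 split ``n_repeats`` times with
consecutive seeds, trains, tests, and collects the metric distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import MLDataset, split_dataset
from .metrics import Metrics, compute_metrics
from .models import train_predict

logger = logging.getLogger(__name__)

__all__ = ["Scenario", "ScenarioResult", "enumerate_scenarios",
           "scenario_name", "repeated_evaluation"]

_OPT_PREFIX = {"grid": "GS", "random": "RS", "ACO": "ACO", "HHO": "HHO", "Bayes": "BO"}
_KNN_OPTIMIZERS = ("grid", "random")
_FULL_OPTIMIZERS = ("grid", "random", "ACO", "HHO", "Bayes")


@dataclass(frozen=True)
class Scenario:
    view: str
    kind: str
    optimizer: str

    @property
    def name(self) -> str:
        return scenario_name(self.kind, self.optimizer)


def scenario_name(kind: str, optimizer: str) -> str:
    return f"{_OPT_PREFIX[optimizer]}{kind}"


def enumerate_scenarios(views=("transcription", "translation")) -> list[Scenario]:
    """The full model-family × optimizer × view design."""
    scenarios = []
    for view in views:
        for opt in _KNN_OPTIMIZERS:
            scenarios.append(Scenario(view, "KNN", opt))
        for kind in ("SVR", "CNN", "LSTM"):
            for opt in _FULL_OPTIMIZERS:
                scenarios.append(Scenario(view, kind, opt))
    return scenarios


@dataclass
class ScenarioResult:
    scenario: Scenario
    config: dict
    n_repeats: int
    metrics: list[Metrics] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    n_failures: int = 0

    def summary(self) -> dict:
        out = {"scenario": self.scenario.name, "view": self.scenario.view,
               "n_repeats": self.n_repeats, "n_failures": self.n_failures}
        for key in ("r2", "rmse", "evs", "mae"):
            vals = np.array([getattr(m, key) for m in self.metrics])
            out[f"{key}_mean"] = float(np.mean(vals))
            out[f"{key}_sd"] = float(np.std(vals))
        return out

    def values(self, key: str) -> np.ndarray:
        return np.array([getattr(m, key) for m in self.metrics])


def repeated_evaluation(
    scenario: Scenario,
    ds: MLDataset,
    config: dict,
    n_repeats: int = 100,
    seed0: int = 0,
    train_frac: float = 0.8,
    max_failure_frac: float = 0.05,
) -> ScenarioResult:
    """Independent split/train/test cycles with seeds seed0..seed0+n−1.

    Individual repeat failures are logged, not fatal, up to
    ``max_failure_frac`` of the repeats.
    """
    result = ScenarioResult(scenario=scenario, config=dict(config),
                            n_repeats=n_repeats)
    for rep in range(n_repeats):
        seed = seed0 + rep
        try:
            train, test = split_dataset(ds, train_frac=train_frac, seed=seed)
            y_pred = train_predict(scenario.kind, config, train, test, seed=seed)
            result.metrics.append(compute_metrics(test.y.to_numpy(), y_pred))
            result.seeds.append(seed)
        except Exception as exc:
            result.n_failures += 1
            logger.warning("repeat %d (seed %d) failed: %s", rep, seed, exc)
            if result.n_failures > max(1, int(max_failure_frac * n_repeats)):
                raise RuntimeError(
                    f"too many repeat failures ({result.n_failures}/{n_repeats})"
                ) from exc
    return result
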