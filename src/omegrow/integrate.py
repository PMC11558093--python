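"""ME ↔ ML integration loop.

The ME model simulates expression/growth arrays (GE-MF) that extend the
experimental ML dataset; ML-predicted growth rates and expression targets
flow back into the ME model by rescaling per-gene transcription and
translation efficiencies (bounded multipliers), yielding the EM-updated
model; prediction accuracy is scored gene-by-gene on the normalized scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .me.analyses import predicted_expression
from .me.model import MEModel, MuExpr
from .me.solve import maximize_growth, solve_at_mu
from .ml.datasets import MLDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SimulatedArraySet",
    "AccuracyReport",
    "generate_gemf",
    "augment_dataset",
    "update_me_model",
    "score_expression_accuracy",
]


@dataclass
class SimulatedArraySet:
    """ME-simulated expression columns with their growth rates."""

    expression: pd.DataFrame  # genes × conditions, values in [0,1]
    mu: pd.Series  # growth rate per condition
    conditions: list[dict] = field(default_factory=list)
    origin: str = "simulated"

    def __post_init__(self):
        vals = self.expression.to_numpy()
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValueError("simulated expression outside [0,1]")


@dataclass
class AccuracyReport:
    n_correct: int
    n_total: int
    rule: str
    per_gene_abs_error: pd.Series = field(default_factory=pd.Series)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total

    def to_dict(self) -> dict:
        return {
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "accuracy": self.accuracy,
            "rule": self.rule,
        }


def generate_gemf(
    model: MEModel,
    conditions: list[dict],
    tol: float = 1e-6,
) -> SimulatedArraySet:
    """Simulate one expression column + growth rate per condition.

    A condition is ``{"name": ..., "exchange": rxn id, "uptake": bound}``
    (extra descriptor keys are carried through).  Infeasible conditions are
    skipped with a warning.
    """
    cols, mus, kept = {}, {}, []
    for i, cond in enumerate(conditions):
        name = cond.get("name", f"cond{i:03d}")
        bounds = {cond["exchange"]: (0.0, float(cond["uptake"]))}
        try:
            sol = maximize_growth(model, tol=tol, extra_bounds=bounds)
        except Exception as exc:
            warnings.warn(f"condition {name!r} not solvable ({exc}); skipped")
            continue
        if sol.status != "optimal":
            warnings.warn(f"condition {name!r} infeasible; skipped")
            continue
        cols[name] = predicted_expression(sol, model)
        mus[name] = sol.mu
        kept.append(dict(cond, name=name))
    expression = pd.DataFrame(cols)
    return SimulatedArraySet(expression, pd.Series(mus, name="mu"), kept)


def augment_dataset(
    experimental: MLDataset,
    sim: SimulatedArraySet,
    placement: str = "test_extension",
) -> tuple[MLDataset, pd.Index]:
    """Append simulated arrays to the experimental dataset.

    Features are intersected (logged); origin flags mark the provenance of
    every array.  ``placement`` is recorded by returning the index of the
    appended arrays — "test_extension" callers keep those arrays out of
    training splits, "train" callers may use them freely.
    """
    if placement not in ("test_extension", "train"):
        raise ValueError(f"unknown placement {placement!r}")
    if sim.expression.empty:
        return experimental, pd.Index([])
    sim_X = sim.expression.T  # conditions × genes
    shared = experimental.X.columns.intersection(sim_X.columns)
    if len(shared) == 0:
        raise ValueError("no shared features between experimental and simulated data")
    if len(shared) < experimental.n_features:
        logger.info(
            "feature intersection: %d of %d experimental features kept",
            len(shared), experimental.n_features,
        )
    X = pd.concat([experimental.X[shared], sim_X[shared]], axis=0)
    y = pd.concat([experimental.y, sim.mu])
    origin = pd.concat(
        [
            experimental.origin,
            pd.Series("simulated", index=sim_X.index),
        ]
    )
    return MLDataset(X, y, experimental.view, origin), sim_X.index


def update_me_model(
    model: MEModel,
    mu_pred: float,
    expression_targets: dict[str, float],
    bounds: tuple[float, float] = (0.2, 5.0),
    n_grid: int = 17,
) -> tuple[MEModel, dict[str, float]]:
    """EM update: rescale per-gene expression efficiency toward targets.

    For each targeted gene a bounded multiplier scales the mRNA requirement
    of translation (the gene's transcription demand per unit protein).  The
    multiplier is chosen, gene by gene on a log-spaced grid over ``bounds``,
    to minimize the squared deviation between the model's predicted
    expression and the target at growth fixed to ``mu_pred``; any update
    that breaks feasibility at ``mu_pred`` is reverted and logged.  Targets
    equal to current predictions yield multipliers of 1 (fixed point).
    """
    lo, hi = bounds
    if not 0 < lo <= 1 <= hi:
        raise ValueError("multiplier bounds must bracket 1")
    bad = {g: t for g, t in expression_targets.items() if not 0 <= t <= 1}
    if bad:
        raise ValueError(f"targets outside [0,1]: {bad}")
    base = maximize_growth(model)
    if mu_pred > base.mu + 1e-9:
        raise ValueError(
            f"mu_pred={mu_pred} exceeds the model's maximal growth {base.mu:.6f}"
        )
    sol = solve_at_mu(model, mu_pred, fixed_biomass=mu_pred)
    current = predicted_expression(sol, model)

    updated = model.copy()
    multipliers: dict[str, float] = {}
    grid = np.geomspace(lo, hi, n_grid)
    grid = np.sort(np.append(grid, 1.0))
    for gene in sorted(expression_targets):
        if gene not in updated.gene_mrna:
            logger.warning("gene %s not in model; skipped", gene)
            continue
        target = expression_targets[gene]
        if abs(current.get(gene, np.nan) - target) < 1e-9:
            multipliers[gene] = 1.0
            continue
        rxn = updated.reactions[f"translation_{gene}"]
        mrna = updated.gene_mrna[gene]
        base_expr = rxn.stoichiometry[mrna]
        best_m, best_err = 1.0, abs(current[gene] - target)
        for mcand in grid:
            rxn.stoichiometry[mrna] = base_expr.scaled(mcand)
            trial = solve_at_mu(updated, mu_pred, fixed_biomass=mu_pred)
            if trial.status != "optimal":
                continue
            expr = predicted_expression(trial, updated)
            err = abs(expr[gene] - target)
            if err < best_err - 1e-12:
                best_m, best_err = float(mcand), err
        rxn.stoichiometry[mrna] = base_expr.scaled(best_m)
        check = solve_at_mu(updated, mu_pred, fixed_biomass=mu_pred)
        if check.status != "optimal":
            logger.warning("gene %s: update infeasible; reverted", gene)
            rxn.stoichiometry[mrna] = base_expr
            best_m = 1.0
        multipliers[gene] = best_m
    return updated, multipliers


def score_expression_accuracy(
    predicted: dict[str, float] | pd.Series,
    reference: dict[str, float] | pd.Series,
    rule: str = "band",
    tol: float = 0.2,
) -> AccuracyReport:
    """Per-gene correctness of expression predictions on the [0,1] scale.

    rule "band": correct iff |pred − ref| ≤ tol.  rule "tertile": correct
    iff both values fall in the same tertile bin of [0,1].
    """
    pred = pd.Series(predicted, dtype=float)
    ref = pd.Series(reference, dtype=float)
    shared = pred.index.intersection(ref.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between predicted and reference")
    pred, ref = pred[shared], ref[shared]
    errors = (pred - ref).abs()
    if rule == "band":
        correct = errors <= tol
    elif rule == "tertile":
        bins = [0.0, 1.0 / 3.0, 2.0 / 3.0, np.inf]
        correct = pd.Series(
            np.digitize(pred, bins) == np.digitize(ref, bins), index=shared
        )
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return AccuracyReport(
        n_correct=int(correct.sum()),
        n_total=int(len(shared)),
        rule=rule,
        per_gene_abs_error=errors,
    )
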