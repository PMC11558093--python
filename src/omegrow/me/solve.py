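"""Growth solving: LP at fixed μ, bisection for the maximal growth rate.

At a fixed growth rate μ the ME model is an ordinary LP: coefficients are
evaluated at μ and the biomass-dilution flux v_bio is maximized subject to
steady-state mass balance S(μ)·v = 0 and flux bounds.  μ is feasible iff
max v_bio ≥ μ, and because every coupling coefficient grows with μ the
feasible growth set is a single interval [0, μ*]; bisection on that
feasibility predicate recovers μ* to a requested tolerance.

Solved in double precision with HiGHS through scipy, with tightened primal
feasibility so reported solutions satisfy ‖S(μ)v‖∞ < 1e−9 at toy scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MEModel

__all__ = ["MESolution", "solve_at_mu", "maximize_growth", "SolverError"]

_LP_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


class SolverError(RuntimeError):
    """LP solver failed for a reason other than plain infeasibility."""


@dataclass
class MESolution:
    mu: float
    status: str  # "optimal" or "infeasible"
    objective: float = float("nan")  # max attainable biomass flux at this mu
    fluxes: dict[str, float] = field(default_factory=dict)
    duals: dict[str, float] = field(default_factory=dict)  # metabolite duals
    #: shadow prices of exchange upper bounds (positive = growth-limiting)
    bound_duals: dict[str, float] = field(default_factory=dict)
    residual: float = float("nan")  # ||S(mu) v||_inf

    @property
    def feasible_at_mu(self) -> bool:
        return self.status == "optimal" and self.objective >= self.mu - 1e-9


def solve_at_mu(
    model: MEModel,
    mu: float,
    objective: str | None = None,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    sense: str = "max",
    fixed_biomass: float | None = None,
) -> MESolution:
    """Solve the LP with coefficients evaluated at ``mu``.

    By default maximizes the biomass-dilution flux.  ``objective`` may name
    any reaction; ``fixed_biomass`` pins v_bio (used by FVA and scans);
    ``extra_bounds`` overrides per-reaction bounds for this solve only.
    """
    if mu < 0:
        raise ValueError(f"mu must be non-negative, got {mu}")
    S, lb, ub, met_index, rxn_index = model.build_matrices(mu)
    lb, ub = lb.copy(), ub.copy()
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            j = rxn_index[rid]
            lb[j], ub[j] = lo, hi
    if fixed_biomass is not None:
        j = rxn_index[model.biomass_reaction]
        lb[j] = ub[j] = fixed_biomass
    obj_rxn = objective or model.biomass_reaction
    if obj_rxn is None:
        raise ValueError("model has no biomass reaction and no objective given")
    c = np.zeros(S.shape[1])
    c[rxn_index[obj_rxn]] = -1.0 if sense == "max" else 1.0

    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options=_LP_OPTIONS,
    )
    if res.status == 2:  # infeasible
        return MESolution(mu=mu, status="infeasible")
    if res.status != 0:
        raise SolverError(f"LP solver status {res.status} at mu={mu}: {res.message}")

    v = res.x
    sign = -1.0 if sense == "max" else 1.0
    fluxes = {rid: float(v[j]) for rid, j in rxn_index.items()}
    duals = {m: sign * float(res.eqlin.marginals[i]) for m, i in met_index.items()}
    bound_duals = {
        rid: sign * float(res.upper.marginals[j])
        for rid, j in rxn_index.items()
        if model.reactions[rid].kind == "exchange"
    }
    residual = float(np.max(np.abs(S @ v))) if v.size else 0.0
    return MESolution(
        mu=mu,
        status="optimal",
        objective=float(sign * res.fun),
        fluxes=fluxes,
        duals=duals,
        bound_duals=bound_duals,
        residual=residual,
    )


def maximize_growth(
    model: MEModel,
    tol: float = 1e-6,
    mu_max_bracket: float = 10.0,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> MESolution:
    """Largest self-consistent growth rate by bisection on LP feasibility.

    Returns the solution at μ* (feasible); μ*+tol is infeasible.  Raises if
    the model cannot even sustain μ=0, or if the bracket top is feasible
    (ask for a larger bracket).
    """

    def feasible(mu: float) -> MESolution:
        return solve_at_mu(model, mu, extra_bounds=extra_bounds)

    sol0 = feasible(0.0)
    if sol0.status != "optimal":
        raise SolverError("model infeasible at mu=0")
    hi_sol = feasible(mu_max_bracket)
    if hi_sol.feasible_at_mu:
        raise SolverError(
            f"growth still feasible at bracket top mu={mu_max_bracket}; "
            "increase mu_max_bracket"
        )
    lo, hi = 0.0, mu_max_bracket
    best = sol0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        sol = feasible(mid)
        if sol.feasible_at_mu:
            lo, best = mid, sol
        else:
            hi = mid
    return best
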