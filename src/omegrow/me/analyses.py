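"""Simulation analyses on a solved ME model.

Growth curves over substrate uptake, growth-regime classification
(strictly-nutrient-limited / Janusian / batch), RNA-to-protein mass ratio,
flux variability at fixed growth, metabolite-synthesis capability scans, and
per-gene predicted expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import MEModel, MEReaction, MuExpr
from .process_data import ComplexData, TranscriptionData
from .solve import MESolution, maximize_growth, solve_at_mu

__all__ = [
    "GrowthCurve",
    "growth_curve",
    "classify_regions",
    "rna_protein_ratio",
    "flux_variability",
    "metabolite_synthesis_scan",
    "predicted_expression",
    "knockout_gene",
]

#: average monomer masses, g/mmol
NT_MASS = 0.330
AA_MASS = 0.110
TRNA_LENGTH = 76  # nt, aggregate tRNA mass proxy


@dataclass
class GrowthCurve:
    substrate_exchange: str
    uptake: list[float]
    mu_star: list[float]
    solutions: list[MESolution] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    @property
    def shadow_prices(self) -> list[float]:
        return [s.bound_duals.get(self.substrate_exchange, 0.0) for s in self.solutions]


def growth_curve(
    model: MEModel,
    substrate_exchange: str,
    uptake_grid: list[float],
    tol: float = 1e-6,
    mu_max_bracket: float = 10.0,
) -> GrowthCurve:
    """Maximal growth rate as a function of the substrate uptake bound."""
    grid = list(uptake_grid)
    if grid != sorted(grid):
        raise ValueError("uptake grid must be sorted ascending")
    mu_star, sols = [], []
    for i, u in enumerate(grid):
        try:
            sol = maximize_growth(
                model, tol=tol, mu_max_bracket=mu_max_bracket,
                extra_bounds={substrate_exchange: (0.0, u)},
            )
        except Exception as exc:
            raise RuntimeError(f"growth solve failed at grid index {i} (u={u})") from exc
        mu_star.append(sol.mu)
        sols.append(sol)
    return GrowthCurve(substrate_exchange, grid, mu_star, sols)


def classify_regions(
    curve: GrowthCurve,
    eps: float = 1e-6,
    slope_tol: float = 0.05,
) -> GrowthCurve:
    """Label curve points SNL / Janusian / batch.

    SNL: substrate shadow price > eps and local slope within ``slope_tol``
    of the initial slope.  Batch: shadow price < eps.  Janusian: between.
    Labels are forced into at most three contiguous blocks in that order.
    """
    n = len(curve.uptake)
    if n < 5:
        raise ValueError("need at least 5 grid points to classify regions")
    mu = np.asarray(curve.mu_star)
    if np.any(np.diff(mu) < -1e-6):
        raise ValueError("growth curve is not non-decreasing (upstream bug)")
    duals = np.asarray(curve.shadow_prices)
    du = np.diff(np.asarray(curve.uptake, dtype=float))
    slopes = np.diff(mu) / du
    slope0 = slopes[0]

    batch_start = n
    for i in range(n):
        if duals[i] < eps:
            batch_start = i
            break
    snl_end = -1
    for i in range(min(batch_start, n)):
        local = slopes[min(i, len(slopes) - 1)]
        if slope0 > 0 and abs(local - slope0) <= slope_tol * abs(slope0):
            snl_end = i
        else:
            break
    labels = (
        ["SNL"] * (snl_end + 1)
        + ["Janusian"] * (batch_start - snl_end - 1)
        + ["batch"] * (n - batch_start)
    )
    curve.labels = labels
    return curve


def _production_flux(model: MEModel, solution: MESolution, met_id: str,
                     exclude_kinds: tuple = ("dilution", "generic_formation")) -> float:
    total = 0.0
    for rid, rxn in model.reactions.items():
        if rxn.kind in exclude_kinds or met_id not in rxn.stoichiometry:
            continue
        coef = rxn.coefficient(met_id, solution.mu)
        if coef > 0:
            total += coef * solution.fluxes[rid]
    return total


def rna_protein_ratio(solution: MESolution, model: MEModel) -> float:
    """Steady-state RNA-to-protein mass ratio (g RNA / g protein).

    Macromolecule amounts follow from the dilution balance: everything
    translated dilutes at μ, so total protein amount is Σ v_transl/μ per
    gene; mRNA turns over at μ + k_deg; stable RNA (rRNA) dilutes at μ;
    aggregate tRNA is a turnover proxy (charging flux · L / (k_trna·3600)).
    """
    if solution.status != "optimal":
        raise ValueError("solution is not optimal")
    mu = solution.mu
    if mu <= 0:
        raise ValueError("RNA/protein ratio undefined at mu=0")
    k_deg = model.params.k_deg_mrna

    protein_mass = 0.0
    for rid, rxn in model.reactions.items():
        if rxn.kind != "translation":
            continue
        prot = model.gene_protein[rxn.gene_id]
        L_aa = model.metabolites[prot].length
        protein_mass += solution.fluxes[rid] / mu * L_aa * AA_MASS
    if protein_mass <= 0:
        raise ValueError("zero protein mass in solution")

    rna_mass = 0.0
    for met_id, met in model.metabolites.items():
        if met.met_class == "mrna":
            prod = _production_flux(model, solution, met_id)
            rna_mass += prod / (mu + k_deg) * met.length * NT_MASS
        elif met.met_class == "rrna":
            prod = _production_flux(model, solution, met_id)
            rna_mass += prod / mu * met.length * NT_MASS
        elif met.met_class == "trna":
            prod = _production_flux(model, solution, met_id)
            rna_mass += prod * TRNA_LENGTH / (model.params.k_trna * 3600.0) * NT_MASS
    return rna_mass / protein_mass


def flux_variability(
    model: MEModel,
    reaction: str,
    mu_fraction: float = 1.0,
    mu_star: float | None = None,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Min and max flux of ``reaction`` with growth fixed at mu_fraction·μ*."""
    if reaction not in model.reactions:
        raise KeyError(f"unknown reaction {reaction!r}")
    if mu_star is None:
        mu_star = maximize_growth(model, tol=tol, extra_bounds=extra_bounds).mu
    mu = mu_fraction * mu_star
    lo = solve_at_mu(model, mu, objective=reaction, sense="min",
                     fixed_biomass=mu, extra_bounds=extra_bounds)
    hi = solve_at_mu(model, mu, objective=reaction, sense="max",
                     fixed_biomass=mu, extra_bounds=extra_bounds)
    if lo.status != "optimal" or hi.status != "optimal":
        raise RuntimeError(f"FVA infeasible at mu={mu} (fraction {mu_fraction})")
    return lo.objective, hi.objective


def metabolite_synthesis_scan(
    model: MEModel,
    metabolite: str,
    substrate_exchange: str,
    glucose_grid: list[float],
    mu_fraction: float = 0.5,
    tol: float = 1e-6,
) -> list[float]:
    """Maximal synthesis (demand) rate of a metabolite along a substrate grid,
    while growth is held at ``mu_fraction`` of the point's maximum."""
    if metabolite not in model.metabolites:
        warnings.warn(f"metabolite {metabolite!r} not in model; zero curve")
        return [0.0] * len(glucose_grid)
    work = model.copy()
    demand_id = f"DM_{metabolite}"
    if demand_id not in work.reactions:
        work.add_reaction(
            MEReaction(demand_id, {metabolite: MuExpr(const=-1.0)}, kind="demand")
        )
    rates = []
    for u in glucose_grid:
        bounds = {substrate_exchange: (0.0, u)}
        if u == 0.0:
            rates.append(0.0)
            continue
        mu_star = maximize_growth(work, tol=tol, extra_bounds=bounds).mu
        mu = mu_fraction * mu_star
        sol = solve_at_mu(work, mu, objective=demand_id, sense="max",
                          fixed_biomass=mu, extra_bounds=bounds)
        if sol.status != "optimal":
            warnings.warn(f"synthesis scan infeasible at u={u}; rate 0")
            rates.append(0.0)
        else:
            rates.append(max(sol.objective, 0.0))
    return rates


def predicted_expression(solution: MESolution, model: MEModel) -> dict[str, float]:
    """Per-gene expression prediction in [0,1].

    The raw signal is the gene's transcription flux (shared for genes on one
    transcription unit); values are min–max rescaled across genes with the
    compendium convention (a constant vector maps to 0).
    """
    from ..compendium import minmax_rescale_vector

    genes = model.genes
    raw = np.array(
        [solution.fluxes[model.gene_transcription[g]] for g in genes]
    )
    scaled = minmax_rescale_vector(raw)
    return dict(zip(genes, scaled))


def knockout_gene(model: MEModel, gene_id: str) -> MEModel:
    """Return a copy with a gene's translation disabled."""
    if gene_id not in model.gene_protein:
        raise KeyError(f"gene {gene_id!r} has no translation reaction")
    out = model.copy()
    out.reactions[f"translation_{gene_id}"].upper_bound = 0.0
    return out
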