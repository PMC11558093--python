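"""Growth solving and the simulation analyses on the toy organism."""

import numpy as np
import pytest

from omegrow.me import (
    ComplexData,
    MEParams,
    OrganismSpec,
    ProcessDataSet,
    StoichiometricData,
    build_me_model,
    classify_regions,
    flux_variability,
    growth_curve,
    knockout_gene,
    maximize_growth,
    metabolite_synthesis_scan,
    predicted_expression,
    rna_protein_ratio,
    solve_at_mu,
)
from omegrow.me.organism import GeneRecord
from omegrow.synthdata import make_toy_organism


class TestSolveAtMu:
    def test_mu_zero_feasible(self, toy_model):
        sol = solve_at_mu(toy_model, 0.0)
        assert sol.status == "optimal"

    def test_far_mu_infeasible_for_growth(self, toy_model):
        sol = solve_at_mu(toy_model, 50.0)
        assert not sol.feasible_at_mu

    def test_mass_balance_residual(self, toy_model):
        sol = solve_at_mu(toy_model, 0.5)
        assert sol.residual < 1e-9
        # recompute independently
        S, *_ , rxn_index = toy_model.build_matrices(0.5)
        v = np.array([sol.fluxes[r] for r in toy_model.reaction_ids])
        assert np.max(np.abs(S @ v)) < 1e-9


class TestMaximizeGrowth:
    def test_yield_limited_growth_matches_oracle(self, toy_organism):
        """With machinery non-binding, μ* = Y·u within tolerance."""
        org, pds, kcat = toy_organism
        model = build_me_model(org, pds, kcat)
        u = 1.0
        sol = maximize_growth(model, mu_max_bracket=5.0,
                              extra_bounds={"EX_glc": (0.0, u)})
        assert sol.mu == pytest.approx(org.yield_oracle * u, rel=0.02)

    def test_no_carbon_no_growth(self, toy_model):
        sol = maximize_growth(toy_model, mu_max_bracket=5.0,
                              extra_bounds={"EX_glc": (0.0, 0.0)})
        assert sol.mu == 0.0

    def test_tolerance_contract(self, toy_model):
        mu_coarse = maximize_growth(toy_model, tol=1e-4, mu_max_bracket=5.0).mu
        mu_fine = maximize_growth(toy_model, tol=1e-6, mu_max_bracket=5.0).mu
        assert abs(mu_coarse - mu_fine) < 1e-4

    def test_feasible_bracket_top_raises(self, toy_model):
        with pytest.raises(Exception, match="bracket"):
            maximize_growth(toy_model, mu_max_bracket=0.05)

    def test_bisection_matches_dense_sweep_oracle(self, toy_model):
        """μ* agrees with a brute-force dense feasibility sweep."""
        mu_star = maximize_growth(toy_model, tol=1e-6, mu_max_bracket=5.0).mu
        grid = np.arange(0.0, 2.0, 1e-4)
        feasible = [mu for mu in grid
                    if solve_at_mu(toy_model, mu).feasible_at_mu]
        assert abs(mu_star - max(feasible)) <= 1e-4

    def test_feasibility_monotone_in_mu(self):
        """Random toy variants: feasible at μ ⇒ feasible below μ."""
        for seed in (0, 1, 2):
            org, pds, kcat = make_toy_organism(seed=seed)
            model = build_me_model(org, pds, kcat)
            mu_star = maximize_growth(model, mu_max_bracket=5.0).mu
            for frac in (0.25, 0.5, 0.75, 0.999):
                assert solve_at_mu(model, frac * mu_star).feasible_at_mu

    def test_mu_star_decreases_with_slower_machinery(self, toy_organism):
        org, pds, kcat = toy_organism
        base = maximize_growth(build_me_model(org, pds, kcat),
                               mu_max_bracket=5.0).mu
        slow_ribo = build_me_model(org, pds, kcat,
                                   params=MEParams(k_ribo=12.0 / 4))
        assert maximize_growth(slow_ribo, mu_max_bracket=5.0).mu < base
        slow_kcat = build_me_model(
            org, pds, {k: v / 1000 for k, v in kcat.items()},
            params=MEParams(default_kcat=65.0 / 1000))
        assert maximize_growth(slow_kcat, mu_max_bracket=5.0).mu < base


class TestGrowthCurve:
    def test_zero_uptake_zero_growth(self, toy_growth_curve):
        assert toy_growth_curve.mu_star[0] == 0.0

    def test_monotone_non_decreasing(self, toy_growth_curve):
        mu = toy_growth_curve.mu_star
        assert all(b >= a - 1e-9 for a, b in zip(mu, mu[1:]))

    def test_snl_slope_matches_yield_oracle(self, toy_organism, toy_growth_curve):
        org, _, _ = toy_organism
        c = toy_growth_curve
        slope = (c.mu_star[2] - c.mu_star[1]) / (c.uptake[2] - c.uptake[1])
        assert slope == pytest.approx(org.yield_oracle, rel=0.02)

    def test_plateau_equals_unbounded_solve(self, toy_model, toy_growth_curve):
        unbounded = maximize_growth(toy_model, mu_max_bracket=5.0).mu
        assert toy_growth_curve.mu_star[-1] == pytest.approx(unbounded, abs=1e-5)

    def test_unsorted_grid_rejected(self, toy_model):
        with pytest.raises(ValueError, match="sorted"):
            growth_curve(toy_model, "EX_glc", [1.0, 0.5])


class TestRegions:
    def test_three_regions_with_ceiling(self, toy_growth_curve):
        labels = toy_growth_curve.labels
        assert set(labels) == {"SNL", "Janusian", "batch"}
        # contiguous blocks in order
        order = [labels[0]]
        for lab in labels[1:]:
            if lab != order[-1]:
                order.append(lab)
        assert order == ["SNL", "Janusian", "batch"]

    def test_shadow_price_signs(self, toy_growth_curve):
        for lab, sp in zip(toy_growth_curve.labels,
                           toy_growth_curve.shadow_prices):
            if lab == "batch":
                assert sp < 1e-6
            elif lab == "SNL":
                assert sp > 1e-6

    def test_no_batch_without_ceiling(self, toy_model_no_ceiling):
        grid = [0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0]
        curve = classify_regions(
            growth_curve(toy_model_no_ceiling, "EX_glc", grid,
                         mu_max_bracket=10.0))
        assert "batch" not in curve.labels

    def test_huge_eps_everything_batch(self, toy_growth_curve):
        import copy

        curve = classify_regions(copy.deepcopy(toy_growth_curve), eps=1e9)
        assert set(curve.labels) == {"batch"}


class TestRnaProteinRatio:
    def test_increases_with_growth_rate(self, toy_model):
        bounds = {"EX_glc": (0.0, 4.0)}
        lo = rna_protein_ratio(
            solve_at_mu(toy_model, 0.2, fixed_biomass=0.2, extra_bounds=bounds),
            toy_model)
        hi = rna_protein_ratio(
            solve_at_mu(toy_model, 0.6, fixed_biomass=0.6, extra_bounds=bounds),
            toy_model)
        assert hi > lo

    def test_strictly_increasing_across_snl(self, toy_model, toy_growth_curve):
        ratios = []
        for u, mu, lab in zip(toy_growth_curve.uptake, toy_growth_curve.mu_star,
                              toy_growth_curve.labels):
            if lab != "SNL" or mu <= 0:
                continue
            sol = solve_at_mu(toy_model, mu, fixed_biomass=mu,
                              extra_bounds={"EX_glc": (0.0, u)})
            ratios.append(rna_protein_ratio(sol, toy_model))
        assert len(ratios) >= 3
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_faster_ribosome_lowers_ratio(self, toy_organism):
        org, pds, kcat = toy_organism
        fast = build_me_model(org, pds, kcat, params=MEParams(k_ribo=24.0))
        slow = build_me_model(org, pds, kcat)
        bounds = {"EX_glc": (0.0, 4.0)}
        r_fast = rna_protein_ratio(
            solve_at_mu(fast, 0.5, fixed_biomass=0.5, extra_bounds=bounds), fast)
        r_slow = rna_protein_ratio(
            solve_at_mu(slow, 0.5, fixed_biomass=0.5, extra_bounds=bounds), slow)
        assert r_fast < r_slow

    def test_low_mu_limit_matches_symbolic_floor(self, toy_model):
        """The μ→0 ratio floor, derived by hand from the coupling algebra.

        Per unit translation flux v: the mRNA amount settles at the
        degradation-dominated value v·L_aa/(k_ribo·3600) (TU-shared flux =
        the max member requirement); the ribosome amount — hence rRNA mass —
        is usage/μ = Σ v·L_aa/(k_ribo·3600), which stays proportional to
        the translation demand; the aggregate tRNA proxy adds its turnover
        term.  Protein amount is Σ v·L_aa/μ.
        """
        from collections import defaultdict

        from omegrow.me.analyses import AA_MASS, NT_MASS, TRNA_LENGTH

        mu = 1e-3
        sol = solve_at_mu(toy_model, mu, fixed_biomass=mu,
                          extra_bounds={"EX_glc": (0.0, 4.0)})
        p = toy_model.params
        k_tl = p.k_ribo * 3600.0
        protein_expected = 0.0
        tu_need = defaultdict(list)
        ribosome_amount = 0.0
        for rid, rxn in toy_model.reactions.items():
            if rxn.kind != "translation":
                continue
            v = sol.fluxes[rid]
            g = rxn.gene_id
            L_aa = toy_model.metabolites[toy_model.gene_protein[g]].length
            protein_expected += v / mu * L_aa * AA_MASS
            tu_need[toy_model.gene_transcription[g]].append((g, v * L_aa / k_tl))
            ribosome_amount += v * L_aa / k_tl
        rna_expected = 0.0
        for tu, needs in tu_need.items():
            shared_amt = max(a for _, a in needs)
            for g, _ in needs:
                L_nt = toy_model.metabolites[toy_model.gene_mrna[g]].length
                rna_expected += shared_amt * L_nt * NT_MASS
        L_rrna = toy_model.metabolites["rrna_g_rrna"].length
        rna_expected += ribosome_amount * L_rrna * NT_MASS
        for rid, rxn in toy_model.reactions.items():
            for met, expr in rxn.stoichiometry.items():
                if (toy_model.metabolites[met].met_class == "trna"
                        and expr(mu) > 0):
                    rna_expected += (expr(mu) * sol.fluxes[rid] * TRNA_LENGTH
                                     / (p.k_trna * 3600.0) * NT_MASS)
        ratio = rna_protein_ratio(sol, toy_model)
        assert ratio == pytest.approx(rna_expected / protein_expected, rel=0.05)


def _mini_parallel_model(cap: float | None):
    """A hand-checkable metabolic-only model: uptake → A → B → biomass,
    with an optional second A→B route capped at ``cap``."""
    pds = ProcessDataSet()
    pds.add(StoichiometricData("R_main", stoichiometry={"A": -1.0, "B": 1.0},
                               spontaneous=True))
    if cap is not None:
        pds.add(StoichiometricData("R_alt", stoichiometry={"A": -1.0, "B": 1.0},
                                   spontaneous=True, upper_bound=cap))
    org = OrganismSpec(
        id="mini", genes=[], sequences={},
        biomass={"B": 1.0},
        exchanges={"EX_A": ("A", 0.0, 5.0)},
    )
    return build_me_model(org, pds)


class TestFluxVariability:
    def test_unique_pathway_min_equals_max(self, ):
        model = _mini_parallel_model(cap=None)
        lo, hi = flux_variability(model, "R_main", mu_fraction=1.0)
        assert hi - lo < 1e-8

    def test_parallel_capacity_sets_range(self):
        cap = 2.0
        model = _mini_parallel_model(cap=cap)
        # at full growth demand 10, R_alt ∈ [0, cap] so R_main spans cap
        lo, hi = flux_variability(model, "R_main", mu_fraction=1.0)
        assert hi - lo == pytest.approx(cap, abs=1e-6)

    def test_bounds_bracket_fba_flux(self, toy_model):
        sol = maximize_growth(toy_model, mu_max_bracket=5.0,
                              extra_bounds={"EX_glc": (0.0, 4.0)})
        for rid in ("GLYC_EFF", "GLYC_INEFF", "RESP"):
            lo, hi = flux_variability(toy_model, rid, mu_fraction=1.0,
                                      mu_star=sol.mu,
                                      extra_bounds={"EX_glc": (0.0, 4.0)})
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_relaxed_growth_widens_range(self, toy_model):
        bounds = {"EX_glc": (0.0, 4.0)}
        mu_star = maximize_growth(toy_model, mu_max_bracket=5.0,
                                  extra_bounds=bounds).mu
        lo1, hi1 = flux_variability(toy_model, "RESP", mu_fraction=1.0,
                                    mu_star=mu_star, extra_bounds=bounds)
        lo0, hi0 = flux_variability(toy_model, "RESP", mu_fraction=0.0,
                                    mu_star=mu_star, extra_bounds=bounds)
        assert hi0 - lo0 >= hi1 - lo1 - 1e-9


class TestSynthesisScan:
    def test_zero_glucose_zero_rate(self, toy_model):
        rates = metabolite_synthesis_scan(toy_model, "prec", "EX_glc", [0.0])
        assert rates == [0.0]

    def test_rate_non_decreasing(self, toy_model):
        rates = metabolite_synthesis_scan(
            toy_model, "prec", "EX_glc", [0.0, 1.0, 2.0, 4.0])
        assert all(b >= a - 1e-6 for a, b in zip(rates, rates[1:]))

    def test_full_growth_fraction_leaves_little_slack(self, toy_model):
        lo_frac = metabolite_synthesis_scan(
            toy_model, "prec", "EX_glc", [2.0], mu_fraction=0.5)[0]
        hi_frac = metabolite_synthesis_scan(
            toy_model, "prec", "EX_glc", [2.0], mu_fraction=1.0)[0]
        assert hi_frac < 0.05 * max(lo_frac, 1.0)

    def test_unknown_metabolite_warns_zero_curve(self, toy_model):
        with pytest.warns(UserWarning, match="not in model"):
            rates = metabolite_synthesis_scan(
                toy_model, "nonexistent", "EX_glc", [1.0, 2.0])
        assert rates == [0.0, 0.0]


class TestPredictedExpression:
    def test_vector_shape_and_range(self, toy_model):
        sol = maximize_growth(toy_model, mu_max_bracket=5.0,
                              extra_bounds={"EX_glc": (0.0, 4.0)})
        expr = predicted_expression(sol, toy_model)
        assert set(expr) == set(toy_model.genes)
        vals = np.array(list(expr.values()))
        assert vals.min() >= 0 and vals.max() <= 1

    def test_knockout_drives_expression_to_minimum(self, toy_model):
        """In SNL, E1 (the uncapped route) is expressed; knocking it out
        forces flux through the capped route and zeroes E1's expression."""
        bounds = {"EX_glc": (0.0, 4.0)}  # Janusian: both routes active
        sol = maximize_growth(toy_model, mu_max_bracket=5.0,
                              extra_bounds=bounds)
        expr = predicted_expression(sol, toy_model)
        assert expr["g_E1"] > 0
        ko = knockout_gene(toy_model, "g_E1")
        sol_ko = maximize_growth(ko, mu_max_bracket=5.0, extra_bounds=bounds)
        expr_ko = predicted_expression(sol_ko, ko)
        assert expr_ko["g_E1"] == pytest.approx(0.0, abs=1e-9)
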