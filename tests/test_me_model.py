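"""ME model construction: expression stoichiometry, builder, kcats, JSON."""

import numpy as np
import pytest

from omegrow.me import (
    MEParams,
    MuExpr,
    TranscriptionData,
    TranslationData,
    build_me_model,
    expression_stoichiometry,
    integrate_kcats,
    model_from_dict,
    model_to_dict,
    read_model_json,
    write_model_json,
)
from omegrow.me.serialize import SchemaError


class TestExpressionStoichiometry:
    def test_transcription_base_counting(self):
        tx = TranscriptionData("TU1", sequence="ATGC", rna_products=["mrna_g"])
        stoich = expression_stoichiometry(tx, {})
        assert stoich["ntp_A"](0) == -1
        assert stoich["ntp_U"](0) == -1  # T read as U
        assert stoich["ntp_G"](0) == -1
        assert stoich["ntp_C"](0) == -1
        assert stoich["ppi"](0) == 4
        assert stoich["mrna_g"](0) == 1

    def test_translation_counts_and_gtp_cost(self):
        tl = TranslationData("TL1", gene_id="g", sequence="ATGAAA",
                             mrna_id="mrna_g", protein_id="p_g")
        trna = {"M": "trna_M", "K": "trna_K"}
        stoich = expression_stoichiometry(tl, trna)
        assert stoich["trna_M"](0) == -1
        assert stoich["trna_K"](0) == -1
        # 2 GTP-equivalents per amino acid (bond + initiation aggregate)
        assert stoich["atp"](0) == -4
        assert stoich["p_g"](0) == 1

    def test_mrna_coupling_is_affine_with_decay_floor(self):
        tl = TranslationData("TL1", gene_id="g", sequence="ATGAAA",
                             mrna_id="mrna_g", protein_id="p_g")
        params = MEParams()
        stoich = expression_stoichiometry(tl, {"M": "t", "K": "t2"}, params)
        coef = 2 / (params.k_ribo * 3600.0)
        assert stoich["mrna_g"](0) == pytest.approx(-params.k_deg_mrna * coef)
        assert stoich["mrna_g"](1.0) == pytest.approx(
            -(params.k_deg_mrna + 1.0) * coef)

    def test_unknown_trna_names_position(self):
        tl = TranslationData("TL1", gene_id="g", sequence="ATGAAA",
                             mrna_id="m", protein_id="p")
        with pytest.raises(ValueError, match="position"):
            expression_stoichiometry(tl, {"M": "trna_M"})  # K missing

    def test_internal_stop_names_position(self):
        tl = TranslationData("TL1", gene_id="g", sequence="ATGTAAAAA",
                             mrna_id="m", protein_id="p")
        with pytest.raises(ValueError, match="position 4"):
            expression_stoichiometry(tl, {"M": "t", "K": "t"})

    def test_empty_product_rejected(self):
        tx = TranscriptionData("TU1", sequence="ATGC", rna_products=[])
        with pytest.raises(ValueError, match="product"):
            expression_stoichiometry(tx, {})


class TestBuilder:
    def test_toy_model_reaction_inventory(self, toy_organism, toy_model):
        org, pds, _ = toy_organism
        # per coding gene: transcription (via TU), translation, dilutions
        for gene in ("g_E1", "g_dummy"):
            assert f"translation_{gene}" in toy_model.reactions
            assert toy_model.gene_transcription[gene] in toy_model.reactions
            prot = toy_model.gene_protein[gene]
            assert f"dilution_{prot}" in toy_model.reactions
            assert f"dilution_{toy_model.gene_mrna[gene]}" in toy_model.reactions
        assert "biomass_dilution" in toy_model.reactions
        assert "EX_glc" in toy_model.reactions
        # at least exchange + catalysis + transcription + translation + 2 dilutions
        assert len(toy_model.reactions) >= 6

    def test_default_kcat_applied_and_logged(self, toy_organism):
        org, pds, _ = toy_organism
        model = build_me_model(org, pds, kcat_table={})
        assert all(v == "default" for v in model.kcat_sources.values())
        assert any("default kcat" in n for n in model.notes)
        rxn = model.reactions["GLYC_INEFF"]
        expected = -1.0 / (model.params.default_kcat * 3600.0)
        assert rxn.stoichiometry[rxn.enzyme].lin == pytest.approx(expected)

    def test_machinery_coefficients_vanish_at_mu_zero(self, toy_model):
        rxn = toy_model.reactions["translation_g_dummy"]
        assert rxn.stoichiometry["ribosome"](0.0) == 0.0
        tx = toy_model.reactions[toy_model.gene_transcription["g_dummy"]]
        assert tx.stoichiometry["generic_rnap"](0.0) == 0.0
        # degradation floor persists at mu=0
        mrna = toy_model.gene_mrna["g_dummy"]
        assert rxn.stoichiometry[mrna](0.0) < 0

    def test_operon_tu_produces_both_mrnas(self, toy_model):
        rxn = toy_model.reactions["transcription_TU_E23"]
        assert rxn.stoichiometry["mrna_g_E2"](0) == 1
        assert rxn.stoichiometry["mrna_g_E3"](0) == 1


class TestIntegrateKcats:
    def test_empty_table_all_defaults(self, toy_organism):
        org, pds, _ = toy_organism
        model = build_me_model(org, pds, {})
        model2, report = integrate_kcats(model, {})
        assert report["coverage"] == 0.0
        assert report["n_provided"] == 0

    def test_full_coverage(self, toy_organism):
        org, pds, _ = toy_organism
        model = build_me_model(org, pds, {})
        table = {r.id: 50.0 for r in model.reactions.values()
                 if r.enzyme is not None}
        model2, report = integrate_kcats(model, table)
        assert report["coverage"] == 1.0

    def test_doubling_kcat_halves_coupling(self, toy_organism):
        org, pds, _ = toy_organism
        model = build_me_model(org, pds, {"GLYC_INEFF": 40.0})
        model2, _ = integrate_kcats(model, {"GLYC_INEFF": 80.0})
        mu = 0.7
        rxn1 = model.reactions["GLYC_INEFF"]
        rxn2 = model2.reactions["GLYC_INEFF"]
        c1 = rxn1.stoichiometry[rxn1.enzyme](mu)
        c2 = rxn2.stoichiometry[rxn2.enzyme](mu)
        assert c2 == pytest.approx(c1 / 2)

    def test_nonpositive_kcat_rejected(self, toy_model):
        with pytest.raises(ValueError, match="kcat"):
            integrate_kcats(toy_model, {"GLYC_INEFF": -1.0})


class TestSerialization:
    def test_round_trip_deep_equality(self, toy_model, tmp_path):
        path = tmp_path / "model.json"
        write_model_json(toy_model, path)
        model2 = read_model_json(path)
        assert model_to_dict(toy_model) == model_to_dict(model2)
        # bit-exact re-serialization
        path2 = tmp_path / "model2.json"
        write_model_json(model2, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_bad_coefficient_names_path(self, toy_model):
        d = model_to_dict(toy_model)
        rid = d["reactions"][3]["id"]
        met = next(iter(d["reactions"][3]["stoichiometry"]))
        d["reactions"][3]["stoichiometry"][met] = [1.0, "oops"]
        with pytest.raises(SchemaError, match=rf"reactions\[3\].stoichiometry.{met}"):
            model_from_dict(d)

    def test_schema_version_checked(self, toy_model):
        d = model_to_dict(toy_model)
        d["schema_version"] = 99
        with pytest.raises(SchemaError, match="version"):
            model_from_dict(d)

    def test_round_trip_preserves_mu_star(self, toy_model, tmp_path):
        from omegrow.me import maximize_growth

        path = tmp_path / "model.json"
        write_model_json(toy_model, path)
        model2 = read_model_json(path)
        mu1 = maximize_growth(toy_model, mu_max_bracket=5.0).mu
        mu2 = maximize_growth(model2, mu_max_bracket=5.0).mu
        assert mu1 == mu2


class TestMuExpr:
    def test_affine_rational_evaluation(self):
        e = MuExpr(const=1.0, lin=2.0, rat=0.5)
        assert e(0.0) == 1.0
        assert e(2.0) == pytest.approx((1 + 4) / (1 + 1))

    def test_negative_mu_rejected(self):
        with pytest.raises(ValueError):
            MuExpr(1.0)(-0.1)


def test_fba_optimum_matches_cobra_oracle(toy_model):
    """Cross-check: the μ-evaluated LP agrees with an independent FBA solver.

    The ME matrices at a fixed growth rate form an ordinary stoichiometric
    model; rebuilding them in cobrapy and maximizing the biomass flux must
    give the same optimum as the package's own LP path.
    """
    cobra = pytest.importorskip("cobra")
    from omegrow.me import solve_at_mu

    mu = 0.4
    sol = solve_at_mu(toy_model, mu)
    S, lb, ub, met_index, rxn_index = toy_model.build_matrices(mu)
    cm = cobra.Model("oracle")
    mets = {m: cobra.Metabolite(m) for m in met_index}
    rxns = []
    for rid, j in sorted(rxn_index.items(), key=lambda kv: kv[1]):
        r = cobra.Reaction(rid)
        r.lower_bound, r.upper_bound = lb[j], ub[j]
        rxns.append(r)
    cm.add_reactions(rxns)
    for rid, j in rxn_index.items():
        stoich = {mets[m]: S[i, j] for m, i in met_index.items() if S[i, j] != 0}
        cm.reactions.get_by_id(rid).add_metabolites(stoich)
    cm.objective = "biomass_dilution"
    csol = cm.optimize()
    assert csol.status == "optimal"
    assert csol.objective_value == pytest.approx(sol.objective, rel=1e-5)
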