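"""ME-model construction: expression stoichiometry and full assembly.

The coupling algebra follows the COBRAme convention.  With k_eff = k_cat·3600
(1/h), L_aa the protein length and L_nt the transcript length:

* a catalyzed metabolic reaction consumes its enzyme complex at μ/k_eff;
* translation consumes ribosome at μ·L_aa/(k_ribo·3600);
* transcription consumes RNA polymerase at μ·L_nt/(k_rnap·3600);
* translation consumes its mRNA at (μ + k_deg_mrna)·L_aa/(k_ribo·3600),
  i.e. the ribosome coupling with growth dilution replaced by growth
  dilution plus first-order decay;
* every macromolecule has a free dilution reaction so its balance closes.

Polymerization costs are counted exactly from sequence composition: NTPs by
base counts (T read as U), one pyrophosphate per nucleotide incorporated,
one charged tRNA per codon and ``gtp_per_aa`` GTP-equivalents per amino acid
(the per-bond cost plus initiation/termination, aggregated).
"""

from __future__ import annotations

from collections import Counter

from Bio.Data import CodonTable

from .model import MEModel, MEParams, MEReaction, Metabolite, MuExpr
from .organism import OrganismSpec
from .process_data import (
    ComplexData,
    GenericData,
    PostTranslationData,
    ProcessDataSet,
    StoichiometricData,
    SubreactionData,
    TranscriptionData,
    TranslationData,
    TRNAData,
)

__all__ = ["expression_stoichiometry", "build_me_model", "integrate_kcats", "translate_cds"]

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]  # bacterial

#: metabolite ids used for polymerization substrates
NTP_IDS = {"A": "ntp_A", "T": "ntp_U", "G": "ntp_G", "C": "ntp_C"}
PPI_ID = "ppi"
GTP_EQUIV_ID = "atp"  # GTP-equivalents drawn from the energy pool


def translate_cds(sequence: str) -> list[str]:
    """Translate a coding DNA sequence to amino acids, naming bad positions.

    A single trailing stop codon is allowed and dropped; internal stops and
    unknown codons raise with the 1-based nucleotide position.
    """
    seq = sequence.upper()
    aas: list[str] = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in _CODON_TABLE.stop_codons:
            if i == n_codons - 1:
                break
            raise ValueError(
                f"internal stop codon {codon!r} at nucleotide position {3 * i + 1}"
            )
        try:
            aas.append(_CODON_TABLE.forward_table[codon])
        except KeyError:
            raise ValueError(
                f"invalid codon {codon!r} at nucleotide position {3 * i + 1}"
            ) from None
    return aas


def _transcript_base_counts(sequence: str) -> Counter:
    counts = Counter(sequence.upper())
    bad = set(counts) - set(NTP_IDS)
    if bad:
        raise ValueError(f"invalid bases in transcript: {sorted(bad)}")
    return counts


def expression_stoichiometry(
    data: TranscriptionData | TranslationData,
    trna_set: dict[str, str],
    params: MEParams | None = None,
) -> dict[str, MuExpr]:
    """Stoichiometry of one transcription or translation reaction.

    ``trna_set`` maps one-letter amino acid codes to charged-tRNA metabolite
    ids (only consulted for translation).  Machinery coupling (RNAP,
    ribosome, mRNA) is included; negative = consumed.
    """
    params = params or MEParams()
    stoich: dict[str, MuExpr] = {}
    if isinstance(data, TranscriptionData):
        data.validate()
        counts = _transcript_base_counts(data.sequence)
        L_nt = len(data.sequence)
        for base, n in sorted(counts.items()):
            stoich[NTP_IDS[base]] = MuExpr(const=-float(n))
        stoich[PPI_ID] = MuExpr(const=float(L_nt))
        for product in data.rna_products:
            stoich[product] = MuExpr(const=1.0)
        return stoich

    if isinstance(data, TranslationData):
        data.validate()
        aas = translate_cds(data.sequence)
        if not aas:
            raise ValueError(f"translation {data.id!r}: empty product")
        L_aa = len(aas)
        for aa, n in sorted(Counter(aas).items()):
            if aa not in trna_set:
                pos = 3 * aas.index(aa) + 1
                raise ValueError(
                    f"translation {data.id!r}: no charged tRNA for amino acid "
                    f"{aa!r} (first needed at nucleotide position {pos})"
                )
            stoich[trna_set[aa]] = MuExpr(const=-float(n))
        stoich[GTP_EQUIV_ID] = MuExpr(const=-params.gtp_per_aa * L_aa)
        stoich[data.protein_id] = MuExpr(const=1.0)
        # mRNA coupling: growth dilution + first-order decay per translation
        coef = L_aa / (params.k_ribo * 3600.0)
        stoich[data.mrna_id] = MuExpr(
            const=-params.k_deg_mrna * coef, lin=-coef
        )
        return stoich

    raise TypeError(f"unsupported process data type {type(data).__name__}")


def _ensure_met(model: MEModel, met_id: str, met_class: str = "small_molecule", **kw) -> None:
    if met_id not in model.metabolites:
        model.add_metabolite(Metabolite(met_id, met_class, **kw))


def _enzyme_species(model: MEModel, enzyme_id: str) -> str:
    """Resolve an enzyme reference, preferring a generic wrapper if declared."""
    for gen in model.process_data.of_type(GenericData):
        if enzyme_id in gen.members:
            return gen.id
    return enzyme_id


def build_me_model(
    organism: OrganismSpec,
    process_data: ProcessDataSet,
    kcat_table: dict[str, float] | None = None,
    params: MEParams | None = None,
) -> MEModel:
    """Assemble a full ME model from an organism spec and process data.

    Emits, per coding gene: transcription (via its TU), mRNA dilution,
    translation, protein dilution; per complex: formation and dilution; per
    metabolic reaction: the catalyzed reaction with enzyme coupling; plus
    exchanges and the biomass-dilution reaction that closes all balances.
    """
    organism.validate()
    process_data.validate_links()
    params = params or MEParams()
    model = MEModel(model_id=f"{organism.id}_me", params=params)
    model.process_data = process_data
    kcat_table = dict(kcat_table or {})

    # universal small molecules
    for met in sorted(set(NTP_IDS.values())) + [PPI_ID, GTP_EQUIV_ID]:
        _ensure_met(model, met)

    trna_set: dict[str, str] = {}
    for td in process_data.of_type(TRNAData):
        trna_set[td.amino_acid] = td.trna_id
        _ensure_met(model, td.trna_id, "trna")

    translations = {t.gene_id: t for t in process_data.of_type(TranslationData)}
    post_translation = {
        p.protein_id: p for p in process_data.of_type(PostTranslationData)
    }

    # --- RNA species and transcription ----------------------------------
    for tx in sorted(process_data.of_type(TranscriptionData), key=lambda d: d.id):
        for product in tx.rna_products:
            rna_type = tx.rna_types.get(product, "mrna")
            gene = product[len("mrna_"):] if product.startswith("mrna_") else None
            length = len(tx.sequence)
            if gene and gene in translations:
                length = len(translations[gene].sequence)
            _ensure_met(model, product, rna_type, length=length, gene_id=gene)
        stoich = expression_stoichiometry(tx, trna_set, params)
        L_nt = len(tx.sequence)
        rnap = _enzyme_species(model, organism.rnap_id)
        _ensure_met(model, rnap, "complex" if rnap == organism.rnap_id else "generic")
        stoich[rnap] = MuExpr(lin=-L_nt / (params.k_rnap * 3600.0))
        rxn = MEReaction(
            id=f"transcription_{tx.id}", stoichiometry=stoich, kind="transcription"
        )
        model.add_reaction(rxn)
        for product in tx.rna_products:
            gene = model.metabolites[product].gene_id
            if gene:
                model.gene_mrna[gene] = product
                model.gene_transcription[gene] = rxn.id
            elif product.startswith("rrna_"):
                model.gene_transcription[product[len("rrna_"):]] = rxn.id
        # dilution for every RNA product
        for product in tx.rna_products:
            did = f"dilution_{product}"
            if did not in model.reactions:
                model.add_reaction(
                    MEReaction(did, {product: MuExpr(const=-1.0)}, kind="dilution")
                )

    # --- proteins and translation ---------------------------------------
    for gene_id in sorted(translations):
        tl = translations[gene_id]
        mature = tl.protein_id
        has_post = mature in post_translation
        raw_id = f"{mature}_pre" if has_post else mature
        L_aa = len(translate_cds(tl.sequence))
        _ensure_met(model, raw_id, "protein", length=L_aa, gene_id=gene_id)
        if tl.mrna_id not in model.metabolites:
            raise ValueError(
                f"gene {gene_id!r}: mRNA {tl.mrna_id!r} has no transcription unit"
            )
        stoich = expression_stoichiometry(tl, trna_set, params)
        if has_post:
            stoich[raw_id] = stoich.pop(mature)
        stoich[organism.ribosome_id] = MuExpr(lin=-L_aa / (params.k_ribo * 3600.0))
        _ensure_met(model, organism.ribosome_id, "complex")
        model.add_reaction(
            MEReaction(
                f"translation_{gene_id}", stoich, kind="translation", gene_id=gene_id
            )
        )
        model.gene_protein[gene_id] = mature
        if has_post:
            _ensure_met(model, mature, "protein", length=L_aa, gene_id=gene_id)
            pt = post_translation[mature]
            pstoich = {raw_id: MuExpr(const=-1.0), mature: MuExpr(const=1.0)}
            if pt.translocation is not None:
                tr = process_data[pt.translocation]
                for met, coef in tr.stoichiometry.items():
                    _ensure_met(model, met)
                    pstoich[met] = MuExpr(const=float(coef))
                for enz in tr.enzymes:
                    _ensure_met(model, enz, "complex")
                    pstoich[enz] = MuExpr(lin=-1.0 / tr.k_eff)
            for mod in pt.modifications:
                sub = process_data[mod]
                for met, coef in sorted(sub.stoichiometry.items()):
                    _ensure_met(model, met)
                    prev = pstoich.get(met, MuExpr()).const
                    pstoich[met] = MuExpr(const=prev + float(coef))
            model.add_reaction(
                MEReaction(
                    f"post_translation_{gene_id}", pstoich, kind="post_translation",
                    gene_id=gene_id,
                )
            )
        model.add_reaction(
            MEReaction(
                f"dilution_{mature}", {mature: MuExpr(const=-1.0)}, kind="dilution"
            )
        )

    # --- complexes -------------------------------------------------------
    for cplx in sorted(process_data.of_type(ComplexData), key=lambda d: d.id):
        _ensure_met(model, cplx.id, "complex")
        stoich: dict[str, MuExpr] = {cplx.id: MuExpr(const=1.0)}
        for sub, n in sorted(cplx.subunits.items()):
            _ensure_met(model, sub, "protein")
            stoich[sub] = MuExpr(const=-float(n))
        for mod in cplx.modifications:
            subre = process_data[mod]
            if not isinstance(subre, SubreactionData):
                raise ValueError(f"complex {cplx.id!r}: {mod!r} is not a subreaction")
            for met, coef in sorted(subre.stoichiometry.items()):
                _ensure_met(model, met)
                prev = stoich.get(met, MuExpr()).const
                stoich[met] = MuExpr(const=prev + float(coef))
        rid = f"formation_{cplx.id}"
        rxn = MEReaction(rid, stoich, kind="complex_formation")
        if rid in organism.machinery_caps:
            rxn.upper_bound = organism.machinery_caps[rid]
        model.add_reaction(rxn)
        model.add_reaction(
            MEReaction(
                f"dilution_{cplx.id}", {cplx.id: MuExpr(const=-1.0)}, kind="dilution"
            )
        )

    # --- generic components ----------------------------------------------
    for gen in sorted(process_data.of_type(GenericData), key=lambda d: d.id):
        _ensure_met(model, gen.id, "generic")
        for member in gen.members:
            _ensure_met(model, member, "complex")
            model.add_reaction(
                MEReaction(
                    f"generic_{gen.id}_from_{member}",
                    {member: MuExpr(const=-1.0), gen.id: MuExpr(const=1.0)},
                    kind="generic_formation",
                )
            )
        model.add_reaction(
            MEReaction(
                f"dilution_{gen.id}", {gen.id: MuExpr(const=-1.0)}, kind="dilution"
            )
        )

    # --- metabolic reactions ---------------------------------------------
    for sd in sorted(process_data.of_type(StoichiometricData), key=lambda d: d.id):
        sd.validate()
        stoich = {}
        for met, coef in sorted(sd.stoichiometry.items()):
            _ensure_met(model, met)
            stoich[met] = MuExpr(const=float(coef))
        enzyme = None
        if sd.enzyme is not None:
            enzyme = _enzyme_species(model, sd.enzyme)
            _ensure_met(model, enzyme, "complex" if enzyme == sd.enzyme else "generic")
            kcat = kcat_table.get(sd.id, params.default_kcat)
            if kcat <= 0:
                raise ValueError(f"reaction {sd.id!r}: non-positive kcat {kcat}")
            model.kcat_sources[sd.id] = "table" if sd.id in kcat_table else "default"
            if sd.id not in kcat_table:
                model.notes.append(
                    f"reaction {sd.id}: default kcat {params.default_kcat}/s applied"
                )
            stoich[enzyme] = MuExpr(lin=-1.0 / (kcat * 3600.0))
        rxn = MEReaction(
            sd.id,
            stoich,
            lower_bound=-sd.upper_bound if sd.reversible else sd.lower_bound,
            upper_bound=sd.upper_bound,
            kind="metabolic",
            enzyme=enzyme,
        )
        if sd.id in organism.machinery_caps:
            rxn.upper_bound = organism.machinery_caps[sd.id]
        model.add_reaction(rxn)

    # --- exchanges --------------------------------------------------------
    for rid, (met, lo, hi) in sorted(organism.exchanges.items()):
        _ensure_met(model, met)
        model.add_reaction(
            MEReaction(
                rid, {met: MuExpr(const=1.0)}, lower_bound=lo, upper_bound=hi,
                kind="exchange",
            )
        )

    # --- biomass dilution --------------------------------------------------
    stoich = {}
    for met, coef in sorted(organism.biomass.items()):
        _ensure_met(model, met)
        stoich[met] = MuExpr(const=-float(coef))
    model.add_reaction(MEReaction("biomass_dilution", stoich, kind="biomass"))
    model.biomass_reaction = "biomass_dilution"

    model.validate()
    return model


def integrate_kcats(
    model: MEModel,
    kcat_table: dict[str, float],
    default_kcat: float | None = None,
) -> tuple[MEModel, dict]:
    """Replace enzyme turnover numbers from a table (kcat in 1/s).

    Unresolvable reaction ids are skipped with a warning entry; returns the
    updated model (copy) and a coverage report
    ``{"n_provided", "n_default", "coverage", "skipped"}``.
    """
    model = model.copy()
    default_kcat = default_kcat or model.params.default_kcat
    skipped = []
    for rid, kcat in sorted(kcat_table.items()):
        if kcat <= 0:
            raise ValueError(f"non-positive kcat for {rid!r}: {kcat}")
        rxn = model.reactions.get(rid)
        if rxn is None or rxn.enzyme is None:
            skipped.append(rid)
            continue
        rxn.stoichiometry[rxn.enzyme] = MuExpr(lin=-1.0 / (kcat * 3600.0))
        model.kcat_sources[rid] = "table"
    catalyzed = [r for r in model.reactions.values() if r.enzyme is not None]
    n_provided = sum(
        1 for r in catalyzed if model.kcat_sources.get(r.id) == "table"
    )
    report = {
        "n_provided": n_provided,
        "n_default": len(catalyzed) - n_provided,
        "coverage": n_provided / len(catalyzed) if catalyzed else 0.0,
        "skipped": skipped,
    }
    return model, report
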