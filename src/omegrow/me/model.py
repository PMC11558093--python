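"""In-memory ME model: metabolites, reactions with μ-dependent coefficients.

A metabolism-and-expression model couples metabolic flux to the expression
machinery that carries it.  Every coupling coefficient is a function of the
growth rate μ (1/h), represented here as the affine-rational family

    coeff(μ) = (const + lin·μ) / (1 + rat·μ)

stored as a ``(const, lin, rat)`` triple.  The default builder only emits
affine coefficients (``rat = 0``), but the ratio slot is part of the schema so
saturating forms round-trip through serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .process_data import ProcessDataSet

__all__ = ["MuExpr", "Metabolite", "MEReaction", "MEModel", "MEParams"]


@dataclass(frozen=True)
class MuExpr:
    """Affine-rational function of growth rate: (const + lin·μ)/(1 + rat·μ)."""

    const: float = 0.0
    lin: float = 0.0
    rat: float = 0.0

    def __call__(self, mu: float) -> float:
        if mu < 0:
            raise ValueError(f"growth rate must be non-negative, got {mu}")
        val = (self.const + self.lin * mu) / (1.0 + self.rat * mu)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite coefficient at mu={mu}: {self}")
        return val

    def scaled(self, factor: float) -> "MuExpr":
        return MuExpr(self.const * factor, self.lin * factor, self.rat)

    def as_triple(self) -> tuple[float, float, float]:
        return (self.const, self.lin, self.rat)

    @property
    def is_constant(self) -> bool:
        return self.lin == 0.0 and self.rat == 0.0


#: metabolite classes recognized by the model
MET_CLASSES = ("small_molecule", "mrna", "rrna", "trna", "protein", "complex", "generic")


@dataclass
class Metabolite:
    """A model species.  ``length`` carries nt (RNA) or aa (protein) counts
    so macromolecule masses can be reconstructed from fluxes."""

    id: str
    met_class: str = "small_molecule"
    length: int = 0
    gene_id: str | None = None

    def __post_init__(self):
        if self.met_class not in MET_CLASSES:
            raise ValueError(f"unknown metabolite class {self.met_class!r}")


@dataclass
class MEReaction:
    """A reaction whose stoichiometry maps metabolite id -> MuExpr."""

    id: str
    stoichiometry: dict[str, MuExpr] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    kind: str = "metabolic"  # metabolic|exchange|transcription|translation|...
    enzyme: str | None = None
    gene_id: str | None = None

    def coefficient(self, met_id: str, mu: float) -> float:
        return self.stoichiometry[met_id](mu)


@dataclass
class MEParams:
    """Global expression-machinery rate parameters.

    k_ribo   — ribosome elongation rate, aa/s (default 12)
    k_rnap   — RNA polymerase elongation rate, nt/s (default 55)
    k_deg_mrna — first-order mRNA degradation rate, 1/h (default 8)
    default_kcat — fallback enzyme turnover, 1/s (default 65)
    k_trna   — tRNA turnover used for the tRNA mass proxy, 1/s (default 50)
    unmodeled_protein_fraction — fraction of proteome outside the model (0.2)
    gtp_per_aa — GTP-equivalents hydrolyzed per amino acid polymerized (2)
    """

    k_ribo: float = 12.0
    k_rnap: float = 55.0
    k_deg_mrna: float = 8.0
    default_kcat: float = 65.0
    k_trna: float = 50.0
    unmodeled_protein_fraction: float = 0.2
    gtp_per_aa: float = 2.0

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


class MEModel:
    """A μ-parametric stoichiometric model.

    ``build_matrices(mu)`` evaluates every coefficient at a growth rate and
    returns the numeric LP data (S, bounds).  The model also keeps the
    :class:`ProcessDataSet` it was built from, gene↔species maps, and the id
    of the biomass-dilution reaction used as the growth objective.
    """

    def __init__(self, model_id: str = "me_model", params: MEParams | None = None):
        self.id = model_id
        self.params = params or MEParams()
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, MEReaction] = {}
        self.process_data: ProcessDataSet = ProcessDataSet()
        self.biomass_reaction: str | None = None
        self.gene_mrna: dict[str, str] = {}
        self.gene_protein: dict[str, str] = {}
        self.gene_transcription: dict[str, str] = {}  # gene -> transcription rxn
        self.kcat_sources: dict[str, str] = {}  # reaction -> "table"|"default"
        self.notes: list[str] = []

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: MEReaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ValueError(f"reaction {rxn.id!r}: unknown metabolite {met_id!r}")
        self.reactions[rxn.id] = rxn

    # -- ordered views (deterministic) ------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return sorted(self.metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_transcription)

    # -- numeric assembly --------------------------------------------------

    def build_matrices(self, mu: float):
        """Evaluate all coefficients at ``mu``.

        Returns ``(S, lb, ub, met_index, rxn_index)`` with S dense
        (metabolites × reactions).
        """
        mets = self.metabolite_ids
        rxns = self.reaction_ids
        met_index = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rxns)))
        lb = np.empty(len(rxns))
        ub = np.empty(len(rxns))
        for j, rid in enumerate(rxns):
            rxn = self.reactions[rid]
            lb[j] = rxn.lower_bound
            ub[j] = rxn.upper_bound
            for met_id, expr in rxn.stoichiometry.items():
                S[met_index[met_id], j] = expr(mu)
        return S, lb, ub, met_index, {r: j for j, r in enumerate(rxns)}

    def validate(self) -> None:
        """Structural invariants: finite coefficients, resolvable references."""
        for rid, rxn in self.reactions.items():
            for mu_probe in (0.0, 1.0, 10.0):
                for met_id, expr in rxn.stoichiometry.items():
                    expr(mu_probe)
            if rxn.enzyme is not None and rxn.enzyme not in self.metabolites:
                raise ValueError(f"reaction {rid!r}: enzyme {rxn.enzyme!r} not in model")
        for gene, mrna in self.gene_mrna.items():
            if mrna not in self.metabolites:
                raise ValueError(f"gene {gene!r}: mRNA {mrna!r} missing")
        for gene, prot in self.gene_protein.items():
            if prot not in self.metabolites:
                raise ValueError(f"gene {gene!r}: protein {prot!r} missing")
        if self.biomass_reaction is not None and self.biomass_reaction not in self.reactions:
            raise ValueError(f"biomass reaction {self.biomass_reaction!r} missing")

    def copy(self) -> "MEModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MEModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.gene_transcription)} genes>"
        )
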