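"""Organism description consumed by the ME-model builder.

An :class:`OrganismSpec` bundles what a reconstruction pipeline would
normally scrape from a genome annotation: the gene/TU/operon map with
sequences, the identities of the expression machines, exchange reactions,
growth-associated biomass demands, and optional hard capacity caps on
machinery formation (used to create a batch-growth ceiling in toy models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GeneRecord", "OrganismSpec"]


@dataclass
class GeneRecord:
    """One gene row of the organism map (1-based genome coordinates)."""

    gene_id: str
    tu_id: str
    operon_id: str
    product: str  # "protein" or "rRNA"
    enzyme_of: str | None = None  # complex id this gene's protein belongs to
    start: int = 1
    end: int = 1


@dataclass
class OrganismSpec:
    id: str
    genes: list[GeneRecord] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)  # gene_id -> DNA
    ribosome_id: str = "ribosome"
    rnap_id: str = "rnap"
    #: metabolite -> mmol (or mmol-equivalent) consumed per unit growth flux
    biomass: dict[str, float] = field(default_factory=dict)
    #: exchange reaction id -> (metabolite, lower bound, upper bound);
    #: positive flux = uptake (the reaction produces the metabolite)
    exchanges: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    #: reaction id -> hard upper bound (machinery ceiling caps)
    machinery_caps: dict[str, float] = field(default_factory=dict)
    #: hand-derived SNL growth yield, 1/h per mmol gDW^-1 h^-1 of glucose;
    #: recorded by the generator with its derivation, None for real inputs
    yield_oracle: float | None = None
    notes: list[str] = field(default_factory=list)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def validate(self) -> None:
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.gene_id not in self.sequences:
                raise ValueError(f"gene {g.gene_id!r} has no sequence")
            if g.product == "protein" and len(self.sequences[g.gene_id]) % 3 != 0:
                raise ValueError(
                    f"coding gene {g.gene_id!r}: length not divisible by 3"
                )
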