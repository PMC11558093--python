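"""Process-data records for metabolism-and-expression (ME) model construction.

Nine record families describe everything the builder needs to emit reactions:
plain metabolic stoichiometry, enzyme complex composition, multistep machinery
sub-reactions, transcription units, translation of coding genes, tRNA charging,
membrane translocation, post-translational processing, and generic-component
groupings.  Each instance carries a unique id; the builder consumes a
:class:`ProcessDataSet` and turns every record into one or more reactions with
growth-rate-dependent coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ProcessData",
    "StoichiometricData",
    "ComplexData",
    "SubreactionData",
    "TranscriptionData",
    "TranslationData",
    "TRNAData",
    "TranslocationData",
    "PostTranslationData",
    "GenericData",
    "ProcessDataSet",
]

_DNA_ALPHABET = set("ACGT")


@dataclass
class ProcessData:
    """Base record: a uniquely identified piece of reconstruction knowledge."""

    id: str

    def validate(self) -> None:
        if not self.id:
            raise ValueError("process data id must be non-empty")


@dataclass
class StoichiometricData(ProcessData):
    """A metabolic reaction: metabolite stoichiometry and reversibility.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed).  ``enzyme`` names the catalyzing complex, or is
    ``None`` for spontaneous reactions (``spontaneous`` must then be True).
    """

    stoichiometry: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    enzyme: str | None = None
    spontaneous: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0

    def validate(self) -> None:
        super().validate()
        if self.enzyme is None and not self.spontaneous:
            raise ValueError(
                f"reaction {self.id!r} has neither an enzyme nor a spontaneous flag"
            )


@dataclass
class ComplexData(ProcessData):
    """Subunit stoichiometry of an enzyme/machine complex plus modifications."""

    subunits: dict[str, float] = field(default_factory=dict)
    modifications: list[str] = field(default_factory=list)  # SubreactionData ids


@dataclass
class SubreactionData(ProcessData):
    """A multistep machinery sub-reaction (e.g. a cofactor modification)."""

    stoichiometry: dict[str, float] = field(default_factory=dict)


@dataclass
class TranscriptionData(ProcessData):
    """A transcription unit: DNA sequence, RNA products, sigma factor usage."""

    sequence: str = ""
    rna_products: list[str] = field(default_factory=list)  # RNA metabolite ids
    rna_types: dict[str, str] = field(default_factory=dict)  # product -> mRNA/rRNA/tRNA
    sigma_factor: str | None = None

    def validate(self) -> None:
        super().validate()
        if not self.sequence:
            raise ValueError(f"transcription unit {self.id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"transcription unit {self.id!r}: invalid bases {sorted(bad)}")
        if not self.rna_products:
            raise ValueError(f"transcription unit {self.id!r} has no RNA products")


@dataclass
class TranslationData(ProcessData):
    """Translation of one coding gene: mRNA/protein sequence, tRNA additions."""

    gene_id: str = ""
    sequence: str = ""  # coding DNA sequence, length divisible by 3
    mrna_id: str = ""
    protein_id: str = ""

    def validate(self) -> None:
        super().validate()
        if not self.sequence:
            raise ValueError(f"translation data {self.id!r} has an empty sequence")
        if len(self.sequence) % 3 != 0:
            raise ValueError(
                f"translation data {self.id!r}: sequence length {len(self.sequence)} "
                "not divisible by 3"
            )
        bad = set(self.sequence.upper()) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"translation data {self.id!r}: invalid bases {sorted(bad)}")


@dataclass
class TRNAData(ProcessData):
    """Aggregate tRNA charging for one amino acid (per-codon detail collapsed)."""

    amino_acid: str = ""  # one-letter code
    codon: str | None = None
    trna_id: str = ""
    modifications: list[str] = field(default_factory=list)


@dataclass
class TranslocationData(ProcessData):
    """A protein translocation pathway: k_eff, machinery, stoichiometry."""

    k_eff: float = 65.0 * 3600.0  # 1/h
    enzymes: list[str] = field(default_factory=list)
    stoichiometry: dict[str, float] = field(default_factory=dict)


@dataclass
class PostTranslationData(ProcessData):
    """Post-translational processing: translocation pathway + modifications."""

    protein_id: str = ""
    translocation: str | None = None  # TranslocationData id
    modifications: list[str] = field(default_factory=list)  # SubreactionData ids


@dataclass
class GenericData(ProcessData):
    """A generic component standing for any member of a redundant set."""

    members: list[str] = field(default_factory=list)

    def validate(self) -> None:
        super().validate()
        if not self.members:
            raise ValueError(f"generic component {self.id!r} has no members")


class ProcessDataSet:
    """A validated, id-unique collection of process data records."""

    _FAMILIES = (
        StoichiometricData,
        ComplexData,
        SubreactionData,
        TranscriptionData,
        TranslationData,
        TRNAData,
        TranslocationData,
        PostTranslationData,
        GenericData,
    )

    def __init__(self, records: list[ProcessData] | None = None):
        self._records: dict[str, ProcessData] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, rec: ProcessData) -> None:
        rec.validate()
        if rec.id in self._records:
            raise ValueError(f"duplicate process data id {rec.id!r}")
        self._records[rec.id] = rec

    def __getitem__(self, rec_id: str) -> ProcessData:
        return self._records[rec_id]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def of_type(self, cls: type) -> list[ProcessData]:
        return [r for r in self._records.values() if isinstance(r, cls)]

    def validate_links(self) -> None:
        """Cross-record checks: complex subunits must reference known proteins."""
        protein_ids = {t.protein_id for t in self.of_type(TranslationData)}
        for cplx in self.of_type(ComplexData):
            for sub in cplx.subunits:
                if sub not in protein_ids and not self._is_rna(sub):
                    raise ValueError(
                        f"complex {cplx.id!r}: subunit {sub!r} is not a known "
                        "protein or RNA product"
                    )

    def _is_rna(self, met_id: str) -> bool:
        return any(
            met_id in td.rna_products for td in self.of_type(TranscriptionData)
        )
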