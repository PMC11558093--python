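"""COBRA-style JSON serialization of ME models.

The schema extends the familiar metabolite/reaction layout with a
``process_data`` section and stores every stoichiometric coefficient as a
``[const, lin, rat]`` triple meaning (const + lin·μ)/(1 + rat·μ).
Round-trips are bit-exact: floats are emitted with ``repr`` precision and
all collections are sorted deterministically.
"""

from __future__ import annotations

import dataclasses
import json

from . import process_data as pdata
from .model import MEModel, MEParams, MEReaction, Metabolite, MuExpr

__all__ = ["SchemaError", "model_to_dict", "model_from_dict",
           "write_model_json", "read_model_json"]

SCHEMA_VERSION = 1

_FAMILIES = {
    cls.__name__: cls
    for cls in (
        pdata.StoichiometricData,
        pdata.ComplexData,
        pdata.SubreactionData,
        pdata.TranscriptionData,
        pdata.TranslationData,
        pdata.TRNAData,
        pdata.TranslocationData,
        pdata.PostTranslationData,
        pdata.GenericData,
    )
}


class SchemaError(ValueError):
    pass


def _triple(expr: MuExpr) -> list[float]:
    return [expr.const, expr.lin, expr.rat]


def _expr(raw, path: str) -> MuExpr:
    if (
        not isinstance(raw, (list, tuple))
        or len(raw) != 3
        or not all(isinstance(v, (int, float)) for v in raw)
    ):
        raise SchemaError(
            f"{path}: coefficient must be a [const, lin, rat] triple, got {raw!r}"
        )
    return MuExpr(float(raw[0]), float(raw[1]), float(raw[2]))


def model_to_dict(model: MEModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "id": model.id,
        "params": model.params.as_dict(),
        "metabolites": [
            {
                "id": m.id,
                "met_class": m.met_class,
                "length": m.length,
                "gene_id": m.gene_id,
            }
            for m in (model.metabolites[k] for k in model.metabolite_ids)
        ],
        "reactions": [
            {
                "id": r.id,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "kind": r.kind,
                "enzyme": r.enzyme,
                "gene_id": r.gene_id,
                "stoichiometry": {
                    met: _triple(expr)
                    for met, expr in sorted(r.stoichiometry.items())
                },
            }
            for r in (model.reactions[k] for k in model.reaction_ids)
        ],
        "biomass_reaction": model.biomass_reaction,
        "gene_mrna": dict(sorted(model.gene_mrna.items())),
        "gene_protein": dict(sorted(model.gene_protein.items())),
        "gene_transcription": dict(sorted(model.gene_transcription.items())),
        "kcat_sources": dict(sorted(model.kcat_sources.items())),
        "notes": list(model.notes),
        "process_data": [
            dict(dataclasses.asdict(rec), family=type(rec).__name__)
            for rec in sorted(
                (model.process_data[i] for i in model.process_data._records),
                key=lambda r: (type(r).__name__, r.id),
            )
        ],
    }


def model_from_dict(d: dict) -> MEModel:
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {version!r} (expected {SCHEMA_VERSION})"
        )
    model = MEModel(model_id=d["id"], params=MEParams(**d["params"]))
    for m in d["metabolites"]:
        model.add_metabolite(
            Metabolite(m["id"], m["met_class"], m["length"], m["gene_id"])
        )
    for i, r in enumerate(d["reactions"]):
        stoich = {
            met: _expr(raw, f"reactions[{i}].stoichiometry.{met}")
            for met, raw in r["stoichiometry"].items()
        }
        model.add_reaction(
            MEReaction(
                r["id"],
                stoich,
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                kind=r["kind"],
                enzyme=r["enzyme"],
                gene_id=r["gene_id"],
            )
        )
    model.biomass_reaction = d["biomass_reaction"]
    model.gene_mrna = dict(d["gene_mrna"])
    model.gene_protein = dict(d["gene_protein"])
    model.gene_transcription = dict(d["gene_transcription"])
    model.kcat_sources = dict(d.get("kcat_sources", {}))
    model.notes = list(d.get("notes", []))
    records = []
    for rec in d.get("process_data", []):
        rec = dict(rec)
        family = rec.pop("family", None)
        if family not in _FAMILIES:
            raise SchemaError(f"unknown process data family {family!r}")
        records.append(_FAMILIES[family](**rec))
    model.process_data = pdata.ProcessDataSet(records)
    model.validate()
    return model


def write_model_json(model: MEModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model_json(path) -> MEModel:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid model JSON: {exc}") from exc
    return model_from_dict(d)
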