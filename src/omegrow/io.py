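"""Shared readers/writers and run configuration.

Conventions: matrices are TSV with genes as rows and a header of array ids,
missing cells written as the declared NA token "NA"; metadata TSV is keyed
by array id; id maps are two-column TSV (source_id, canonical_id, empty
canonical = unmapped); genome coordinates in organism maps are 1-based
inclusive.  Every run directory receives a serialized copy of the
configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .compendium import META_COLUMNS, ExpressionCompendium, RawExpressionTable
from .me.organism import GeneRecord, OrganismSpec

NA_TOKEN = "NA"

__all__ = [
    "RunConfig", "read_matrix_tsv", "write_matrix_tsv", "read_meta_tsv",
    "read_id_map", "read_kcat_table", "read_raw_table", "write_compendium",
    "read_compendium", "write_organism", "read_organism", "NA_TOKEN",
]


_DEFAULTS = {
    "seed": 0,
    "k_orders": 2.0,
    "n_trees": 100,
    "min_obs": 3,
    "conf_threshold": 0.95,
    "lfc_min": 1.0,
    "alpha": 0.05,
    "train_frac": 0.8,
    "n_repeats": 100,
    "budget": 50,
    "tol": 1e-6,
    "mu_max_bracket": 10.0,
    "mu_fraction": 0.5,
    "expression_tol": 0.2,
    "log_level": "INFO",
}


@dataclasses.dataclass
class RunConfig:
    """Stage parameters with strict key checking."""

    values: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw)

    def write(self, outdir) -> Path:
        out = Path(outdir) / "run_config.yaml"
        with open(out, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)
        return out

    @property
    def digest(self) -> str:
        blob = json.dumps(self.values, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                     keep_default_na=False)
    return df.astype(float)


def write_matrix_tsv(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=float_format)


def read_meta_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    return meta


def read_id_map(path) -> dict[str, str | None]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["source_id", "canonical_id"]:
        raise ValueError("id map must have columns source_id, canonical_id")
    return {
        r["source_id"]: (r["canonical_id"] or None) for _, r in df.iterrows()
    }


def read_kcat_table(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if list(df.columns[:2]) != ["reaction_id", "kcat_per_s"]:
        raise ValueError("kcat table must have columns reaction_id, kcat_per_s")
    return {r["reaction_id"]: float(r["kcat_per_s"]) for _, r in df.iterrows()}


def read_raw_table(values_path, meta_path, source_id: str) -> RawExpressionTable:
    return RawExpressionTable(
        source_id, read_matrix_tsv(values_path), read_meta_tsv(meta_path)
    )


def write_compendium(comp: ExpressionCompendium, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(comp.values, outdir / "compendium.tsv")
    comp.missing_mask.astype(int).to_csv(outdir / "missing_mask.tsv", sep="\t")
    comp.outlier_mask.astype(int).to_csv(outdir / "outlier_mask.tsv", sep="\t")
    comp.provenance.to_csv(outdir / "provenance.tsv", sep="\t")
    comp.array_meta.to_csv(outdir / "array_meta.tsv", sep="\t")


def read_compendium(outdir) -> ExpressionCompendium:
    outdir = Path(outdir)
    values = read_matrix_tsv(outdir / "compendium.tsv")
    return ExpressionCompendium(
        values=values,
        array_meta=pd.read_csv(outdir / "array_meta.tsv", sep="\t", index_col=0,
                               keep_default_na=False),
        missing_mask=pd.read_csv(outdir / "missing_mask.tsv", sep="\t",
                                 index_col=0).astype(bool),
        outlier_mask=pd.read_csv(outdir / "outlier_mask.tsv", sep="\t",
                                 index_col=0).astype(bool),
        provenance=pd.read_csv(outdir / "provenance.tsv", sep="\t", index_col=0,
                               keep_default_na=False),
    )


def write_ml_dataset(ds, path) -> None:
    """Arrays × features TSV with growth_rate / view / origin columns."""
    df = ds.X.copy()
    df["growth_rate"] = ds.y
    df["view"] = ds.view
    df["origin"] = ds.origin
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_ml_dataset(path):
    from .ml.datasets import MLDataset

    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                     keep_default_na=False)
    for col in ("growth_rate", "view", "origin"):
        if col not in df.columns:
            raise ValueError(f"ML dataset missing column {col!r}")
    views = df["view"].unique()
    if len(views) != 1:
        raise ValueError(f"mixed views in one dataset: {sorted(views)}")
    y = df["growth_rate"].astype(float)
    origin = df["origin"]
    X = df.drop(columns=["growth_rate", "view", "origin"]).astype(float)
    return MLDataset(X, y, views[0], origin)


def write_organism(org: OrganismSpec, outdir) -> None:
    """FASTA (sequences) + gene map TSV + auxiliary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(org.sequences[g.gene_id]), id=g.gene_id, description="")
        for g in org.genes
    ]
    SeqIO.write(records, outdir / "genes.fasta", "fasta")
    rows = [
        {
            "gene_id": g.gene_id, "tu_id": g.tu_id, "operon_id": g.operon_id,
            "product": g.product, "enzyme_of": g.enzyme_of or "",
            "start_1based": g.start, "end_1based": g.end,
        }
        for g in org.genes
    ]
    pd.DataFrame(rows).to_csv(outdir / "gene_map.tsv", sep="\t", index=False)
    aux = {
        "id": org.id,
        "ribosome_id": org.ribosome_id,
        "rnap_id": org.rnap_id,
        "biomass": org.biomass,
        "exchanges": {k: list(v) for k, v in org.exchanges.items()},
        "machinery_caps": org.machinery_caps,
        "yield_oracle": org.yield_oracle,
        "notes": org.notes,
    }
    with open(outdir / "organism.json", "w") as fh:
        json.dump(aux, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_organism(outdir) -> OrganismSpec:
    outdir = Path(outdir)
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(outdir / "genes.fasta", "fasta")
    }
    gmap = pd.read_csv(outdir / "gene_map.tsv", sep="\t", keep_default_na=False)
    genes = [
        GeneRecord(
            r["gene_id"], r["tu_id"], r["operon_id"], r["product"],
            r["enzyme_of"] or None, int(r["start_1based"]), int(r["end_1based"]),
        )
        for _, r in gmap.iterrows()
    ]
    with open(outdir / "organism.json") as fh:
        aux = json.load(fh)
    return OrganismSpec(
        id=aux["id"],
        genes=genes,
        sequences=sequences,
        ribosome_id=aux["ribosome_id"],
        rnap_id=aux["rnap_id"],
        biomass=aux["biomass"],
        exchanges={k: tuple(v) for k, v in aux["exchanges"].items()},
        machinery_caps=aux["machinery_caps"],
        yield_oracle=aux["yield_oracle"],
        notes=aux["notes"],
    )
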