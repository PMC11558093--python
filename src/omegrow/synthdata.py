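"""Synthetic toy organisms, compendia, regulatory and growth ground truth.

Every generator is deterministic given its seed and returns the planted
truth alongside the data, so downstream analyses can be scored against what
was actually put in: informative features, signed TF effects, corruption
positions, and the hand-derivable glucose yield of the toy metabolism.

Toy organism metabolism (per unit flux):

* ``GLYC_EFF``   glc → 2 prec + 2 atp      (spontaneous, capacity-capped)
* ``GLYC_INEFF`` glc → 1 prec + 1 atp      (enzyme E1)
* ``RESP``       prec → 3 atp              (spontaneous)
* ``CHG_<aa>``   prec + atp → charged tRNA (enzyme E2)
* ``NTPS_<b>``   prec + 2 atp → NTP        (enzyme E3)
* ``EXTRA_<i>``  prec → m_i                (one enzyme gene each)
* biomass: b_prec·prec + gam·atp + P_u·unmodeled protein + Σ wᵢ·m_i

At low growth the efficient pathway carries everything, so the growth/uptake
slope has the closed form Y = 1/g where g solves the 2×2 balance
2g − r = P, 2g + 3r = A (r = respiration flux; P, A = μ-linear precursor and
ATP demands summed from the composition above).  The generator records Y as
``yield_oracle``.  A cap on ribosome formation (machinery ceiling) forces a
batch-growth plateau; the efficient-pathway cap creates the intermediate
mixed-limitation regime between the two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compendium import META_COLUMNS, RawExpressionTable
from .me.model import MEParams
from .me.organism import GeneRecord, OrganismSpec
from .me.process_data import (
    ComplexData,
    GenericData,
    PostTranslationData,
    ProcessDataSet,
    StoichiometricData,
    SubreactionData,
    TranscriptionData,
    TranslationData,
    TRNAData,
    TranslocationData,
)

__all__ = [
    "SyntheticTruth",
    "make_toy_organism",
    "make_synthetic_compendium",
    "make_growth_truth",
    "make_regulatory_truth",
    "make_ml_benchmark",
    "make_two_view_benchmark",
]

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

STRAINS = ["168", "MP902", "MP901", "AG174", "G336C"]
MEDIA = ["LB", "MC", "SMM", "BM", "CHG"]
STRESSES = ["none", "heat", "salt", "acid", "metal"]


@dataclass
class SyntheticTruth:
    """Planted parameters recorded next to every generated dataset."""

    seed: int
    informative_features: list[str] = field(default_factory=list)
    feature_weights: dict[str, float] = field(default_factory=dict)
    tf_betas: dict[str, float] = field(default_factory=dict)  # "tf->target"
    tf_betas_normalized: dict[str, float] = field(default_factory=dict)
    mu_sat: float | None = None
    noise_sd: float | None = None
    outlier_positions: list[tuple[str, str]] = field(default_factory=list)
    missing_positions: list[tuple[str, str]] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["outlier_positions"] = [list(t) for t in self.outlier_positions]
        d["missing_positions"] = [list(t) for t in self.missing_positions]
        return json.dumps(d, indent=2, sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons - 2))
    return "ATG" + body + "TAA"


def make_toy_organism(
    n_genes: int = 8,
    n_enzymes: int = 5,
    include_machinery_ceiling: bool = True,
    seed: int = 0,
    mu_ceiling: float = 1.2,
    eff_capacity: float = 3.0,
    params: MEParams | None = None,
) -> tuple[OrganismSpec, ProcessDataSet, dict[str, float]]:
    """Generate a toy organism spec, its process data, and a kcat table.

    ``n_genes``/``n_enzymes`` control how many metabolic enzyme genes exist
    beyond the three essential ones (E1–E3); machinery genes (RNAP subunit,
    ribosomal protein, rRNA) and the unmodeled-proteome stand-in are always
    present.  Returns (organism, process_data, kcat_table).
    """
    if n_genes < 3:
        raise ValueError("need at least 3 genes")
    params = params or MEParams()
    rng = np.random.default_rng(seed)
    n_extra = max(n_enzymes - 3, n_genes - 6, 0)

    coding = ["g_E1", "g_E2", "g_E3", "g_rnapA", "g_ribA", "g_dummy"] + [
        f"g_x{i + 1}" for i in range(n_extra)
    ]
    sequences: dict[str, str] = {}
    for g in coding:
        n_codons = int(rng.integers(30, 101))  # 90..300 nt
        sequences[g] = _random_orf(rng, n_codons)
    sequences["g_rrna"] = "".join(rng.choice(list("ACGT")) for _ in range(120))

    genes = []
    pos = 1
    tu_of = {}
    for g in coding + ["g_rrna"]:
        # E2 and E3 share a transcription unit (a 2-gene operon)
        tu = "TU_E23" if g in ("g_E2", "g_E3") else f"TU_{g[2:]}"
        operon = "op_E23" if tu == "TU_E23" else tu.replace("TU_", "op_")
        product = "rRNA" if g == "g_rrna" else "protein"
        enzyme_of = {
            "g_E1": "cplx_E1",
            "g_E2": "cplx_E2",
            "g_E3": "cplx_E3",
            "g_rnapA": "cplx_rnap",
            "g_ribA": "ribosome",
        }.get(g)
        if g.startswith("g_x"):
            enzyme_of = f"cplx_{g[2:]}"
        end = pos + len(sequences[g]) - 1
        genes.append(GeneRecord(g, tu, operon, product, enzyme_of, pos, end))
        tu_of[g] = tu
        pos = end + 50

    pd_set = ProcessDataSet()

    # transcription units
    done_tus = set()
    for g in coding + ["g_rrna"]:
        tu = tu_of[g]
        if tu in done_tus:
            continue
        done_tus.add(tu)
        members = [x for x in coding + ["g_rrna"] if tu_of[x] == tu]
        seq = "".join(sequences[m] for m in members)
        products, types = [], {}
        for m in members:
            if m == "g_rrna":
                products.append("rrna_g_rrna")
                types["rrna_g_rrna"] = "rrna"
            else:
                products.append(f"mrna_{m}")
                types[f"mrna_{m}"] = "mrna"
        pd_set.add(
            TranscriptionData(
                tu, sequence=seq, rna_products=products, rna_types=types,
                sigma_factor="sigA",
            )
        )

    # translation + tRNA charging for every amino acid used
    from .me.builder import translate_cds

    aas_used = set()
    for g in coding:
        td = TranslationData(
            f"TL_{g}", gene_id=g, sequence=sequences[g],
            mrna_id=f"mrna_{g}", protein_id=f"p_{g[2:]}",
        )
        pd_set.add(td)
        aas_used.update(translate_cds(sequences[g]))
    for aa in sorted(aas_used):
        pd_set.add(
            TRNAData(f"trna_data_{aa}", amino_acid=aa, trna_id=f"trna_{aa}_charged")
        )

    # machinery complexes; ribosome assembly consumes ATP via a subreaction
    pd_set.add(SubreactionData("mod_ribosome_assembly", stoichiometry={"atp": -2.0}))
    pd_set.add(
        ComplexData(
            "ribosome",
            subunits={"p_ribA": 2.0, "rrna_g_rrna": 1.0},
            modifications=["mod_ribosome_assembly"],
        )
    )
    pd_set.add(ComplexData("cplx_rnap", subunits={"p_rnapA": 2.0}))
    pd_set.add(GenericData("generic_rnap", members=["cplx_rnap"]))
    for enz_gene in ["g_E1", "g_E2", "g_E3"] + [f"g_x{i + 1}" for i in range(n_extra)]:
        pd_set.add(ComplexData(f"cplx_{enz_gene[2:]}", subunits={f"p_{enz_gene[2:]}": 1.0}))

    # E1 is membrane-associated: exercises translocation/post-translation
    pd_set.add(
        TranslocationData("sec_toy", k_eff=65.0 * 3600.0, enzymes=[],
                          stoichiometry={"atp": -1.0})
    )
    pd_set.add(PostTranslationData("PT_p_E1", protein_id="p_E1", translocation="sec_toy"))

    # metabolism
    pd_set.add(
        StoichiometricData(
            "GLYC_EFF", stoichiometry={"glc": -1.0, "prec": 2.0, "atp": 2.0},
            spontaneous=True, upper_bound=eff_capacity,
        )
    )
    pd_set.add(
        StoichiometricData(
            "GLYC_INEFF", stoichiometry={"glc": -1.0, "prec": 1.0, "atp": 1.0},
            enzyme="cplx_E1",
        )
    )
    pd_set.add(
        StoichiometricData(
            "RESP", stoichiometry={"prec": -1.0, "atp": 3.0}, spontaneous=True
        )
    )
    for aa in sorted(aas_used):
        pd_set.add(
            StoichiometricData(
                f"CHG_{aa}",
                stoichiometry={"prec": -1.0, "atp": -1.0, f"trna_{aa}_charged": 1.0},
                enzyme="cplx_E2",
            )
        )
    for base in ("A", "U", "G", "C"):
        pd_set.add(
            StoichiometricData(
                f"NTPS_{base}",
                stoichiometry={"prec": -1.0, "atp": -2.0, f"ntp_{base}": 1.0},
                enzyme="cplx_E3",
            )
        )
    pd_set.add(StoichiometricData("ATPM", stoichiometry={"atp": -1.0}, spontaneous=True))
    pd_set.add(StoichiometricData("SINK_ppi", stoichiometry={"ppi": -1.0}, spontaneous=True))

    extra_weights = {}
    for i in range(n_extra):
        gid = f"g_x{i + 1}"
        pd_set.add(
            StoichiometricData(
                f"EXTRA_{i + 1}",
                stoichiometry={"prec": -1.0, f"m_x{i + 1}": 1.0},
                enzyme=f"cplx_{gid[2:]}",
            )
        )
        extra_weights[f"m_x{i + 1}"] = float(np.round(0.02 + 0.02 * i, 4))

    # biomass composition
    b_prec, gam = 1.0, 1.0
    L_dummy = len(translate_cds(sequences["g_dummy"]))
    aa_per_mu = 5.0  # mmol amino acid polymerized per unit growth
    P_u = aa_per_mu / L_dummy
    biomass = {"prec": b_prec, "atp": gam, "p_dummy": P_u, **extra_weights}

    # closed-form SNL yield oracle (see module docstring)
    L_nt = {g: len(sequences[g]) for g in coding}
    L_aa = {g: len(translate_cds(sequences[g])) for g in coding}
    k_tl = params.k_ribo * 3600.0
    # mu-linear mRNA synthesis floor: only the dummy protein is translated at
    # a mu-linear rate; enzyme/machinery synthesis is O(mu^2) and excluded
    ntp_per_mu = P_u * params.k_deg_mrna * L_aa["g_dummy"] / k_tl * L_nt["g_dummy"]
    prec_per_mu = b_prec + aa_per_mu + sum(extra_weights.values()) + ntp_per_mu
    atp_per_mu = (
        gam
        + (1.0 + params.gtp_per_aa) * aa_per_mu  # charging + GTP-equivalents
        + 2.0 * ntp_per_mu
    )
    P, A = prec_per_mu, atp_per_mu
    r = max((A - P) / 4.0, 0.0)
    g_per_mu = (P + r) / 2.0
    yield_oracle = 1.0 / g_per_mu

    caps = {}
    if include_machinery_ceiling:
        caps["formation_ribosome"] = mu_ceiling**2 * aa_per_mu / k_tl

    organism = OrganismSpec(
        id=f"toy{seed}",
        genes=genes,
        sequences=sequences,
        ribosome_id="ribosome",
        rnap_id="generic_rnap",
        biomass=biomass,
        exchanges={"EX_glc": ("glc", 0.0, 10.0)},
        machinery_caps=caps,
        yield_oracle=yield_oracle,
        notes=[
            f"aa_per_mu={aa_per_mu}",
            f"P={P:.6f}",
            f"A={A:.6f}",
            f"eff_capacity={eff_capacity}",
            f"mu_ceiling={mu_ceiling if include_machinery_ceiling else 'off'}",
        ],
    )
    kcat_table = {"GLYC_INEFF": 80.0, "NTPS_A": 100.0}
    return organism, pd_set, kcat_table


# --------------------------------------------------------------------------
# expression compendium generator


def _gene_list(organism_or_genes) -> list[str]:
    if isinstance(organism_or_genes, OrganismSpec):
        return organism_or_genes.gene_ids()
    return list(organism_or_genes)


def make_synthetic_compendium(
    organism_or_genes,
    n_arrays: int = 60,
    noise_sd: float = 0.05,
    missing_frac: float = 0.02,
    outlier_frac: float = 0.01,
    n_factors: int = 5,
    regulatory=None,  # (RegulatoryNetwork, SyntheticTruth) to plant TF effects
    n_source_tables: int = 2,
    seed: int = 0,
) -> tuple[list[RawExpressionTable], dict[str, str], pd.DataFrame, SyntheticTruth]:
    """Latent-factor expression tables with planted corruption.

    Returns (raw tables, id_map, clean normalized matrix, truth).  The clean
    matrix is the uncorrupted [0,1] signal (genes × arrays), useful when an
    analysis should see the planted structure without pipeline noise.  The
    raw tables carry strictly positive intensities 10^(2 + signal), split
    across ``n_source_tables`` sources with synonym gene ids in all but the
    first, plus planted missing cells and magnitude outliers (×10³).
    """
    if not (0 <= missing_frac < 1 and 0 <= outlier_frac < 1):
        raise ValueError("fractions must be in [0,1)")
    genes = _gene_list(organism_or_genes)
    rng = np.random.default_rng(seed)
    arrays = [f"arr{j:04d}" for j in range(n_arrays)]

    W = rng.normal(0, 1, size=(len(genes), n_factors))
    Z = rng.normal(0, 1, size=(n_factors, n_arrays))
    signal = W @ Z / np.sqrt(n_factors)
    truth = SyntheticTruth(seed=seed, noise_sd=noise_sd)

    if regulatory is not None:
        net, reg_truth = regulatory
        gi = {g: i for i, g in enumerate(genes)}
        # TFs get independent uniform drive; targets respond linearly
        tf_expr = {}
        for tf in net.tf_ids:
            tf_expr[tf] = rng.uniform(0.05, 0.95, size=n_arrays)
            signal[gi[tf]] = tf_expr[tf] * 4 - 2  # spread on the latent scale
        for _, row in net.edges.iterrows():
            tf, tgt = row["tf_id"], row["target_gene_id"]
            beta = reg_truth.tf_betas.get(f"{tf}->{tgt}", 0.0)
            signal[gi[tgt]] = signal[gi[tgt]] * 0.0 + beta * (tf_expr[tf] * 4 - 2)
        truth.tf_betas = dict(reg_truth.tf_betas)

    signal = signal + rng.normal(0, noise_sd, size=signal.shape)

    # clean normalized view
    lo = signal.min(axis=1, keepdims=True)
    hi = signal.max(axis=1, keepdims=True)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    clean = pd.DataFrame((signal - lo) / span, index=genes, columns=arrays)
    if regulatory is not None:
        net, reg_truth = regulatory
        gi = {g: i for i, g in enumerate(genes)}
        for key, beta in reg_truth.tf_betas.items():
            tf, tgt = key.split("->")
            truth.tf_betas_normalized[key] = float(
                beta * span[gi[tf], 0] / span[gi[tgt], 0]
            )

    # strictly positive raw intensities, spread < 1 order of magnitude so the
    # planted x10^3 outliers are the only cells beyond k=2 orders
    raw = 10 ** (2.0 + clean.to_numpy())

    n_cells = raw.size
    flat = rng.permutation(n_cells)
    n_out = int(round(outlier_frac * n_cells))
    n_miss = int(round(missing_frac * n_cells))
    out_idx = flat[:n_out]
    miss_idx = flat[n_out : n_out + n_miss]
    direction = rng.choice([-3.0, 3.0], size=n_out)
    rawf = raw.reshape(-1)
    rawf[out_idx] = rawf[out_idx] * 10.0**direction
    raw = rawf.reshape(raw.shape)
    mask_missing = np.zeros(raw.shape, dtype=bool)
    mask_missing.reshape(-1)[miss_idx] = True

    def pos_list(idx):
        gi, ai = np.unravel_index(idx, raw.shape)
        return sorted((genes[i], arrays[j]) for i, j in zip(gi, ai))

    truth.outlier_positions = pos_list(out_idx)
    truth.missing_positions = pos_list(miss_idx)

    meta = pd.DataFrame(
        {
            "strain": rng.choice(STRAINS, size=n_arrays),
            "medium": rng.choice(MEDIA, size=n_arrays),
            "temperature": rng.choice([22, 30, 37, 40], size=n_arrays),
            "pH": rng.choice([6.0, 7.0, 9.0], size=n_arrays),
            "stress": rng.choice(STRESSES, size=n_arrays),
            "perturbation": rng.choice(["none", "knockout", "overexpression"],
                                       size=n_arrays),
        },
        index=arrays,
    )[META_COLUMNS]

    values = pd.DataFrame(raw, index=genes, columns=arrays).mask(
        pd.DataFrame(mask_missing, index=genes, columns=arrays)
    )

    tables = []
    id_map: dict[str, str] = {}
    bounds = np.linspace(0, n_arrays, n_source_tables + 1).astype(int)
    for t in range(n_source_tables):
        cols = arrays[bounds[t] : bounds[t + 1]]
        sub = values[cols].copy()
        if t > 0:
            synonyms = {g: f"s{t}_{g}" for g in genes}
            sub.index = [synonyms[g] for g in genes]
            id_map.update({v: k for k, v in synonyms.items()})
        else:
            id_map.update({g: g for g in genes})
        tables.append(RawExpressionTable(f"source{t + 1}", sub, meta.loc[cols]))

    return tables, id_map, clean, truth


# --------------------------------------------------------------------------
# growth-rate ground truth


def make_growth_truth(
    expression: pd.DataFrame,  # genes × arrays, [0,1]
    n_informative: int = 20,
    weight_range: tuple[float, float] = (0.5, 1.5),
    mu_sat: float = 5.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.Series, SyntheticTruth]:
    """Sparse linear + saturating growth mapping over gene features.

    y = S / (1 + S/μ_sat) + N(0, σ) with S = Σ w_g x_g over the planted
    informative genes.
    """
    rng = np.random.default_rng(seed)
    genes = list(expression.index)
    if n_informative > len(genes):
        raise ValueError("more informative genes than genes")
    chosen = sorted(rng.choice(len(genes), size=n_informative, replace=False))
    weights = rng.uniform(*weight_range, size=n_informative)
    S = weights @ expression.iloc[chosen].to_numpy()
    y = S / (1.0 + S / mu_sat) + rng.normal(0, noise_sd, size=S.shape)
    truth = SyntheticTruth(
        seed=seed,
        informative_features=[genes[i] for i in chosen],
        feature_weights={genes[i]: float(w) for i, w in zip(chosen, weights)},
        mu_sat=mu_sat,
        noise_sd=noise_sd,
    )
    return pd.Series(y, index=expression.columns, name="growth_rate"), truth


# --------------------------------------------------------------------------
# regulatory ground truth


def make_regulatory_truth(
    organism_or_genes,
    n_tfs: int = 5,
    targets_per_tf: int = 4,
    beta_range: tuple[float, float] = (0.8, 2.0),
    seed: int = 0,
):
    """Random bipartite TF→gene network with planted signed effects."""
    from .regnet import EDGE_COLUMNS, RegulatoryNetwork

    genes = _gene_list(organism_or_genes)
    if n_tfs >= len(genes):
        raise ValueError("n_tfs must be smaller than the gene count")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    tfs = [genes[i] for i in order[:n_tfs]]
    pool = [genes[i] for i in order[n_tfs:]]
    rows, betas = [], {}
    used = set()
    for tf in tfs:
        avail = [g for g in pool if g not in used]
        k = min(targets_per_tf, len(avail))
        for tgt in rng.choice(avail, size=k, replace=False):
            used.add(tgt)
            mag = rng.uniform(*beta_range)
            beta = float(mag * rng.choice([-1.0, 1.0]))
            betas[f"{tf}->{tgt}"] = beta
            rows.append(
                {
                    "tf_id": tf,
                    "operon_id": f"op_{tgt}",
                    "target_gene_id": tgt,
                    "sign": "+" if beta > 0 else "-",
                    "evidence": "planted",
                }
            )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    net = RegulatoryNetwork(edges)
    truth = SyntheticTruth(seed=seed, tf_betas=betas)
    return net, truth


# --------------------------------------------------------------------------
# ML benchmarks


def make_ml_benchmark(
    n_features: int = 500,
    n_informative: int = 20,
    n_arrays: int = 400,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """The standard planted-signal regression benchmark.

    Features are uniform [0,1] 'gene expression' columns; the growth target
    follows the sparse saturating mapping.  Returns (X DataFrame arrays ×
    features, y Series, truth).
    """
    rng = np.random.default_rng(seed)
    genes = [f"BSU{i:05d}" for i in range(n_features)]
    arrays = [f"arr{j:04d}" for j in range(n_arrays)]
    X = pd.DataFrame(
        rng.uniform(0, 1, size=(n_features, n_arrays)), index=genes, columns=arrays
    )
    y, truth = make_growth_truth(
        X, n_informative=n_informative, noise_sd=noise_sd, seed=seed
    )
    return X.T, y, truth


def make_two_view_benchmark(
    n_features: int = 60,
    n_arrays: int = 300,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Complementary two-view benchmark: half the growth signal lives in the
    transcription view, half in the translation view.

    Returns (X_transcription, X_translation, y, truth); each X is arrays ×
    features and shares the array index.
    """
    rng = np.random.default_rng(seed)
    arrays = [f"arr{j:04d}" for j in range(n_arrays)]
    Xa = pd.DataFrame(
        rng.uniform(0, 1, size=(n_arrays, n_features)),
        index=arrays,
        columns=[f"tx_{i}" for i in range(n_features)],
    )
    Xb = pd.DataFrame(
        rng.uniform(0, 1, size=(n_arrays, n_features)),
        index=arrays,
        columns=[f"tl_{i}" for i in range(n_features)],
    )
    ka = kb = 5
    wa = rng.uniform(0.5, 1.5, size=ka)
    wb = rng.uniform(0.5, 1.5, size=kb)
    S = Xa.iloc[:, :ka].to_numpy() @ wa + Xb.iloc[:, :kb].to_numpy() @ wb
    y = pd.Series(
        S + rng.normal(0, noise_sd, size=n_arrays), index=arrays, name="growth_rate"
    )
    truth = SyntheticTruth(
        seed=seed,
        informative_features=list(Xa.columns[:ka]) + list(Xb.columns[:kb]),
        feature_weights={
            **{c: float(w) for c, w in zip(Xa.columns[:ka], wa)},
            **{c: float(w) for c, w in zip(Xb.columns[:kb], wb)},
        },
        noise_sd=noise_sd,
    )
    return Xa, Xb, y, truth
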