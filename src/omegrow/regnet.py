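"""TF–operon–target regulatory network and per-edge regression fits.

Each target gene's expression is regressed (OLS, with intercept) on the
expression of all its annotated regulator TFs across the compendium arrays.
The per-regulator coefficient β carries the direction and intensity of the
regulatory effect; ``confidence`` is 1 − p for the coefficient's two-sided
t-test, and edges with confidence above a threshold are classified as
activation (β > 0) or repression (β < 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .compendium import ExpressionCompendium

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "EdgeFit",
    "load_network",
    "write_network",
    "fit_tf_gene_regression",
    "classify_confident_edges",
]

EDGE_COLUMNS = ["tf_id", "operon_id", "target_gene_id", "sign", "evidence"]
VALID_SIGNS = {"+", "-", "unknown"}


@dataclass
class RegulatoryNetwork:
    """Signed TF→gene edges with operon annotation."""

    edges: pd.DataFrame  # columns EDGE_COLUMNS, unique (tf_id, target_gene_id)
    sigma_factors: set[str] = field(default_factory=set)
    stress_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns: {missing}")
        dup = self.edges.duplicated(subset=["tf_id", "target_gene_id"])
        if dup.any():
            raise ValueError("duplicate (tf, target) pairs present")
        bad_sign = ~self.edges["sign"].isin(VALID_SIGNS)
        if bad_sign.any():
            raise ValueError(
                f"invalid signs: {sorted(self.edges.loc[bad_sign, 'sign'].unique())}"
            )

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.edges["tf_id"].unique())

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.edges["target_gene_id"].unique())

    def regulators_of(self, target: str) -> list[str]:
        sub = self.edges[self.edges["target_gene_id"] == target]
        return sorted(sub["tf_id"].unique())


@dataclass
class EdgeFit:
    tf_id: str
    target_gene_id: str
    beta: float
    stderr: float
    p_value: float
    klass: str = "unclassified"  # activation | repression | unclassified

    @property
    def confidence(self) -> float:
        return 1.0 - self.p_value


def load_network(path_or_df) -> tuple[RegulatoryNetwork, int]:
    """Read an edge TSV (or DataFrame); collapse duplicates with a warning.

    Returns (network, n_duplicates_collapsed).  Malformed rows raise with
    the offending line number.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sign", "evidence"):
        if col not in df.columns:
            df[col] = "unknown" if col == "sign" else ""
    missing = [c for c in ("tf_id", "target_gene_id") if c not in df.columns]
    if missing:
        raise ValueError(f"edge table missing required columns: {missing}")
    if "operon_id" not in df.columns:
        df["operon_id"] = ""
    for i, row in df.iterrows():
        if not row["tf_id"] or not row["target_gene_id"]:
            raise ValueError(f"malformed edge row at line {i + 2}: empty id")
        if row["sign"] not in VALID_SIGNS:
            raise ValueError(
                f"malformed edge row at line {i + 2}: sign {row['sign']!r}"
            )
        if row["tf_id"] == row["target_gene_id"]:
            logger.info("self-loop edge %s -> itself (line %d)", row["tf_id"], i + 2)
    n_before = len(df)
    df = df.drop_duplicates(subset=["tf_id", "target_gene_id"], keep="first")
    n_dup = n_before - len(df)
    if n_dup:
        logger.warning("collapsed %d duplicate edges", n_dup)
    net = RegulatoryNetwork(df[EDGE_COLUMNS].reset_index(drop=True))
    return net, n_dup


def write_network(net: RegulatoryNetwork, path) -> None:
    net.edges[EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


def fit_tf_gene_regression(
    comp: ExpressionCompendium,
    net: RegulatoryNetwork,
) -> list[EdgeFit]:
    """OLS of each target on all of its annotated regulator TFs.

    Requires every TF and target in the compendium, and at least
    (#regulators + 2) arrays.  Near-collinear regressor sets are flagged
    unstable: their edges come back unclassified with p = 1.
    """
    values = comp.values
    present = set(values.index)
    fits: list[EdgeFit] = []
    for target in net.target_ids:
        regulators = net.regulators_of(target)
        missing = [g for g in [target] + regulators if g not in present]
        if missing:
            raise ValueError(f"genes absent from compendium: {missing}")
        n_arrays = values.shape[1]
        if n_arrays < len(regulators) + 2:
            raise ValueError(
                f"target {target!r}: {n_arrays} arrays < {len(regulators)} "
                "regulators + 2"
            )
        y = values.loc[target].to_numpy(dtype=float)
        X = values.loc[regulators].to_numpy(dtype=float).T
        keep = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
        y, X = y[keep], X[keep]
        Xc = sm.add_constant(X, has_constant="add")
        unstable = np.linalg.matrix_rank(Xc) < Xc.shape[1]
        if unstable:
            logger.warning("target %s: collinear regressors; fit unstable", target)
            for tf in regulators:
                fits.append(EdgeFit(tf, target, np.nan, np.nan, 1.0, "unclassified"))
            continue
        res = sm.OLS(y, Xc).fit()
        for k, tf in enumerate(regulators, start=1):
            fits.append(
                EdgeFit(
                    tf_id=tf,
                    target_gene_id=target,
                    beta=float(res.params[k]),
                    stderr=float(res.bse[k]),
                    p_value=float(res.pvalues[k]),
                )
            )
    return fits


def classify_confident_edges(
    fits: list[EdgeFit],
    conf_threshold: float = 0.95,
    bh_adjust: bool = False,
) -> tuple[list[EdgeFit], int, int]:
    """Keep edges with confidence > threshold; β sign sets the class.

    Returns (confident edges, n_activation, n_repression).  With
    ``bh_adjust`` the confidence is computed from BH-adjusted p-values.
    """
    if not fits:
        raise ValueError("no fits to classify")
    pvals = np.array([f.p_value for f in fits])
    if bh_adjust:
        _, pvals, _, _ = multipletests(pvals, method="fdr_bh")
    confident: list[EdgeFit] = []
    n_act = n_rep = 0
    for f, p in zip(fits, pvals):
        if 1.0 - p <= conf_threshold or np.isnan(f.beta):
            f.klass = "unclassified"
            continue
        f.klass = "activation" if f.beta > 0 else "repression"
        if f.beta > 0:
            n_act += 1
        else:
            n_rep += 1
        confident.append(f)
    return confident, n_act, n_rep
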