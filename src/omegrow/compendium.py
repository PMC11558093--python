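"""Multi-source expression compendium: normalization pipeline and analyses.

The pipeline turns heterogeneous gene×array tables into one compendium on a
common [0,1] scale, in five fixed stages:

1. harmonize gene identifiers to canonical (BSU-style) ids and merge tables;
2. per-gene min–max rescaling;
3. magnitude-outlier flagging (cells off by more than ``k`` orders of
   magnitude from the gene's median on the log10 scale of the raw values);
4. random-forest imputation of missing cells (one pass, gene-on-genes);
5. a second min–max rescale to restore the [0,1] guarantee.

Missing cells are carried as NaN throughout and tracked in an explicit mask;
a per-cell provenance table remembers which source each value came from.
Descriptive analyses: per-group Pearson correlation against a reference
condition, and Welch-test differential expression with Benjamini–Hochberg
correction (volcano-style up/down/unchanged calls).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "RawExpressionTable",
    "ExpressionCompendium",
    "NormalizationReport",
    "PIPELINE_STAGES",
    "harmonize_gene_ids",
    "minmax_rescale",
    "minmax_rescale_vector",
    "flag_magnitude_outliers",
    "impute_missing",
    "normalize_pipeline",
    "condition_correlation",
    "differential_expression",
]

PIPELINE_STAGES = [
    "harmonize_gene_ids",
    "minmax_rescale",
    "flag_magnitude_outliers",
    "impute_missing",
    "minmax_rescale",
]

META_COLUMNS = ["strain", "medium", "temperature", "pH", "stress", "perturbation"]


@dataclass
class RawExpressionTable:
    """One source table: gene×array values (NaN = missing) plus metadata."""

    source_id: str
    values: pd.DataFrame  # genes (index) × arrays (columns)
    array_meta: pd.DataFrame  # indexed by array id

    def __post_init__(self):
        if list(self.values.columns) != list(self.array_meta.index):
            raise ValueError(
                f"table {self.source_id!r}: array ids of values and metadata differ"
            )
        if (self.values == 0).any().any():
            # zeros are legal values; just make sure nobody used 0 for missing
            pass

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ExpressionCompendium:
    """Normalized gene×array matrix with masks and provenance."""

    values: pd.DataFrame
    array_meta: pd.DataFrame
    missing_mask: pd.DataFrame
    outlier_mask: pd.DataFrame
    provenance: pd.DataFrame  # per-cell source table id (str, "" = none)

    def __post_init__(self):
        shape = self.values.shape
        for name in ("missing_mask", "outlier_mask", "provenance"):
            m = getattr(self, name)
            if m.shape != shape:
                raise ValueError(f"{name} shape {m.shape} != values shape {shape}")
        finite = self.values.to_numpy()[~self.missing_mask.to_numpy()]
        if finite.size and (np.nanmin(finite) < -1e-12 or np.nanmax(finite) > 1 + 1e-12):
            raise ValueError("non-missing compendium values outside [0,1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class NormalizationReport:
    n_outliers_removed: int = 0
    n_imputed: int = 0
    n_unmapped_dropped: int = 0
    n_conflicts: int = 0
    per_gene_scale: pd.DataFrame | None = None  # columns: min, max
    stage_order: list[str] = field(default_factory=lambda: list(PIPELINE_STAGES))

    def to_dict(self) -> dict:
        d = {
            "n_outliers_removed": int(self.n_outliers_removed),
            "n_imputed": int(self.n_imputed),
            "n_unmapped_dropped": int(self.n_unmapped_dropped),
            "n_conflicts": int(self.n_conflicts),
            "stage_order": list(self.stage_order),
        }
        if self.per_gene_scale is not None:
            d["per_gene_scale"] = self.per_gene_scale.to_dict(orient="index")
        return d


# --------------------------------------------------------------------------
# stage 1: id harmonization


def harmonize_gene_ids(
    tables: list[RawExpressionTable],
    id_map: dict[str, str | None],
) -> tuple[RawExpressionTable, dict]:
    """Merge source tables onto canonical gene ids.

    ``id_map`` maps source-native ids to canonical ids (None = explicitly
    unmapped).  Rows whose id is unmapped or absent from the map are dropped
    and counted.  If two sources contribute to the same canonical gene in
    the same array, the cell is marked conflicting and set missing.
    """
    seen_arrays: dict[str, str] = {}
    for t in tables:
        for a in t.values.columns:
            if a in seen_arrays and seen_arrays[a] != t.source_id:
                raise ValueError(
                    f"array id {a!r} appears in both {seen_arrays[a]!r} "
                    f"and {t.source_id!r}"
                )
            seen_arrays[a] = t.source_id

    n_dropped = 0
    dropped_ids: list[str] = []
    frames = []
    prov_frames = []
    metas = []
    for t in tables:
        canon = {}
        for gid in t.values.index:
            target = id_map.get(gid)
            if target is None:
                n_dropped += 1
                dropped_ids.append(gid)
            else:
                canon[gid] = target
        sub = t.values.loc[list(canon)].copy()
        sub.index = [canon[g] for g in sub.index]
        frames.append(sub)
        prov = pd.DataFrame(t.source_id, index=sub.index, columns=sub.columns)
        prov_frames.append(prov)
        metas.append(t.array_meta)

    all_genes = sorted(set().union(*[set(f.index) for f in frames])) if frames else []
    all_arrays = [a for t in tables for a in t.values.columns]
    merged = pd.DataFrame(np.nan, index=all_genes, columns=all_arrays)
    provenance = pd.DataFrame("", index=all_genes, columns=all_arrays)
    n_conflicts = 0
    for sub, prov in zip(frames, prov_frames):
        for gid, row in sub.groupby(level=0):
            if len(row) > 1:  # same canonical id twice within one table
                collided = row.notna().sum(axis=0) > 1
                n_conflicts += int(collided.sum())
                collapsed = row.mean(axis=0)
                collapsed[collided] = np.nan
                row = collapsed
            else:
                row = row.iloc[0]
            cols = row.index[row.notna()]
            already = merged.loc[gid, cols].notna()
            conflict_cols = cols[already.to_numpy()]
            n_conflicts += len(conflict_cols)
            ok_cols = cols[~already.to_numpy()]
            merged.loc[gid, ok_cols] = row[ok_cols]
            provenance.loc[gid, ok_cols] = prov.loc[:, ok_cols].iloc[0]
            merged.loc[gid, conflict_cols] = np.nan
            provenance.loc[gid, conflict_cols] = "conflict"
    meta = pd.concat(metas) if metas else pd.DataFrame(columns=META_COLUMNS)
    out = RawExpressionTable("merged", merged, meta.loc[all_arrays])
    log = {
        "n_unmapped_dropped": n_dropped,
        "dropped_ids": dropped_ids,
        "n_conflicts": n_conflicts,
        "provenance": provenance,
    }
    if n_dropped:
        logger.info("harmonize: dropped %d unmapped rows", n_dropped)
    return out, log


# --------------------------------------------------------------------------
# stage 2/5: min–max rescaling


def minmax_rescale_vector(x: np.ndarray) -> np.ndarray:
    """(x−min)/(max−min) over non-missing entries; constant vectors map to 0."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    obs = ~np.isnan(x)
    if not obs.any():
        raise ValueError("all-missing vector cannot be rescaled")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi - lo == 0:
        out[obs] = 0.0
    else:
        out[obs] = (x[obs] - lo) / (hi - lo)
    return out


def minmax_rescale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene min–max rescale.  Returns (scaled matrix, per-gene min/max).

    Constant rows map to 0 (logged as degenerate); missing cells stay NaN.
    """
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        raise ValueError(
            "all-missing gene rows: " + ", ".join(matrix.index[all_missing])
        )
    lo = matrix.min(axis=1)
    hi = matrix.max(axis=1)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        logger.info(
            "minmax_rescale: %d constant rows mapped to 0", int(degenerate.sum())
        )
    safe_span = span.replace(0, 1.0)
    scaled = matrix.sub(lo, axis=0).div(safe_span, axis=0)
    scaled.loc[degenerate] = scaled.loc[degenerate].where(
        matrix.loc[degenerate].isna(), 0.0
    )
    scale = pd.DataFrame({"min": lo, "max": hi})
    return scaled, scale


# --------------------------------------------------------------------------
# stage 3: magnitude outliers


def flag_magnitude_outliers(matrix: pd.DataFrame, k_orders: float = 2.0) -> pd.DataFrame:
    """Flag cells more than ``k_orders`` orders of magnitude from the gene
    median on the log10 scale.  Requires strictly positive non-missing values
    (the rule applies to raw intensities, before any rescaling)."""
    if k_orders <= 0:
        raise ValueError("k_orders must be positive")
    vals = matrix.to_numpy(dtype=float)
    nonpos = (vals <= 0) & ~np.isnan(vals)
    if nonpos.any():
        gi, ai = np.argwhere(nonpos)[0]
        raise ValueError(
            f"non-positive value at gene {matrix.index[gi]!r}, "
            f"array {matrix.columns[ai]!r}: log-scale outlier rule needs "
            "strictly positive intensities"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        logs = np.log10(vals)
        med = np.nanmedian(logs, axis=1, keepdims=True)
    mask = np.abs(logs - med) > k_orders
    mask &= ~np.isnan(vals)
    return pd.DataFrame(mask, index=matrix.index, columns=matrix.columns)


# --------------------------------------------------------------------------
# stage 4: random-forest imputation


def impute_missing(
    matrix: pd.DataFrame,
    n_trees: int = 100,
    min_obs: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Impute missing cells with per-gene random-forest regressions.

    Each gene with missing cells is regressed on all other genes over the
    arrays where it is observed (one pass; other genes' missing entries are
    temporarily filled with their means).  Deterministic given ``seed``.
    """
    missing = matrix.isna()
    if not missing.any().any():
        return matrix.copy(), 0
    n_obs = (~missing).sum(axis=1)
    too_few = n_obs < min_obs
    if too_few.any():
        raise ValueError(
            f"genes below min_obs={min_obs}: "
            + ", ".join(matrix.index[too_few])
        )
    base = matrix.T  # arrays × genes
    filled = base.fillna(base.mean())
    out = matrix.copy()
    n_imputed = 0
    for gi, gene in enumerate(matrix.index):
        miss_arrays = missing.columns[missing.loc[gene]]
        if len(miss_arrays) == 0:
            continue
        obs_arrays = missing.columns[~missing.loc[gene]]
        predictors = filled.drop(columns=gene)
        rf = RandomForestRegressor(
            n_estimators=n_trees, random_state=seed + gi, n_jobs=1
        )
        rf.fit(predictors.loc[obs_arrays], base.loc[obs_arrays, gene])
        out.loc[gene, miss_arrays] = rf.predict(predictors.loc[miss_arrays])
        n_imputed += len(miss_arrays)
    return out, n_imputed


# --------------------------------------------------------------------------
# full pipeline


def normalize_pipeline(
    tables: list[RawExpressionTable],
    id_map: dict[str, str | None],
    k_orders: float = 2.0,
    n_trees: int = 100,
    min_obs: int = 3,
    seed: int = 0,
) -> tuple[ExpressionCompendium, NormalizationReport]:
    """Run the five normalization stages in their fixed order."""
    report = NormalizationReport()
    try:
        merged, log = harmonize_gene_ids(tables, id_map)
    except Exception as exc:
        raise RuntimeError(f"stage harmonize_gene_ids failed: {exc}") from exc
    report.n_unmapped_dropped = log["n_unmapped_dropped"]
    report.n_conflicts = log["n_conflicts"]
    provenance = log["provenance"]

    raw = merged.values
    try:
        outlier_mask = flag_magnitude_outliers(raw, k_orders=k_orders)
    except Exception as exc:
        raise RuntimeError(f"stage flag_magnitude_outliers failed: {exc}") from exc

    try:
        scaled, scale = minmax_rescale(raw)
    except Exception as exc:
        raise RuntimeError(f"stage minmax_rescale failed: {exc}") from exc
    report.per_gene_scale = scale

    flagged = scaled.mask(outlier_mask)
    report.n_outliers_removed = int(outlier_mask.to_numpy().sum())

    missing_before = flagged.isna()
    try:
        completed, n_imputed = impute_missing(
            flagged, n_trees=n_trees, min_obs=min_obs, seed=seed
        )
    except Exception as exc:
        raise RuntimeError(f"stage impute_missing failed: {exc}") from exc
    report.n_imputed = n_imputed

    try:
        final, _ = minmax_rescale(completed)
    except Exception as exc:
        raise RuntimeError(f"stage minmax_rescale (final) failed: {exc}") from exc

    comp = ExpressionCompendium(
        values=final,
        array_meta=merged.array_meta,
        missing_mask=final.isna(),
        outlier_mask=outlier_mask,
        provenance=provenance,
    )
    # note: after imputation nothing should be missing unless imputation was
    # impossible; missing_before retained only via masks
    _ = missing_before
    return comp, report


# --------------------------------------------------------------------------
# descriptive analyses


def condition_correlation(
    comp: ExpressionCompendium,
    group_key: str,
    reference: str,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Pearson correlation of each metadata group's mean profile against a
    reference group's, over shared non-missing genes.

    Returns a DataFrame indexed by group label with columns ``pcc``,
    ``n_genes``, ``flag`` (PCC ≥ threshold).  Groups with fewer than 3
    usable genes are skipped with a warning.
    """
    meta = comp.array_meta
    if group_key not in meta.columns:
        raise KeyError(f"metadata field {group_key!r} not present")
    groups = meta.groupby(group_key).groups
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not found")
    ref_profile = comp.values[list(groups[reference])].mean(axis=1)
    rows = {}
    for label, arrays in sorted(groups.items()):
        profile = comp.values[list(arrays)].mean(axis=1)
        shared = profile.notna() & ref_profile.notna()
        if shared.sum() < 3:
            warnings.warn(f"group {label!r}: fewer than 3 usable genes; skipped")
            continue
        pcc, _ = stats.pearsonr(profile[shared], ref_profile[shared])
        rows[label] = {"pcc": pcc, "n_genes": int(shared.sum()), "flag": pcc >= threshold}
    return pd.DataFrame.from_dict(rows, orient="index")


def differential_expression(
    comp: ExpressionCompendium,
    group_a: list[str],
    group_b: list[str],
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1e-3,
) -> pd.DataFrame:
    """Welch-test differential expression of group_a vs group_b.

    Per gene: mean log2 fold change (a over b, with a pseudocount since the
    compendium scale includes 0), Welch two-sample p-value, BH-adjusted q.
    Class ``up`` iff lfc ≥ lfc_min and q < alpha; ``down`` symmetric; else
    ``unchanged``.
    """
    if set(group_a) & set(group_b):
        raise ValueError("contrast groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 arrays")
    A = comp.values[group_a]
    B = comp.values[group_b]
    lfc = np.log2(A.mean(axis=1) + pseudocount) - np.log2(B.mean(axis=1) + pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False, nan_policy="omit")
    p = np.where(np.isnan(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    cls = np.where(
        (lfc >= lfc_min) & (q < alpha), "up",
        np.where((lfc <= -lfc_min) & (q < alpha), "down", "unchanged"),
    )
    return pd.DataFrame(
        {"log2fc": lfc, "t": t, "p_value": p, "q_value": q, "klass": cls},
        index=comp.values.index,
    )
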