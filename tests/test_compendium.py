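"""Normalization pipeline and descriptive-analysis behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omegrow.compendium import (
    META_COLUMNS,
    RawExpressionTable,
    condition_correlation,
    differential_expression,
    flag_magnitude_outliers,
    harmonize_gene_ids,
    impute_missing,
    minmax_rescale,
    normalize_pipeline,
)
from omegrow.synthdata import make_synthetic_compendium, make_toy_organism


def _meta(arrays):
    return pd.DataFrame(
        {c: ["x"] * len(arrays) for c in META_COLUMNS}, index=arrays
    )


def _table(values: dict, source="s1"):
    df = pd.DataFrame(values).T  # rows = genes
    return RawExpressionTable(source, df, _meta(df.columns))


class TestHarmonize:
    def test_identity_map_is_identity(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["BSU001"], columns=["a1", "a2"])
        t = RawExpressionTable("s1", df, _meta(["a1", "a2"]))
        merged, log = harmonize_gene_ids([t], {"BSU001": "BSU001"})
        pd.testing.assert_frame_equal(merged.values, df)
        assert log["n_unmapped_dropped"] == 0

    def test_synonyms_merge_across_tables(self):
        t1 = RawExpressionTable(
            "s1", pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["a1", "a2"]),
            _meta(["a1", "a2"]))
        t2 = RawExpressionTable(
            "s2", pd.DataFrame([[3.0, 4.0]], index=["gA"], columns=["b1", "b2"]),
            _meta(["b1", "b2"]))
        merged, log = harmonize_gene_ids(
            [t1, t2], {"g1": "BSU001", "gA": "BSU001"})
        assert merged.values.shape == (1, 4)
        assert list(merged.values.loc["BSU001"]) == [1.0, 2.0, 3.0, 4.0]
        assert log["provenance"].loc["BSU001", "a1"] == "s1"
        assert log["provenance"].loc["BSU001", "b2"] == "s2"

    def test_unmapped_row_dropped_and_counted(self):
        t = _table({"g1": [1.0], "gZ": [2.0]})
        merged, log = harmonize_gene_ids([t], {"g1": "BSU001", "gZ": None})
        assert list(merged.values.index) == ["BSU001"]
        assert log["n_unmapped_dropped"] == 1

    def test_duplicate_array_id_across_tables_raises(self):
        t1 = _table({"g1": [1.0]})
        t2 = _table({"g2": [1.0]}, source="s2")
        with pytest.raises(ValueError, match="0"):  # array id named
            harmonize_gene_ids([t1, t2], {"g1": "BSU001", "g2": "BSU002"})

    def test_conflicting_cells_become_missing(self):
        df1 = pd.DataFrame([[1.0]], index=["g1"], columns=["a1"])
        df2 = pd.DataFrame([[9.0]], index=["gA"], columns=["a1"])
        t1 = RawExpressionTable("s1", df1, _meta(["a1"]))
        # same array id in one table is illegal across tables, so model the
        # conflict with two synonym rows inside one table
        both = RawExpressionTable(
            "s1", pd.concat([df1, df2]), _meta(["a1"])
        )
        merged, log = harmonize_gene_ids(
            [both], {"g1": "BSU001", "gA": "BSU001"})
        assert log["n_conflicts"] == 1
        assert np.isnan(merged.values.loc["BSU001", "a1"])


class TestMinMax:
    def test_closed_form_row(self):
        scaled, scale = minmax_rescale(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc")))
        assert list(scaled.loc["g"]) == [0.0, 0.5, 1.0]
        assert scale.loc["g", "min"] == 1.0 and scale.loc["g", "max"] == 3.0

    def test_constant_row_maps_to_zero(self):
        scaled, _ = minmax_rescale(
            pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=list("abc")))
        assert list(scaled.loc["g"]) == [0.0, 0.0, 0.0]

    def test_unit_range_row_unchanged(self):
        df = pd.DataFrame([[0.0, 0.25, 1.0]], index=["g"], columns=list("abc"))
        scaled, _ = minmax_rescale(df)
        pd.testing.assert_frame_equal(scaled, df)

    def test_all_missing_row_raises(self):
        df = pd.DataFrame([[np.nan, np.nan]], index=["gene7"], columns=list("ab"))
        with pytest.raises(ValueError, match="gene7"):
            minmax_rescale(df)


class TestOutliers:
    def test_three_orders_flagged(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0, 1000.0]], index=["g"],
                          columns=list("abcd"))
        mask = flag_magnitude_outliers(df, k_orders=2.0)
        assert list(mask.loc["g"]) == [False, False, False, True]

    def test_small_spread_unflagged(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        assert not flag_magnitude_outliers(df, 2.0).any().any()

    def test_huge_k_empty_mask(self):
        df = pd.DataFrame([[1.0, 1e8]], index=["g"], columns=list("ab"))
        assert not flag_magnitude_outliers(df, k_orders=1e9).any().any()

    def test_mask_monotone_in_k(self, rng):
        vals = 10 ** rng.normal(2, 1.5, size=(20, 15))
        df = pd.DataFrame(vals)
        m1 = flag_magnitude_outliers(df, 1.0).to_numpy()
        m2 = flag_magnitude_outliers(df, 2.5).to_numpy()
        assert (m1 | m2 == m1).all()  # mask(k=1) ⊇ mask(k=2.5)

    def test_nonpositive_cell_raises_with_name(self):
        df = pd.DataFrame([[1.0, -2.0]], index=["gene3"], columns=["a", "b"])
        with pytest.raises(ValueError, match="gene3"):
            flag_magnitude_outliers(df)


class TestImpute:
    def test_complete_input_unchanged(self, rng):
        df = pd.DataFrame(rng.uniform(0, 1, (4, 6)))
        out, n = impute_missing(df)
        assert n == 0
        pd.testing.assert_frame_equal(out, df)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_planted_linear_relation_recovered(self, seed, rng):
        n = 50
        g1 = rng.uniform(0.1, 1.0, n)
        df = pd.DataFrame(
            {f"a{i}": [g1[i], 2 * g1[i], rng.uniform()] for i in range(n)},
            index=["g1", "g2", "g3"],
        )
        df.loc["g2", "a0"] = np.nan
        out, n_imp = impute_missing(df, n_trees=100, seed=seed)
        assert n_imp == 1
        expected = 2 * g1[0]
        assert abs(out.loc["g2", "a0"] - expected) <= 0.1 * expected

    def test_gene_below_min_obs_raises(self):
        df = pd.DataFrame([[1.0, np.nan, np.nan, np.nan],
                           [1.0, 2.0, 3.0, 4.0]], index=["g1", "g2"])
        with pytest.raises(ValueError, match="g1"):
            impute_missing(df, min_obs=3)


class TestPipeline:
    def test_clean_table_passes_through(self, rng):
        vals = 10 ** (2 + rng.uniform(0, 1, size=(6, 8)))
        t = RawExpressionTable(
            "s1", pd.DataFrame(vals, index=[f"BSU{i}" for i in range(6)],
                               columns=[f"a{j}" for j in range(8)]),
            _meta([f"a{j}" for j in range(8)]))
        comp, report = normalize_pipeline([t], {f"BSU{i}": f"BSU{i}" for i in range(6)})
        assert report.n_outliers_removed == 0
        assert report.n_imputed == 0
        v = comp.values.to_numpy()
        assert v.min() >= 0 and v.max() <= 1

    def test_planted_outliers_all_detected(self):
        org, _, _ = make_toy_organism(n_genes=30, n_enzymes=27, seed=1)
        tables, id_map, _, truth = make_synthetic_compendium(
            org, n_arrays=40, missing_frac=0.02, outlier_frac=0.01, seed=2)
        comp, report = normalize_pipeline(tables, id_map, n_trees=20, seed=0)
        assert report.n_outliers_removed == len(truth.outlier_positions)
        flagged = {
            (g, a)
            for g in comp.outlier_mask.index
            for a in comp.outlier_mask.columns
            if comp.outlier_mask.loc[g, a]
        }
        assert flagged == set(map(tuple, truth.outlier_positions))

    def test_stage_order_recorded(self):
        t = _table({"g1": [1.0, 2.0, 3.0, 4.0]})
        comp, report = normalize_pipeline([t], {"g1": "g1"})
        assert report.stage_order == [
            "harmonize_gene_ids", "minmax_rescale", "flag_magnitude_outliers",
            "impute_missing", "minmax_rescale",
        ]


class TestConditionCorrelation:
    @staticmethod
    def _comp(values, meta):
        from omegrow.compendium import ExpressionCompendium

        return ExpressionCompendium(
            values, meta, values.isna(), values.isna() & False,
            values.astype(str))

    def test_identical_and_reversed_groups(self, rng):
        genes = [f"g{i}" for i in range(10)]
        ref = rng.uniform(0, 1, 10)
        values = pd.DataFrame(
            {"a1": ref, "a2": ref, "a3": 1 - ref}, index=genes)
        meta = _meta(["a1", "a2", "a3"])
        meta["medium"] = ["LB", "same", "flipped"]
        out = condition_correlation(self._comp(values, meta), "medium", "LB")
        assert out.loc["same", "pcc"] == pytest.approx(1.0)
        assert out.loc["same", "flag"]
        assert out.loc["flipped", "pcc"] == pytest.approx(-1.0)
        assert not out.loc["flipped", "flag"]

    def test_noisy_group_correlates(self, rng):
        genes = [f"g{i}" for i in range(200)]
        ref = rng.uniform(0, 1, 200)
        noisy = np.clip(ref + rng.normal(0, 0.05, 200), 0, 1)
        values = pd.DataFrame({"a1": ref, "a2": noisy}, index=genes)
        meta = _meta(["a1", "a2"])
        meta["medium"] = ["LB", "noisy"]
        out = condition_correlation(self._comp(values, meta), "medium", "LB")
        assert out.loc["noisy", "pcc"] > 0.8

    def test_matches_direct_pearson_formula(self, rng):
        genes = [f"g{i}" for i in range(5)]
        values = pd.DataFrame(rng.uniform(0, 1, (5, 2)), index=genes,
                              columns=["a1", "a2"])
        meta = _meta(["a1", "a2"])
        meta["medium"] = ["LB", "other"]
        out = condition_correlation(self._comp(values, meta), "medium", "LB")
        x, y = values["a2"], values["a1"]
        pcc = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert out.loc["other", "pcc"] == pytest.approx(pcc, abs=1e-12)


class TestDifferentialExpression:
    @staticmethod
    def _comp(values):
        from omegrow.compendium import ExpressionCompendium

        meta = _meta(values.columns)
        return ExpressionCompendium(
            values, meta, values.isna(), values.isna() & False,
            values.astype(str))

    def test_identical_groups_all_unchanged(self, rng):
        vals = rng.uniform(0, 1, (20, 2))
        values = pd.DataFrame(np.hstack([vals, vals]),
                              columns=["a1", "a2", "b1", "b2"])
        out = differential_expression(self._comp(values), ["a1", "a2"],
                                      ["b1", "b2"])
        assert (out["klass"] == "unchanged").all()

    def test_planted_shift_recovered_and_label_swap_involution(self, rng):
        n_genes, shift_genes = 300, 30
        base = rng.uniform(0.1, 0.3, size=(n_genes, 12))
        noise = rng.normal(0, 0.2, size=(n_genes, 12))
        vals = base * np.exp2(noise * 0.1)
        vals[:shift_genes, 6:] = vals[:shift_genes, 6:] * 4  # +2 log2
        values = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"a{j}" for j in range(12)])
        comp = self._comp(values / values.to_numpy().max())
        g_ctrl = [f"a{j}" for j in range(6)]
        g_trt = [f"a{j}" for j in range(6, 12)]
        out = differential_expression(comp, g_trt, g_ctrl, lfc_min=1.0)
        up = set(out.index[out["klass"] == "up"])
        planted = {f"g{i}" for i in range(shift_genes)}
        assert len(up & planted) >= 25
        assert not (out.loc[list(set(out.index) - planted), "klass"] == "down").any()
        swapped = differential_expression(comp, g_ctrl, g_trt, lfc_min=1.0)
        assert set(swapped.index[swapped["klass"] == "down"]) == up
        assert set(swapped.index[swapped["klass"] == "up"]) == set(
            out.index[out["klass"] == "down"])

    def test_overlapping_groups_raise(self, rng):
        values = pd.DataFrame(rng.uniform(0, 1, (5, 4)),
                              columns=["a1", "a2", "a3", "a4"])
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(self._comp(values), ["a1", "a2"],
                                    ["a2", "a3"])
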