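"""LFQ table ingestion, peptide filter, imputation, t-test volcano, reference join."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from elcap.proteomics import (
    classify_enriched,
    compare_to_reference,
    default_column_map,
    enrichment_test,
    filter_min_peptides,
    impute_log_intensities,
    load_protein_groups,
)
from elcap.simulate import LfqSimParams, simulate_lfq_table


def small_table(**kw):
    params = LfqSimParams(n_background=100, n_spiked=5, seed=7, **kw)
    return simulate_lfq_table(params)


class TestLoading:
    def test_row_count_preserved(self):
        df = simulate_lfq_table(LfqSimParams(n_background=1000, n_spiked=50, seed=1))
        table = load_protein_groups(df)
        assert len(table) == 1050

    def test_contaminant_and_reverse_rows_dropped(self):
        df = small_table()
        df.loc[0, "Potential contaminant"] = "+"
        df.loc[1, "Reverse"] = "+"
        table = load_protein_groups(df)
        assert len(table) == len(df) - 2
        assert "P00000" not in set(table.ids)

    def test_zeros_become_missing(self):
        df = small_table(missing_rate=0.4)
        table = load_protein_groups(df)
        zeros = (df.filter(like="LFQ intensity").to_numpy() == 0).sum()
        assert int(table.intensities.isna().sum().sum()) == zeros

    def test_missing_mapped_column_is_named(self):
        df = small_table().drop(columns=["Peptides r2"])
        with pytest.raises(KeyError, match="Peptides r2"):
            load_protein_groups(df, default_column_map(small_table().columns))

    def test_tsv_round_trip_preserves_values(self, tmp_path):
        df = small_table()
        path = tmp_path / "pg.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = load_protein_groups(str(path))
        direct = load_protein_groups(df)
        pd.testing.assert_frame_equal(table.intensities, direct.intensities)
        pd.testing.assert_frame_equal(table.peptides, direct.peptides)


class TestPeptideFilter:
    def make(self, counts):
        df = small_table().head(len(counts)).copy()
        df["Peptides r1"] = [c[0] for c in counts]
        df["Peptides r2"] = [c[1] for c in counts]
        return load_protein_groups(df)

    def test_combined_count_three_excluded_four_retained(self):
        table = self.make([(1, 2), (2, 2)])  # sums 3 and 4
        kept = filter_min_peptides(table, min_combined=3)
        assert list(kept.ids) == ["P00001"]

    def test_all_zero_counts_empty_output(self):
        table = self.make([(0, 0), (0, 0)])
        assert len(filter_min_peptides(table)) == 0

    def test_filter_is_monotone_in_threshold(self):
        table = load_protein_groups(small_table())
        previous: set = set()
        for cutoff in (10, 5, 3, 0):
            kept = set(filter_min_peptides(table, cutoff).ids)
            assert previous <= kept
            previous = kept


class TestImputation:
    def test_no_missing_is_pure_log2_and_seed_independent(self):
        df = small_table(missing_rate=0.0)
        t1 = impute_log_intensities(load_protein_groups(df), seed=1)
        t2 = impute_log_intensities(load_protein_groups(df), seed=999)
        pd.testing.assert_frame_equal(t1.log2, t2.log2)
        assert not t1.imputed.any().any()
        assert np.allclose(t1.log2.to_numpy(), np.log2(t1.intensities.to_numpy()))

    def test_imputed_cells_follow_downshifted_gaussian(self):
        params = LfqSimParams(n_background=5_000, n_spiked=0, missing_rate=0.3, seed=3)
        table = load_protein_groups(simulate_lfq_table(params))
        table = impute_log_intensities(table, shift=1.8, width=0.3, seed=4)
        col = table.log2.columns[0]
        observed = table.log2.loc[~table.imputed[col], col]
        imputed = table.log2.loc[table.imputed[col], col]
        assert imputed.size > 1_000
        expected_mu = observed.mean() - 1.8 * observed.std(ddof=1)
        assert imputed.mean() == pytest.approx(expected_mu, abs=0.05 * observed.std(ddof=1))

    def test_same_seed_identical_matrix(self):
        df = small_table(missing_rate=0.3)
        t1 = impute_log_intensities(load_protein_groups(df), seed=5)
        t2 = impute_log_intensities(load_protein_groups(df), seed=5)
        pd.testing.assert_frame_equal(t1.log2, t2.log2)

    def test_fully_missing_column_is_an_error(self):
        df = small_table()
        col = "LFQ intensity IP_r1_i1"
        df[col] = 0.0
        with pytest.raises(ValueError, match="no observed values"):
            impute_log_intensities(load_protein_groups(df), seed=0)


def prepared(df, seed=0):
    return impute_log_intensities(load_protein_groups(df), seed=seed)


class TestEnrichmentTest:
    def test_identical_sides_give_zero_diff_p_one(self):
        df = small_table(missing_rate=0.0)
        ip_cols = [c for c in df.columns if c.startswith("LFQ intensity IP")]
        ctrl_cols = [c for c in df.columns if c.startswith("LFQ intensity control")]
        for ic, cc in zip(ip_cols, ctrl_cols):
            df[ic] = df[cc]
        res = enrichment_test(prepared(df))
        assert np.allclose(res["log2_diff"], 0)
        assert np.allclose(res["p_value"], 1.0)

    def test_matches_closed_form_student_p_on_worked_example(self):
        # test log2 (10,12,11) vs control (5,6,7): Student t, df = 4
        df = small_table(missing_rate=0.0).head(1).copy()
        test_vals = [10.0, 12.0, 11.0]
        ctrl_vals = [5.0, 6.0, 7.0]
        i = 0
        for r in (1, 2):
            for j in (1, 2, 3):
                col_t = f"LFQ intensity IP_r{r}_i{j}"
                col_c = f"LFQ intensity control_r{r}_i{j}"
                if (r, j) in [(1, 1), (1, 2), (1, 3)]:
                    df[col_t] = 2.0 ** test_vals[j - 1]
                    df[col_c] = 2.0 ** ctrl_vals[j - 1]
                else:
                    df = df.drop(columns=[col_t, col_c])
        res = enrichment_test(prepared(df))
        assert res.loc[0, "log2_diff"] == pytest.approx(5.0, abs=1e-12)
        # closed form: t = diff / (sp * sqrt(2/3)), two-sided p from t_4
        x, y = np.array(test_vals), np.array(ctrl_vals)
        sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (2 / 3))
        from scipy.stats import t as tdist

        p_closed = 2 * tdist.sf(abs(t), df=4)
        assert res.loc[0, "p_value"] == pytest.approx(p_closed, abs=1e-12)

    def test_injection_order_permutation_invariance(self):
        df = small_table(missing_rate=0.0)
        res1 = enrichment_test(prepared(df))
        cols = [c for c in df.columns if c.startswith("LFQ intensity IP")]
        permuted = df.copy()
        permuted[cols] = df[list(reversed(cols))].to_numpy()
        res2 = enrichment_test(prepared(permuted))
        assert np.allclose(res1["p_value"], res2["p_value"])
        assert np.allclose(res1["log2_diff"], res2["log2_diff"])

    def test_volcano_symmetry_under_side_swap(self):
        df = small_table(missing_rate=0.2)
        table = prepared(df, seed=11)
        fwd = enrichment_test(table, "IP", "control")
        rev = enrichment_test(table, "control", "IP")
        assert np.allclose(fwd["log2_diff"], -rev["log2_diff"])
        assert np.allclose(fwd["p_value"], rev["p_value"])

    def test_zero_variance_conventions(self):
        df = small_table(missing_rate=0.0).head(2).copy()
        for col in df.filter(like="LFQ intensity").columns:
            df[col] = 2.0 ** 10.0
        for col in df.filter(like="LFQ intensity IP").columns:
            df.loc[1, col] = 2.0 ** 12.0
        res = enrichment_test(prepared(df))
        assert res.loc[0, "p_value"] == 1.0
        assert res.loc[1, "p_value"] == np.finfo(float).tiny
        assert res.loc[1, "degenerate_variance"]

    def test_replicate_means_mode_has_two_observations_per_side(self):
        df = small_table(missing_rate=0.0)
        res = enrichment_test(prepared(df), replicate_means=True)
        assert np.isfinite(res["p_value"]).all()


class TestClassification:
    def frame(self, diffs, neg_log2_ps):
        return pd.DataFrame(
            {
                "protein_id": [f"P{i}" for i in range(len(diffs))],
                "log2_diff": diffs,
                "neg_log2_p": neg_log2_ps,
            }
        )

    def test_clear_enrichment_flagged(self):
        out = classify_enriched(self.frame([5.0], [3.0]))
        assert out["enriched"].all()

    def test_thresholds_are_strict(self):
        out = classify_enriched(self.frame([2.0, 2.01, 2.01], [3.0, 2.0, 2.01]))
        assert list(out["enriched"]) == [False, False, True]

    def test_null_table_false_positive_rate_below_five_percent(self):
        params = LfqSimParams(
            n_background=1_000, n_spiked=0, missing_rate=0.3, seed=21
        )
        table = prepared(simulate_lfq_table(params), seed=22)
        res = classify_enriched(enrichment_test(table))
        assert res["enriched"].mean() <= 0.05


class TestReferenceComparison:
    def res_frame(self, ids, diffs, ps):
        return pd.DataFrame(
            {"protein_id": ids, "log2_diff": diffs, "neg_log2_p": ps}
        )

    def test_empty_reference_enriched_set_is_an_error(self):
        ref = self.res_frame(["A"], [0.5], [0.1])
        double = self.res_frame(["A"], [3.0], [4.0])
        with pytest.raises(ValueError, match="no enriched"):
            compare_to_reference(double, ref)

    def test_protein_missing_from_double_ip_reported_with_nan(self):
        ref = self.res_frame(["A", "B"], [5.0, 4.0], [6.0, 5.0])
        double = self.res_frame(["A"], [1.0], [2.0])
        joined = compare_to_reference(double, ref)
        assert set(joined["protein_id"]) == {"A", "B"}
        assert joined.set_index("protein_id").loc["B", "double_log2_diff"] != \
            joined.set_index("protein_id").loc["B", "double_log2_diff"]  # NaN

    def test_join_equals_brute_force_intersection(self):
        rng = np.random.default_rng(30)
        ids = [f"P{i}" for i in range(200)]
        ref = self.res_frame(ids, rng.normal(2, 2, 200), rng.gamma(2, 2, 200))
        sub = rng.choice(200, 120, replace=False)
        double = self.res_frame(
            [ids[i] for i in sub], rng.normal(0, 2, 120), rng.gamma(2, 2, 120)
        )
        joined = compare_to_reference(double, ref)
        expected_ids = {
            pid for pid, d, p in zip(ref["protein_id"], ref["log2_diff"], ref["neg_log2_p"])
            if d > 2 and p > 2
        }
        assert set(joined["protein_id"]) == expected_ids
        lookup = dict(zip(double["protein_id"], double["log2_diff"]))
        for _, row in joined.iterrows():
            if row["protein_id"] in lookup:
                assert row["double_log2_diff"] == lookup[row["protein_id"]]
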