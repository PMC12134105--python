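import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cysredox import stats_core as sc
from cysredox.synthetic_data import make_meta


def matrix_from(meta, values):
    return pd.DataFrame(values, columns=[m.sample_id for m in meta])


class TestFilterValid:
    def test_boundary_fraction_is_inclusive(self, meta10):
        row = {m.sample_id: np.nan for m in meta10}
        # exactly 3/10 valid per group = 30%
        for sid in ["P001_T", "P002_T", "P003_T", "P001_H", "P002_H", "P003_H"]:
            row[sid] = 1.0
        mat = pd.DataFrame([row])
        spec = sc.FilterSpec(0.30, "each_group")
        assert sc.filter_valid(mat, meta10, spec).shape[0] == 1

    def test_each_group_vs_any_group_modes(self, meta10):
        row = {m.sample_id: np.nan for m in meta10}
        for m in meta10:
            if m.group == "tumor":
                row[m.sample_id] = 1.0  # 10/10 tumor
        for sid in ["P001_H", "P002_H"]:
            row[sid] = 1.0  # 2/10 healthy
        mat = pd.DataFrame([row])
        assert sc.filter_valid(mat, meta10, sc.FilterSpec(0.30, "each_group")).empty
        assert (
            sc.filter_valid(mat, meta10, sc.FilterSpec(0.60, "any_group")).shape[0]
            == 1
        )

    def test_empty_result_warns_not_errors(self, meta10):
        mat = matrix_from(meta10, np.full((2, 20), np.nan))
        with pytest.warns(UserWarning, match="no features"):
            out = sc.filter_valid(mat, meta10, sc.FilterSpec(0.5, "each_group"))
        assert out.empty


class TestMedianCenter:
    def test_small_column(self):
        mat = pd.DataFrame({"s": [1.0, 2.0, 3.0]})
        assert sc.median_center(mat)["s"].tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(50, 20)))
        once = sc.median_center(mat)
        pd.testing.assert_frame_equal(sc.median_center(once), once)
        assert np.allclose(once.median(axis=0), 0.0)

    def test_all_missing_column_is_error(self):
        mat = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="all-missing"):
            sc.median_center(mat)


class TestImputeDownshift:
    def test_draw_moments_match_stated_parameters(self):
        # column with observed mean 25, SD 2 -> draws ~ N(25 - 1.8*2, (0.3*2)^2)
        rng = np.random.default_rng(1)
        observed = rng.normal(25, 2, size=4000)
        col = np.concatenate([observed, np.full(10_000, np.nan)])
        mat = pd.DataFrame({"s": col})
        out = sc.impute_downshift(mat, sc.ImputeSpec(seed=7))
        draws = out["s"].to_numpy()[4000:]
        m, s = observed.mean(), observed.std(ddof=1)
        se_mean = 0.3 * s / np.sqrt(10_000)
        assert abs(draws.mean() - (m - 1.8 * s)) < 3 * se_mean
        assert abs(draws.std(ddof=1) - 0.3 * s) < 0.02

    def test_identity_without_missing_and_observed_untouched(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0, np.nan], "b": [1.0, 2.0, 3.0, 4.0]})
        out = sc.impute_downshift(mat, sc.ImputeSpec(seed=0))
        assert out["b"].tolist() == [1.0, 2.0, 3.0, 4.0]
        assert out["a"].iloc[:3].tolist() == [1.0, 2.0, 3.0]
        assert not out.isna().any().any()

    def test_same_seed_bitwise_identical(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(100, 6))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        mat = pd.DataFrame(vals)
        a = sc.impute_downshift(mat, sc.ImputeSpec(seed=5))
        b = sc.impute_downshift(mat, sc.ImputeSpec(seed=5))
        assert a.equals(b)

    def test_sparse_column_falls_back_to_global_moments(self):
        mat = pd.DataFrame(
            {"a": [np.nan, np.nan, 25.0, np.nan], "b": [24.0, 25.0, 26.0, 27.0]}
        )
        with pytest.warns(UserWarning, match="<3 observed"):
            out = sc.impute_downshift(mat, sc.ImputeSpec(seed=0))
        assert not out.isna().any().any()


class TestTwoGroupTest:
    def test_matches_closed_form_pooled_t(self, meta10):
        meta = make_meta(3)
        mat = matrix_from(meta, [[1, 4, 2, 5, 3, 6]])  # T,H interleaved
        res = sc.two_group_test(mat, meta)
        # tumor = [1,2,3], healthy = [4,5,6]
        assert res["mean_diff"].iloc[0] == -3.0
        assert res["t_stat"].iloc[0] == pytest.approx(-3.6742346, abs=1e-6)
        assert res["p_value"].iloc[0] == pytest.approx(0.0213, abs=5e-4)
        assert res["direction"].iloc[0] == "up_healthy"

    def test_s0_zero_is_plain_t_and_large_s0_kills_statistic(self, null_matrix, meta10):
        res0 = sc.two_group_test(null_matrix, meta10, s0=0.0)
        assert np.allclose(res0["s0_stat"], res0["t_stat"])
        res_big = sc.two_group_test(null_matrix, meta10, s0=1e9)
        assert np.all(np.abs(res_big["s0_stat"]) < 1e-6)

    def test_zero_variance_zero_difference_gives_p_one(self, meta10):
        mat = matrix_from(meta10, np.ones((1, 20)))
        res = sc.two_group_test(mat, meta10)
        assert res["p_value"].iloc[0] == 1.0
        assert res["t_stat"].iloc[0] == 0.0

    def test_insufficient_observations_yield_missing_result(self, meta10):
        row = {m.sample_id: np.nan for m in meta10}
        row["P001_T"] = 1.0
        row["P001_H"] = 2.0
        row["P002_H"] = 3.0
        res = sc.two_group_test(pd.DataFrame([row]), meta10)
        assert np.isnan(res["p_value"].iloc[0])

    def test_paired_matches_scipy_ttest_rel(self):
        meta = make_meta(6)
        rng = np.random.default_rng(8)
        mat = matrix_from(meta, rng.normal(size=(40, 12)))
        res = sc.two_group_test(mat, meta, paired=True)
        t_cols = [m.sample_id for m in meta if m.group == "tumor"]
        h_cols = [m.sample_id for m in meta if m.group == "healthy"]
        expected = sps.ttest_rel(mat[t_cols], mat[h_cols], axis=1)
        assert np.allclose(res["t_stat"], expected.statistic)
        assert np.allclose(res["p_value"], expected.pvalue)

    def test_paired_and_unpaired_agree_in_direction(self):
        meta = make_meta(8)
        rng = np.random.default_rng(9)
        base = rng.normal(size=(30, 8))
        shift = rng.normal(scale=2.0, size=(30, 1))
        tumor = base + shift + 0.1 * rng.normal(size=(30, 8))
        healthy = base
        data = {}
        for i, m in enumerate([x for x in meta if x.group == "tumor"]):
            data[m.sample_id] = tumor[:, i]
        for i, m in enumerate([x for x in meta if x.group == "healthy"]):
            data[m.sample_id] = healthy[:, i]
        mat = pd.DataFrame(data)
        unpaired = sc.two_group_test(mat, meta, paired=False)
        paired = sc.two_group_test(mat, meta, paired=True)
        assert (np.sign(unpaired["mean_diff"]) == np.sign(paired["mean_diff"])).all()


class TestBH:
    def test_hand_computed_case(self):
        assert np.allclose(sc.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_rank_monotone(self):
        assert sc.bh_adjust([0.2]) == pytest.approx([0.2])
        p = np.random.default_rng(2).uniform(size=200)
        q = sc.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestPermutationFdr:
    def test_complete_null_controls_fdr(self, null_matrix, meta10):
        res = sc.permutation_fdr(null_matrix, meta10, s0=0.1, n_perm=250, seed=4)
        frac = res["significant"].mean()
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert frac <= 0.05 + 3 * se

    def test_planted_effects_recovered_with_power(self, null_matrix, meta10):
        mat = null_matrix.copy()
        tumor_cols = [m.sample_id for m in meta10 if m.group == "tumor"]
        mat.iloc[:50, [mat.columns.get_loc(c) for c in tumor_cols]] += 2.0
        res = sc.permutation_fdr(mat, meta10, s0=0.1, n_perm=250, seed=4)
        assert res["significant"].iloc[:50].mean() >= 0.80

    def test_identical_groups_give_zero_significant(self, meta10):
        rng = np.random.default_rng(6)
        half = rng.normal(size=(100, 10))
        # each patient's tumor column equals their healthy column
        data = {}
        for i, pair in enumerate(sorted({m.pair_key for m in meta10})):
            data[f"{pair}_T"] = half[:, i]
            data[f"{pair}_H"] = half[:, i]
        mat = pd.DataFrame(data)
        res = sc.permutation_fdr(mat, meta10, s0=0.1, n_perm=100, seed=1)
        assert not res["significant"].any()

    def test_q_values_decrease_with_effect_size(self, meta10):
        rng = np.random.default_rng(12)
        mat = matrix_from(meta10, rng.normal(size=(300, 20)))
        tumor_cols = [m.sample_id for m in meta10 if m.group == "tumor"]
        idx = [mat.columns.get_loc(c) for c in tumor_cols]
        mat.iloc[0, idx] += 3.0
        mat.iloc[1, idx] += 0.5
        res = sc.permutation_fdr(mat, meta10, s0=0.1, n_perm=200, seed=2)
        assert res["q_value"].iloc[0] <= res["q_value"].iloc[1]

    def test_exhaustive_enumeration_for_small_paired_designs(self):
        meta = make_meta(4)  # 2^4 = 16 sign patterns < n_perm
        rng = np.random.default_rng(5)
        mat = matrix_from(meta, rng.normal(size=(50, 8)))
        a = sc.permutation_fdr(mat, meta, s0=0.1, n_perm=1000, seed=1, paired=True)
        b = sc.permutation_fdr(mat, meta, s0=0.1, n_perm=1000, seed=99, paired=True)
        # exhaustive enumeration is seed-independent
        pd.testing.assert_frame_equal(a, b)

    def test_seeded_runs_reproduce(self, null_matrix, meta10):
        a = sc.permutation_fdr(null_matrix, meta10, n_perm=50, seed=3)
        b = sc.permutation_fdr(null_matrix, meta10, n_perm=50, seed=3)
        pd.testing.assert_frame_equal(a, b)
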