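"""Recoding, iterative imputation, discretization and ADASYN."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exacbn.preprocessing import (DiscretizationMap, RecodeRules,
                                  adasyn_balance, discretize_hartemink,
                                  fixed_clinical_cuts,
                                  impute_iterative_forest,
                                  recode_zeros_and_outliers)


class TestRecode:
    def test_zeros_become_missing_in_biomarkers(self):
        df = pd.DataFrame({"feno": [0.0, 25.0, 300.0]})
        out, log = recode_zeros_and_outliers(
            df, RecodeRules(zero_to_missing=("feno",), bounds={}))
        assert out.feno.isna().tolist() == [True, False, False]
        assert log == {"feno": 1}

    def test_clean_table_unchanged_with_empty_log(self):
        df = pd.DataFrame({"feno": [25.0, 30.0], "bec": [100.0, 200.0]})
        out, log = recode_zeros_and_outliers(
            df, RecodeRules(zero_to_missing=("feno", "bec"),
                            bounds={"bec": (0, 5000)}))
        pd.testing.assert_frame_equal(out, df)
        assert log == {}

    def test_out_of_bounds_recoded_and_logged(self):
        df = pd.DataFrame({"bec": [100.0, 7000.0]})
        out, log = recode_zeros_and_outliers(
            df, RecodeRules(zero_to_missing=(), bounds={"bec": (0, 5000)}))
        assert out.bec.isna().tolist() == [False, True]
        assert log == {"bec": 1}

    def test_unknown_column_raises(self):
        with pytest.raises(KeyError):
            recode_zeros_and_outliers(
                pd.DataFrame({"a": [1.0]}),
                RecodeRules(zero_to_missing=("nope",), bounds={}))


class TestImputer:
    def test_complete_table_is_identity_with_zero_iterations(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [3.0, 4.0]})
        res = impute_iterative_forest(df, seed=0)
        pd.testing.assert_frame_equal(res.completed, df)
        assert res.iterations == 0

    def test_beats_mean_imputation_on_correlated_data(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y})
        mask = rng.random(n) < 0.2
        dfm = df.copy()
        dfm.loc[mask, "y"] = np.nan
        res = impute_iterative_forest(dfm, seed=1)
        rmse_rf = np.sqrt(np.mean((res.completed.y[mask] - y[mask]) ** 2))
        rmse_mean = np.sqrt(np.mean((dfm.y.mean() - y[mask]) ** 2))
        assert rmse_rf < rmse_mean

    def test_refuses_column_over_half_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "y": [1.0, np.nan, np.nan, np.nan, 2.0]})
        with pytest.raises(ValueError, match="'y'"):
            impute_iterative_forest(df, seed=0)

    def test_observed_cells_never_altered(self, rng):
        n = 500
        df = pd.DataFrame({"x": rng.normal(size=n),
                           "y": rng.normal(size=n)})
        mask = rng.random(n) < 0.3
        dfm = df.copy()
        dfm.loc[mask, "y"] = np.nan
        res = impute_iterative_forest(dfm, seed=2)
        np.testing.assert_array_equal(res.completed.y[~mask], df.y[~mask])
        np.testing.assert_array_equal(res.completed.x, df.x)

    def test_imputes_categorical_columns(self, rng):
        n = 800
        z = rng.integers(0, 2, n)
        df = pd.DataFrame({"z": pd.Series(np.where(z == 1, "yes", "no")),
                           "w": z + 0.2 * rng.normal(size=n)})
        mask = rng.random(n) < 0.2
        df.loc[mask, "z"] = np.nan
        res = impute_iterative_forest(df, seed=3)
        assert not res.completed.z.isna().any()
        acc = (res.completed.z[mask] == np.where(z == 1, "yes", "no")[mask]).mean()
        assert acc > 0.8


class TestFixedCuts:
    def test_boundary_goes_to_upper_bin(self):
        col = pd.Series([100.0, 150.0, 500.0])
        assert list(fixed_clinical_cuts(col, (150, 300))) == \
            ["<150", "150-300", ">=300"]
        assert list(fixed_clinical_cuts(pd.Series([25.0]), (25, 50))) == \
            ["25-50"]

    def test_empty_column(self):
        out = fixed_clinical_cuts(pd.Series([], dtype=float), (1.0, 2.0))
        assert len(out) == 0

    def test_non_increasing_cuts_rejected(self):
        with pytest.raises(ValueError):
            fixed_clinical_cuts(pd.Series([1.0]), (2.0, 2.0))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30))
    def test_binning_is_order_preserving(self, values):
        col = pd.Series(values, dtype=float)
        codes = fixed_clinical_cuts(col, (-10.0, 10.0)).codes
        order = np.argsort(col.to_numpy(), kind="stable")
        assert (np.diff(codes[order]) >= 0).all()


class TestHartemink:
    def test_merge_counting_six_to_three(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=2000),
                           "b": rng.normal(size=2000)})
        out, dmap = discretize_hartemink(df, ["a", "b"], 3, 6)
        assert out.a.cat.categories.size == 3
        assert len(dmap.cuts["a"]) == 2          # 6 bins - 3 merges = 3 levels

    def test_already_at_target_levels_unchanged(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0] * 200})
        out, dmap = discretize_hartemink(df, ["a"], 3, 3)
        assert out.a.cat.categories.size == 3

    def test_constant_column_single_level_with_warning(self):
        df = pd.DataFrame({"a": np.ones(100), "b": np.arange(100.0)})
        with pytest.warns(UserWarning):
            out, dmap = discretize_hartemink(df, ["a", "b"], 3, 6)
        assert out.a.nunique() == 1

    def test_non_numeric_column_rejected(self):
        with pytest.raises(TypeError):
            discretize_hartemink(pd.DataFrame({"a": ["x", "y"]}), ["a"], 2, 4)

    def test_beats_random_merging_on_copies(self, rng):
        # pairwise MI after greedy merging >= random merging in >= 95% of runs
        wins = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            z = r.normal(size=1500)
            df = pd.DataFrame({
                "a": z, "b": z + 0.3 * r.normal(size=1500),
                "noise": r.normal(size=1500)})
            disc, _ = discretize_hartemink(df, ["a", "b", "noise"], 3, 6)
            mi_greedy = _total_mi(disc)
            mi_rand = _total_mi(_random_merge(df, ["a", "b", "noise"], r))
            wins += mi_greedy >= mi_rand - 1e-12
        assert wins >= 48

    def test_map_round_trips_through_json(self):
        dmap = DiscretizationMap({"x": (1.0, 2.0)}, {"x": ("lo", "mid", "hi")})
        back = DiscretizationMap.from_json(dmap.to_json())
        assert back.cuts == dmap.cuts and back.labels == dmap.labels


def _random_merge(df, cols, rng):
    out = {}
    for c in cols:
        qs = np.unique(np.quantile(df[c], np.linspace(0, 1, 7)[1:-1]))
        codes = np.searchsorted(qs, df[c], side="right")
        while codes.max() + 1 > 3:
            cut = rng.integers(0, codes.max())
            codes = np.where(codes > cut, codes - 1, codes)
        out[c] = codes
    return pd.DataFrame(out)


def _total_mi(df):
    from exacbn.preprocessing import _mi
    cols = [pd.Categorical(df[c]).codes.astype(np.int64) for c in df.columns]
    total = 0.0
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            total += _mi(cols[i], cols[j])
    return total


class TestAdasyn:
    def test_binary_90_10_generates_exactly_eighty(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=100)})
        y = np.array([0] * 90 + [1] * 10)
        Xb, yb = adasyn_balance(X, y, k_neighbors=5, target_ratio=1.0, seed=0)
        assert len(Xb) - len(X) == 80
        assert np.bincount(yb).tolist() == [90, 90]

    def test_balanced_input_is_identity(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=40)})
        y = np.array([0] * 20 + [1] * 20)
        Xb, yb = adasyn_balance(X, y, seed=0)
        assert len(Xb) == 40

    def test_three_class_ratios_land_near_one(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=1000),
                          "g": rng.normal(size=1000)})
        y = np.array([0] * 700 + [1] * 200 + [2] * 100)
        Xb, yb = adasyn_balance(X, y, target_ratio=1.0, seed=1)
        counts = np.bincount(yb)
        for c in (1, 2):
            assert 0.95 <= counts[c] / counts[0] <= 1.05

    def test_synthetic_points_stay_in_segment(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=200)})
        y = np.array([0] * 180 + [1] * 20)
        Xb, yb = adasyn_balance(X, y, seed=2)
        lo, hi = X.f[y == 1].min(), X.f[y == 1].max()
        synth = Xb.f[len(X):]
        assert synth.between(lo - 1e-9, hi + 1e-9).all()

    def test_categoricals_copied_from_seed(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=60),
                          "c": pd.Categorical(["u"] * 30 + ["v"] * 30)})
        y = np.array([0] * 50 + [1] * 10)
        Xb, yb = adasyn_balance(X, y, k_neighbors=3, seed=3)
        assert set(Xb.c.unique()) <= {"u", "v"}

    def test_errors(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=20)})
        with pytest.raises(ValueError):
            adasyn_balance(X, np.zeros(20, dtype=int), seed=0)
        y = np.array([0] * 17 + [1] * 3)
        with pytest.raises(ValueError, match="k_neighbors"):
            adasyn_balance(X, y, k_neighbors=5, seed=0)
        Xm = X.copy()
        Xm.loc[0, "f"] = np.nan
        with pytest.raises(ValueError):
            adasyn_balance(Xm, np.array([0] * 10 + [1] * 10), seed=0)
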