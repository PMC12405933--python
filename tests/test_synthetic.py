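"""Ground-truth spec construction, calibration, sampling and missingness."""

import numpy as np
import pandas as pd
import pytest

from exacbn.bayesnet import bayesnet_from_spec, counterfactual_compare
from exacbn.citest import g2_test
from exacbn.data import DiscreteData
from exacbn.graphs import CycleError
from exacbn.synthetic import (GroundTruthSpec, MissingnessRule, assign_country,
                              inject_missingness, make_ground_truth_network,
                              sample_cohort)


class TestGroundTruth:
    def test_core9_is_ten_node_acyclic_with_pathway_arcs(self, core9):
        assert len(core9.nodes) == 10
        dag = core9.dag()
        assert dag.is_dag()
        for arc in [("crs", "bec"), ("fev1pp", "feno"), ("bec", "feno"),
                    ("age", "crs"), ("sex", "crs"), ("age", "macrolide"),
                    ("prior_exac", "future_exac"),
                    ("macrolide", "future_exac")]:
            assert arc in dag.arcs

    def test_marginals_match_registry_table(self, core9):
        assert core9.marginal("sex")[0] == pytest.approx(0.612, abs=1e-6)
        assert core9.marginal("crs")[2] == pytest.approx(0.311, abs=1e-6)
        assert core9.marginal("macrolide")[1] == pytest.approx(0.119, abs=1e-6)

    def test_cpt_rows_sum_to_one(self, core9):
        for n, cpt in core9.cpts.items():
            rows = cpt.reshape(-1, cpt.shape[-1])
            np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-12)

    def test_cyclic_custom_spec_rejected(self, core9):
        with pytest.raises((CycleError, ValueError)):
            GroundTruthSpec(
                nodes=["a", "b"], levels={"a": ["0", "1"], "b": ["0", "1"]},
                parents={"a": ("b",), "b": ("a",)},
                cpts={"a": np.full((2, 2), 0.5), "b": np.full((2, 2), 0.5)})

    def test_bad_cpt_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GroundTruthSpec(
                nodes=["a"], levels={"a": ["0", "1"]}, parents={"a": ()},
                cpts={"a": np.array([0.5, 0.6])})

    def test_extended15_adds_consequence_nodes(self):
        ext = make_ground_truth_network("extended15")
        assert len(ext.nodes) == 15
        assert ("prior_exac", "er_visits") in ext.dag().arcs

    def test_json_round_trip(self, core9):
        back = GroundTruthSpec.from_json(core9.to_json())
        assert back.nodes == core9.nodes
        for n in core9.nodes:
            np.testing.assert_allclose(back.cpts[n], core9.cpts[n])
        assert back.country.multipliers == core9.country.multipliers


class TestSampling:
    def test_reproducible_and_marginally_calibrated(self, core9):
        a = sample_cohort(core9, 50000, seed=1)
        b = sample_cohort(core9, 50000, seed=1)
        pd.testing.assert_frame_equal(a, b)
        assert (a.sex == "Female").mean() == pytest.approx(0.612, abs=0.01)

    def test_point_mass_sex(self, core9):
        spec = GroundTruthSpec.from_json(core9.to_json())
        spec.cpts["sex"] = np.array([1.0, 0.0])
        df = sample_cohort(spec, 500, seed=3)
        assert (df.sex == "Female").all()

    def test_value_ranges(self, cohort_20k):
        df = cohort_20k
        assert (df.age >= 18).all()
        assert (df[["bec", "feno", "ige"]] >= 0).all().all()
        assert df.fev1pp.between(0, 200, inclusive="neither").all()
        assert set(df.future_exac.unique()) <= {0, 1, 2}

    def test_joint_factorizes_over_dag(self, core9):
        # empirical P(node | parents) at n=100k within ±0.02 of the spec CPT
        df = sample_cohort(core9, 100_000, seed=7)
        bands = {n: pd.Categorical(core9.discretize(df)[n]).codes
                 for n in core9.nodes}
        for node in ("crs", "bec", "feno", "prior_exac", "future_exac"):
            cpt = core9.cpts[node]
            ps = core9.parents[node]
            idx = np.zeros(len(df), dtype=np.int64)
            for j, p in enumerate(ps):
                idx = idx * cpt.shape[j] + bands[p]
            flat = cpt.reshape(-1, cpt.shape[-1])
            for cfg in range(flat.shape[0]):
                sel = idx == cfg
                if sel.sum() < 500:
                    continue
                emp = np.bincount(bands[node][sel],
                                  minlength=cpt.shape[-1]) / sel.sum()
                tol = np.maximum(0.02, 4.5 * np.sqrt(
                    flat[cfg] * (1 - flat[cfg]) / sel.sum()))
                assert (np.abs(emp - flat[cfg]) < tol).all(), (node, cfg)

    def test_faithfulness_sex_indep_macrolide_given_age(self, core9):
        # G² fails to reject Sex ⫫ Macrolide | Age in >= 90% of 50 runs
        keep = 0
        for seed in range(50):
            df = sample_cohort(core9, 50000, seed=1000 + seed)
            d = DiscreteData.from_dataframe(core9.discretize(df),
                                            ["sex", "macrolide", "age"])
            res = g2_test("sex", "macrolide", ("age",), d)
            keep += res.p_value > 0.01
        assert keep >= 45

    def test_spec_counterfactual_is_monotone(self, core9):
        net = bayesnet_from_spec(core9)
        cf = counterfactual_compare(net, "crs", ["None", "CRSwoNP", "CRSwNP"])
        assert cf.p_ge1.is_monotonic_increasing
        assert cf.p_ge1.nunique() == 3


class TestMissingness:
    def test_mcar_rate_within_binomial_band(self, core9):
        df = sample_cohort(core9, 10000, seed=5)
        out = inject_missingness(df, [MissingnessRule("bec", 0.20)], seed=6)
        assert 0.19 <= out.bec.isna().mean() <= 0.21

    def test_zero_rate_is_identity(self, core9, cohort_20k):
        out = inject_missingness(cohort_20k, [MissingnessRule("bec", 0.0)],
                                 seed=1)
        pd.testing.assert_frame_equal(out, cohort_20k)

    def test_mar_rates_differ_by_configured_odds(self, core9):
        df = sample_cohort(core9, 40000, seed=8)
        rule = MissingnessRule("feno", 0.2, "mar", driver="crs", odds=3.0)
        out = inject_missingness(df, [rule], seed=9)
        rates = out.feno.isna().groupby(df.crs, observed=True).mean()
        # odds multiplier applies along the driver's categorical code order
        by_code = [rates[lev] for lev in
                   pd.Categorical(df.crs).categories]
        odds = [r / (1 - r) for r in by_code]
        assert odds[1] / odds[0] == pytest.approx(3.0, rel=0.2)
        assert odds[2] / odds[1] == pytest.approx(3.0, rel=0.2)

    def test_outcome_never_masked_and_driver_protected(self, cohort_20k):
        with pytest.raises(ValueError):
            inject_missingness(cohort_20k,
                               [MissingnessRule("future_exac", 0.1)], seed=1)
        with pytest.raises(ValueError):
            inject_missingness(
                cohort_20k,
                [MissingnessRule("feno", 0.1, "mar", driver="crs"),
                 MissingnessRule("crs", 0.1)], seed=1)


class TestCountry:
    def test_label_coverage(self, core9, cohort_20k):
        out = assign_country(cohort_20k.head(2000), core9, 2, 0.3, seed=1)
        assert out.country.nunique() == 2

    def test_zero_effect_keeps_rates_flat_and_sd_raises_variance(self, core9):
        df = sample_cohort(core9, 100_000, seed=13)
        flat = assign_country(df, core9, 10, 0.0, seed=2)
        bumpy = assign_country(df, core9, 10, 0.3, seed=2)
        var_flat = flat.groupby("country")["future_exac"] \
            .apply(lambda s: (s >= 1).mean()).var()
        var_bumpy = bumpy.groupby("country")["future_exac"] \
            .apply(lambda s: (s >= 1).mean()).var()
        assert var_bumpy > var_flat

    def test_needs_two_countries(self, core9, cohort_20k):
        with pytest.raises(ValueError):
            assign_country(cohort_20k, core9, 1, 0.2, seed=1)
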