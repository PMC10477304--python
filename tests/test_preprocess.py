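"""The six-step chain: each step against its oracle, then the chain contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

import microdyn as md
from microdyn.containers import FeatureTable
from microdyn.exceptions import DegenerateFeatureError, InvalidInputError
from microdyn.preprocess import (
    clip_outliers,
    filter_diet_days,
    filter_low_prevalence,
    impute_paired_minimum,
    log10_transform,
    pc_batch_correct,
    robust_standardize,
    run_preprocessing,
    summarize_diet_periods,
)

from conftest import make_table


def robust_oracle(values, central_fraction=0.90):
    """Brute-force trim-then-moments oracle for the robust standardization."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    tail = 100 * (1 - central_fraction) / 2
    lo = np.percentile(v, tail)
    hi = np.percentile(v, 100 - tail)
    central = sorted(x for x in v if lo <= x <= hi)
    return np.median(central), np.std(central, ddof=1)


class TestLog10:
    def test_known_values(self):
        table = make_table(np.array([[100.0, 1.0], [10.0, 0.0]]))
        out = log10_transform(table)
        assert out.values.iloc[0, 0] == pytest.approx(2.0)
        assert out.values.iloc[0, 1] == pytest.approx(0.0)
        assert np.isnan(out.values.iloc[1, 1])  # zero -> missing

    def test_negative_rejected_with_location(self):
        table = make_table(np.array([[1.0, -2.0], [1.0, 1.0]]))
        with pytest.raises(InvalidInputError, match="f1"):
            log10_transform(table)


class TestRobustStandardize:
    def test_one_to_twenty_oracle(self):
        """1..20 trims to 2..19; the centre point 10.5 maps to 0."""
        v = np.arange(1.0, 21.0)
        m, s = robust_oracle(v)
        assert m == 10.5
        out = robust_standardize(v)
        np.testing.assert_allclose(out, (v - m) / s, atol=1e-12)
        assert out[9] + out[10] == pytest.approx(0.0, abs=1e-12)  # 10 and 11 straddle 10.5

    def test_symmetric_input_centred(self):
        v = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        out = robust_standardize(v)
        assert np.median(out) == pytest.approx(0.0, abs=1e-12)

    def test_all_equal_degenerate(self):
        with pytest.raises(DegenerateFeatureError):
            robust_standardize(np.full(10, 3.14))

    def test_too_few_values_degenerate(self):
        with pytest.raises(DegenerateFeatureError):
            robust_standardize(np.array([1.0, 2.0]))

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=5,
            max_size=80,
        )
    )
    def test_matches_oracle_on_random_vectors(self, values):
        v = np.array(values)
        m, s = robust_oracle(v)
        assume(s > 1e-9)
        np.testing.assert_allclose(robust_standardize(v), (v - m) / s, atol=1e-12)

    def test_nan_passthrough(self):
        v = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        out = robust_standardize(v)
        assert np.isnan(out[2]) and not np.isnan(out[0])


class TestClip:
    @pytest.mark.parametrize(
        "value,expected", [(6.2, 5.0), (-4.9, -4.9), (-7.0, -5.0), (5.0, 5.0)]
    )
    def test_bounds(self, value, expected):
        assert clip_outliers(np.array([value]))[0] == expected

    def test_infinite_k_is_identity(self):
        v = np.array([-100.0, 0.0, 100.0])
        np.testing.assert_array_equal(clip_outliers(v, k=np.inf), v)


class TestPrevalenceFilter:
    def test_boundary_at_min_samples(self):
        values = np.full((25, 2), 1.0)
        values[:6, 0] = np.nan  # feature present in 19 samples -> removed
        values[:5, 1] = np.nan  # present in 20 -> retained
        participants = [f"P{i}" for i in range(25)]
        table = make_table(values, timepoints=["pre"] * 25, participants=participants)
        out, removed = filter_low_prevalence(table, min_samples=20)
        assert removed == ["f0"]
        assert list(out.values.columns) == ["f1"]
        assert (out.values.notna().sum() >= 20).all()

    def test_empty_table(self):
        table = make_table(np.empty((4, 0)))
        out, removed = filter_low_prevalence(table)
        assert out.n_features == 0 and removed == []


class TestPairedImputation:
    def _table(self):
        # P000: pre missing / post present; P001: both missing; P002 complete
        values = np.array(
            [[np.nan, 1.0], [5.0, 2.0], [np.nan, 3.0], [np.nan, 4.0], [2.0, 5.0], [7.0, 6.0]]
        )
        return make_table(values)

    def test_fills_only_with_complement_present(self):
        out, n = impute_paired_minimum(self._table())
        assert n == 1
        assert out.values.iloc[0, 0] == 2.0  # feature minimum
        assert out.imputed.iloc[0, 0]
        assert np.isnan(out.values.iloc[2, 0]) and np.isnan(out.values.iloc[3, 0])

    def test_identity_when_nothing_missing(self):
        table = make_table(np.arange(12.0).reshape(6, 2) + 1)
        out, n = impute_paired_minimum(table)
        assert n == 0
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_imputed_value_is_feature_minimum(self):
        out, _ = impute_paired_minimum(self._table())
        assert out.values.iloc[0, 0] == self._table().values["f0"].min()


class TestBatchCorrection:
    def _planted(self, shift, n=60, m=40, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, m))
        v = rng.normal(0, 1, m)
        v /= np.linalg.norm(v)
        batches = np.repeat([0, 1], n // 2)
        X += shift * np.outer(batches - batches.mean(), v)
        participants = [f"P{i}" for i in range(n)]
        table = make_table(
            X, timepoints=["pre"] * n, participants=participants, batch=batches
        )
        return table, v, batches

    def test_no_batch_structure_removes_nothing(self):
        table, _, batches = self._planted(shift=0.0)
        out, removed = pc_batch_correct(table, batches)
        assert removed == []
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_planted_shift_removed(self):
        table, v, batches = self._planted(shift=6.0)
        out, removed = pc_batch_correct(table, batches)
        assert len(removed) == 1
        # residual variance along the planted direction collapses
        before = np.var(table.values.to_numpy() @ v)
        after = np.var(out.values.to_numpy() @ v)
        assert after < 0.1 * before

    def test_two_planted_components_removed(self):
        table, v, batches = self._planted(shift=6.0, seed=3)
        rng = np.random.default_rng(99)
        w = rng.normal(0, 1, table.n_features)
        w -= w @ v * v
        w /= np.linalg.norm(w)
        plates = np.tile([0, 1], table.n_samples // 2)
        table.values += 6.0 * np.outer(plates - plates.mean(), w)
        combined = batches * 2 + plates
        out, removed = pc_batch_correct(table, combined)
        assert len(removed) == 2


class TestChain:
    def test_diet_assay_gets_steps_three_and_four_only(self, cohort):
        rng = np.random.default_rng(1)
        n = 2 * len(cohort)
        values = rng.normal(100, 10, (n, 3))
        meta = md.sample_pairing(cohort).assign(assay="diet", batch=0)
        table = FeatureTable(
            pd.DataFrame(values, index=meta.index, columns=["kcal", "carb", "fat"]),
            meta,
            pd.DataFrame({"assay": "diet"}, index=["kcal", "carb", "fat"]),
        )
        out, audit = run_preprocessing(table, min_samples=5)
        assert audit["assays"]["diet"]["steps"] == ["clip", "filter"]
        # un-standardized: values keep their raw scale
        assert out.values.mean().mean() == pytest.approx(100, rel=0.1)

    def test_standardized_values_bounded(self, small_table):
        table, _ = small_table
        out, audit = run_preprocessing(table, min_samples=5)
        assert (out.values.abs().max() <= 5.0 + 1e-9).all()
        steps = audit["assays"]["gut_species"]["steps"]
        assert steps == ["log10", "standardize", "clip", "filter", "impute", "batch"]

    def test_rerun_removes_no_additional_components(self):
        """On batch-effect-free data wide enough that noise eigenvalues stay
        under the 5% variance gate, a second pass removes nothing."""
        cohort = md.generate_cohort(30, seed=77)
        panel = md.PanelSpec(
            n_gut_species=200, n_oral_species=0, n_gut_pathways=0,
            n_oral_pathways=0, n_metabolites=0, n_cytokines=0,
            missingness_rate=0.02,
        )
        table, _ = md.generate_paired_features(
            cohort, panel, md.EffectSpec(fraction_affected=0.0), seed=78
        )
        out, audit1 = run_preprocessing(table)
        again, audit2 = run_preprocessing(
            FeatureTable(10.0 ** out.values, out.sample_meta, out.feature_meta)
        )
        for audit in (audit1, audit2):
            removed = [
                len(a.get("removed_components", []))
                for a in audit["assays"].values()
            ]
            assert sum(removed) == 0

    def test_retained_features_meet_prevalence(self, small_table):
        table, _ = small_table
        out, _ = run_preprocessing(table, min_samples=5)
        assert (out.values.notna().sum() >= 5).all()


class TestDietDays:
    def _logs(self):
        return pd.DataFrame(
            {
                "participant_id": ["P1"] * 5,
                "date": [f"d{i}" for i in range(5)],
                "period": ["profiling"] * 5,
                "calories": [1000.0, 4900.0, 2000.0, 2000.0, 3000.0],
                "caloric_target": [2000.0, 2000.0, 2000.0, 2000.0, np.nan],
                "unmatched_fraction": [0.0, 0.0, 0.10, 0.25, 0.0],
                "carbohydrates_g": [100.0, 200.0, 100.0, 200.0, 150.0],
            }
        )

    def test_exclusion_rules(self):
        retained, excluded = filter_diet_days(self._logs())
        reasons = dict(zip(excluded["date"], excluded["reason"]))
        assert reasons == {
            "d0": "low_calories",   # 50% < 60%
            "d1": "high_calories",  # 245% > 240%
            "d3": "unmatched",      # 25% > 20%
            "d4": "no-target",
        }
        assert list(retained["date"]) == ["d2"]

    def test_exact_boundaries_retained(self):
        logs = self._logs().iloc[:2].copy()
        logs["calories"] = [1200.0, 4800.0]  # exactly 60% and 240%
        retained, excluded = filter_diet_days(logs)
        assert len(excluded) == 0 and len(retained) == 2

    def test_period_means(self):
        logs = pd.DataFrame(
            {
                "participant_id": ["P1", "P1", "P1"],
                "date": ["d0", "d1", "d2"],
                "period": ["profiling", "profiling", "intervention"],
                "calories": [1800.0, 2200.0, 2000.0],
                "caloric_target": 2000.0,
                "unmatched_fraction": 0.0,
                "carbohydrates_g": [100.0, 200.0, 130.0],
            }
        )
        summary = summarize_diet_periods(logs).set_index("period")
        assert summary.loc["profiling", "carbohydrates_g"] == 150.0
        assert summary.loc["profiling", "n_days_retained"] == 2
        assert summary.loc["intervention", "carbohydrates_g"] == 130.0

    def test_all_days_excluded_yields_missing_means(self):
        logs = self._logs().iloc[[0]]
        retained, _ = filter_diet_days(logs)
        summary = summarize_diet_periods(
            pd.concat([retained, self._logs().iloc[[2]]])
        )
        prof = summary[summary["period"] == "profiling"]
        assert (prof["n_days_retained"] >= 0).all()
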