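"""Rank transform, rank-lookup table, and logistic model fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from crcpanel.rank_model import (
    LogisticModel,
    RankTable,
    build_rank_table,
    fit_logistic,
    midrank_transform,
    predict_probabilities,
    predict_probability,
    rank_lookup,
)
from crcpanel.synthetic import SubjectRecord


def _subject(i, group, age, calb, fobt):
    return SubjectRecord(id=f"s{i}", cohort="development", group=group,
                         age=age, calb_od=calb, fobt_positive=fobt)


def _make_records(age, calb, fobt, y):
    return [
        _subject(i, "case" if yi else "control", a, c, bool(f))
        for i, (a, c, f, yi) in enumerate(zip(age, calb, fobt, y))
    ]


class TestMidrank:
    def test_simple_ordering(self):
        assert midrank_transform([5, 1, 3]).tolist() == [3, 1, 2]

    def test_tied_pair_gets_midrank(self):
        assert midrank_transform([0, 0, 7]).tolist() == [1.5, 1.5, 3]

    @given(st.lists(st.floats(0, 1e4, allow_nan=False), min_size=1,
                    max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_rank_sum_invariant(self, values):
        ranks = midrank_transform(values)
        n = len(values)
        assert ranks.sum() == pytest.approx(n * (n + 1) / 2)
        assert ranks.min() >= 1 and ranks.max() <= n

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            midrank_transform([])


class TestRankTable:
    def test_tied_zeros_collapse_to_one_entry(self):
        table = build_rank_table([0.0, 0.0, 10.0])
        assert table.calb_od.tolist() == [0.0, 10.0]
        assert table.rank.tolist() == [1.5, 3.0]

    def test_distinct_values_rank_one_to_n(self):
        table = build_rank_table([40.0, 10.0, 30.0, 20.0, 50.0])
        assert table.rank.tolist() == [1, 2, 3, 4, 5]

    def test_lookup_reproduces_midranks(self, rng):
        values = rng.integers(0, 40, size=60).astype(float)
        table = build_rank_table(values)
        ranks = midrank_transform(values)
        for v, r in zip(values, ranks):
            assert rank_lookup(table, v) == r

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            build_rank_table([-1.0, 2.0])

    def test_csv_round_trip_exact(self, tmp_path, rng):
        values = np.concatenate([[0.0] * 5, rng.uniform(1, 5000, 100)])
        table = build_rank_table(values)
        path = tmp_path / "ranks.csv"
        table.to_csv(path)
        back = RankTable.from_csv(path)
        np.testing.assert_array_equal(back.calb_od, table.calb_od)
        np.testing.assert_array_equal(back.rank, table.rank)
        assert back.n == table.n


class TestRankLookup:
    @pytest.fixture()
    def two_entry(self):
        return RankTable(calb_od=np.array([100.0, 200.0]),
                         rank=np.array([1.0, 2.0]), n=2)

    def test_linear_midpoint(self, two_entry):
        assert rank_lookup(two_entry, 150.0, "linear") == 1.5

    def test_closest_prefers_nearer_entry(self, two_entry):
        assert rank_lookup(two_entry, 190.0, "closest") == 2.0
        assert rank_lookup(two_entry, 101.0, "closest") == 1.0

    def test_out_of_range_clamps(self, two_entry):
        assert rank_lookup(two_entry, 0.0) == 1.0
        assert rank_lookup(two_entry, 1e6) == 2.0

    def test_worked_example_od_2224_rank_80(self, rng):
        # synthetic stand-in for the published lookup table: 326 pooled
        # values in which OD 2224 sits at midrank 80
        below = rng.uniform(0.0, 2223.0, 79)
        above = rng.uniform(2225.0, 5432.0, 246)
        values = np.concatenate([below, [2224.0], above])
        assert values.size == 326
        table = build_rank_table(values)
        assert rank_lookup(table, 2224.0, "closest") == 80.0
        assert rank_lookup(table, 2224.0, "linear") == 80.0

    def test_bad_method_and_negative_value(self, two_entry):
        with pytest.raises(ValueError):
            rank_lookup(two_entry, 150.0, "spline")
        with pytest.raises(ValueError):
            rank_lookup(two_entry, -5.0)


class TestFitLogistic:
    def test_null_data_gives_prevalence_intercept(self, rng):
        n = 400
        age = rng.normal(60, 10, n)
        calb = rng.uniform(0, 5000, n)
        fobt = rng.random(n) < 0.3
        y = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
        model = fit_logistic(_make_records(age, calb, fobt, y), 2)
        assert model.converged
        assert model.coefficients["intercept"] == pytest.approx(
            0.0, abs=3 * model.standard_errors["intercept"])
        for term in ("age", "fobt", "rank_calb"):
            assert abs(model.coefficients[term]) < \
                3 * model.standard_errors[term]

    def test_parameter_recovery_within_three_se(self, rng):
        n = 2000
        age = rng.normal(60, 10, n)
        calb = np.where(rng.random(n) < 0.3, 0.0,
                        rng.lognormal(7.0, 0.8, n))
        fobt = rng.random(n) < 0.4
        ranks = midrank_transform(calb)
        truth = {"intercept": -5.0, "age": 0.05, "fobt": 1.2,
                 "rank_calb": 0.002}
        eta = (truth["intercept"] + truth["age"] * age + truth["fobt"] * fobt
               + truth["rank_calb"] * ranks)
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        model = fit_logistic(_make_records(age, calb, fobt, y), 2)
        assert model.converged
        for term, value in truth.items():
            assert model.coefficients[term] == pytest.approx(
                value, abs=3 * model.standard_errors[term])

    def test_tiny_fit_matches_independent_optimizer(self):
        age = [55, 62, 70, 48, 66, 51, 59, 73]
        calb = [0, 1200, 2500, 0, 3100, 150, 900, 4000]
        fobt = [0, 1, 1, 0, 0, 0, 1, 1]
        y = [0, 1, 1, 0, 1, 0, 0, 1]
        records = _make_records(age, calb, fobt, y)
        model = fit_logistic(records, 2)
        X = np.column_stack([np.ones(8), age, fobt, midrank_transform(calb)])
        yv = np.asarray(y, dtype=float)

        def nll(beta):
            eta = X @ beta
            return float(np.sum(np.log1p(np.exp(-np.abs(eta)))
                                + np.maximum(eta, 0) - yv * eta))

        oracle = minimize(nll, np.zeros(4), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12,
                                   "maxiter": 20000})
        assert model.log_likelihood == pytest.approx(-oracle.fun, abs=1e-6)

    def test_single_class_rejected(self):
        records = _make_records([50, 60], [0, 10], [0, 1], [1, 1])
        with pytest.raises(ValueError):
            fit_logistic(records, 1)

    def test_complete_separation_reported(self):
        age = [40.0] * 6 + [80.0] * 6
        y = [0] * 6 + [1] * 6
        records = _make_records(age, [0] * 12, [0] * 12, y)
        model = fit_logistic(records, 1)
        assert not model.converged
        assert "separation" in model.diagnostics
        with pytest.raises(ValueError, match="non-converged"):
            predict_probability(model, records[0])

    def test_firth_fallback_stays_finite(self):
        age = [40.0] * 6 + [80.0] * 6
        y = [0] * 6 + [1] * 6
        records = _make_records(age, [0] * 12, [0] * 12, y)
        model = fit_logistic(records, 1, firth=True)
        assert model.converged
        assert np.isfinite(list(model.coefficients.values())).all()


class TestPredict:
    def test_all_zero_coefficients_give_half(self, small_cohort):
        fitted = fit_logistic(small_cohort, 2)
        model = LogisticModel(
            model=2,
            coefficients={k: 0.0 for k in fitted.coefficients},
            standard_errors=fitted.standard_errors,
            log_likelihood=0.0, converged=True,
            n_case=fitted.n_case, n_control=fitted.n_control,
            rank_table=fitted.rank_table)
        assert predict_probability(model, small_cohort[0]) == 0.5

    def test_in_sample_predictions_match_fit(self, small_cohort):
        model = fit_logistic(small_cohort, 2)
        probs = predict_probabilities(model, small_cohort)
        # recompute from the design directly
        ranks = midrank_transform([r.calb_od for r in small_cohort])
        c = model.coefficients
        eta = (c["intercept"]
               + c["age"] * np.array([r.age for r in small_cohort])
               + c["fobt"] * np.array([r.fobt_positive for r in small_cohort])
               + c["rank_calb"] * ranks)
        np.testing.assert_allclose(probs, 1 / (1 + np.exp(-eta)), atol=1e-12)

    def test_probability_monotone_in_calb(self, small_cohort):
        model = fit_logistic(small_cohort, 2)
        if model.coefficients["rank_calb"] <= 0:
            pytest.skip("needs a positive marker coefficient")
        base = small_cohort[0]
        grid = [0.0, 500.0, 1500.0, 3000.0, 6000.0]
        probs = []
        for od in grid:
            subject = SubjectRecord(id="x", cohort="development",
                                    group=base.group, age=base.age,
                                    calb_od=od,
                                    fobt_positive=base.fobt_positive,
                                    t_stage=base.t_stage, site=base.site)
            probs.append(predict_probability(model, subject))
        assert all(b >= a for a, b in zip(probs, probs[1:]))


class TestModelInvariants:
    def test_rank_invariance_under_monotone_transform(self, small_cohort):
        model_raw = fit_logistic(small_cohort, 2)
        transformed = [
            SubjectRecord(id=r.id, cohort=r.cohort, group=r.group, age=r.age,
                          calb_od=float(np.expm1(r.calb_od / 1000.0)),
                          fobt_positive=r.fobt_positive,
                          t_stage=r.t_stage, site=r.site)
            for r in small_cohort
        ]
        model_tr = fit_logistic(transformed, 2)
        assert model_tr.log_likelihood == pytest.approx(
            model_raw.log_likelihood, abs=1e-8)
        np.testing.assert_allclose(
            predict_probabilities(model_tr, transformed),
            predict_probabilities(model_raw, small_cohort), atol=1e-8)

    def test_nesting_improves_log_likelihood(self, dev_cohort):
        ll1 = fit_logistic(dev_cohort, 1).log_likelihood
        ll2 = fit_logistic(dev_cohort, 2).log_likelihood
        assert ll2 >= ll1 - 1e-9
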