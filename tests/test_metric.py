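"""Metric construction: pruning, BIC wrapper, Poisson scaling, scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sleepacuity import metric
from sleepacuity.errors import InputError, SelectionError

FEATS = ("logical_reasoning.correct_pct", "pvt.crt_sd", "one_back.crt_sd")


def random_matrix(rng, n=60, extra=()):
    cols = {
        "pvt.rt_mean": rng.normal(400, 40, n),
        "pvt.crt_sd": rng.normal(200, 25, n),
        "logical_reasoning.correct_pct": rng.uniform(40, 100, n),
        "one_back.crt_sd": rng.normal(600, 70, n),
        "math_processing.correct_pct": rng.uniform(40, 100, n),
    }
    cols.update(extra)
    return pd.DataFrame(cols)


class TestPrune:
    def test_absolute_rt_features_removed(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, extra={"pvt.crt_mean": rng.normal(380, 30, 60)})
        out = metric.prune_features(m)
        assert "pvt.rt_mean" not in out.columns
        assert "pvt.crt_mean" not in out.columns
        assert "pvt.crt_sd" in out.columns

    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng)
        m["math_processing.crt_sd"] = m["one_back.crt_sd"].to_numpy()  # exact copy
        out = metric.prune_features(m)
        assert "one_back.crt_sd" in out.columns  # earlier-listed column survives
        assert "math_processing.crt_sd" not in out.columns

    def test_independent_columns_retained(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, n=400)
        out = metric.prune_features(m)
        assert set(out.columns) == set(m.columns) - {"pvt.rt_mean"}

    def test_too_small_matrix_rejected(self):
        with pytest.raises(InputError):
            metric.prune_features(pd.DataFrame({"pvt.crt_sd": [1.0, 2.0]}))


class TestBic:
    def test_known_values(self):
        assert metric.bic(10, 10.0, 0) == pytest.approx(0.0)
        assert metric.bic(10, 10.0, 1) == pytest.approx(np.log(10))

    def test_penalty_strictly_increases(self):
        assert metric.bic(50, 123.4, 3) > metric.bic(50, 123.4, 2)

    def test_zero_rss_sentinel(self):
        with pytest.warns(RuntimeWarning):
            assert metric.bic(10, 0.0, 1) == float("-inf")


class TestPoissonScale:
    def test_constant_samples_match_published_scales(self):
        assert metric.poisson_scale(np.full(20, 100.0)) == pytest.approx(200.0)
        assert metric.poisson_scale(np.full(20, 300.0)) == pytest.approx(600.0)

    def test_estimator_consistency(self):
        rng = np.random.default_rng(7)
        x = rng.poisson(150.0, 10_000).astype(float)
        x[x == 0] = 1.0
        assert metric.poisson_scale(x) == pytest.approx(300.0, abs=5.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(InputError):
            metric.poisson_scale(np.linspace(-1, 10, 20))


class TestWrapper:
    def test_three_columns_enumerate_seven_subsets(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame({f"a.f{i}": rng.normal(size=30) for i in range(3)})
        y = rng.normal(size=30)
        ranked = metric.wrapper_search(m, y, cv_folds=3)
        assert len(ranked) == 7

    def test_planted_signal_recovered(self):
        # BIC consistency needs a non-trivial sample: the ln(n) penalty must
        # dominate the chi-square fluctuation a decoy feature can absorb
        rng = np.random.default_rng(11)
        n = 500
        m = pd.DataFrame({f"x.f{i}": rng.normal(size=n) for i in range(8)})
        y = 2.0 * m["x.f1"] - 1.5 * m["x.f4"] + 0.8 * m["x.f6"] + rng.normal(0, 0.1, n)
        ranked = metric.wrapper_search(m, y, cv_folds=5, seed=0)
        assert set(ranked[0].features) == {"x.f1", "x.f4", "x.f6"}

    def test_ranking_invariant_to_row_shuffling(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame({f"a.f{i}": rng.normal(size=40) for i in range(4)})
        y = pd.Series(rng.normal(size=40))
        base = [r.features for r in metric.wrapper_search(m, y, seed=9)]
        perm = rng.permutation(40)
        shuffled = [r.features for r in
                    metric.wrapper_search(m.iloc[perm].reset_index(drop=True), y.iloc[perm].to_numpy(), seed=9)]
        assert base == shuffled

    def test_enumeration_guard(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame({f"a.f{i}": rng.normal(size=30) for i in range(21)})
        with pytest.raises(InputError, match="prune"):
            metric.wrapper_search(m, rng.normal(size=30))

    def test_bic_matches_independent_ols_route(self):
        """Oracle: statsmodels OLS residuals reproduce every subset's BIC."""
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = 50
        m = pd.DataFrame({f"q.f{i}": rng.normal(size=n) for i in range(5)})
        y = m["q.f0"] - m["q.f3"] + rng.normal(0, 0.5, n)
        ranked = metric.wrapper_search(m, y, cv_folds=5, seed=0)
        expected = {}
        for size in range(1, 6):
            for subset in itertools.combinations(m.columns, size):
                X = sm.add_constant(m[list(subset)].to_numpy())
                rss = float(sm.OLS(np.asarray(y), X).fit().ssr)
                expected[subset] = n * np.log(rss / n) + (len(subset) + 1) * np.log(n)
        assert len(ranked) == len(expected)
        for r in ranked:
            assert r.bic == pytest.approx(expected[r.features], abs=1e-8)


class TestSelectFinal:
    def ranked(self, *feature_sets):
        return [metric.WrapperResult(features=f, bic=float(i), cv_rmse=1.0)
                for i, f in enumerate(feature_sets)]

    def test_first_compliant_subset_selected(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng)
        ranked = self.ranked(
            ("logical_reasoning.correct_pct", "math_processing.correct_pct"),  # 2 assessments
            ("logical_reasoning.correct_pct", "one_back.crt_sd", "math_processing.correct_pct"),  # no PVT
            FEATS,
        )
        md = metric.select_final(ranked, m)
        assert md.features == FEATS
        assert md.transforms["pvt.crt_sd"] == "reciprocal_spread"
        assert md.transforms["logical_reasoning.correct_pct"] == "percentage"
        assert md.two_lambda["pvt.crt_sd"] == pytest.approx(
            metric.poisson_scale(m["pvt.crt_sd"]), rel=1e-12
        )

    def test_selection_never_violates_constraints(self):
        rng = np.random.default_rng(13)
        pool = ["pvt.crt_sd", "pvt.rt_sd", "one_back.crt_sd", "one_back.correct_pct",
                "logical_reasoning.correct_pct", "math_processing.crt_sd"]
        m = pd.DataFrame({c: rng.normal(300, 30, 40) for c in pool}).abs()
        for trial in range(20):
            sets = []
            for _ in range(6):
                k = rng.integers(1, 5)
                sets.append(tuple(rng.choice(pool, size=k, replace=False)))
            try:
                md = metric.select_final(self.ranked(*sets), m)
            except SelectionError:
                continue
            assert md.is_compliant()

    def test_no_compliant_subset_raises(self):
        with pytest.raises(SelectionError):
            metric.select_final(self.ranked(("logical_reasoning.correct_pct",)), None)


class TestMentalAcuity:
    def test_scale_endpoint(self):
        md = metric.reference_definition()
        feats = {"logical_reasoning.correct_pct": 100.0, "pvt.crt_sd": 200.0,
                 "one_back.crt_sd": 600.0}
        assert metric.mental_acuity(feats, md) == pytest.approx(100.0, abs=1e-9)

    def test_no_responses_scores_zero(self):
        md = metric.reference_definition()
        feats = {f: float("nan") for f in md.features}
        assert metric.mental_acuity(feats, md) == 0.0

    def test_hand_evaluated_case(self):
        md = metric.reference_definition()
        feats = {"logical_reasoning.correct_pct": 60.0, "pvt.crt_sd": 400.0,
                 "one_back.crt_sd": 1200.0}
        assert metric.mental_acuity(feats, md) == pytest.approx(20 + 50 / 3 + 50 / 3)

    def test_spread_floor_prevents_blowup(self):
        md = metric.reference_definition()
        feats = {"logical_reasoning.correct_pct": 0.0, "pvt.crt_sd": 0.01,
                 "one_back.crt_sd": 0.01}
        capped = metric.mental_acuity(feats, md)
        expected = (100 / 3) * (200 + 600) / metric.SPREAD_FLOOR_MS / 100 * 100
        assert capped == pytest.approx((100 / 3) * (200 / metric.SPREAD_FLOOR_MS
                                                    + 600 / metric.SPREAD_FLOOR_MS))
        assert np.isfinite(capped) and capped == pytest.approx(expected)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        pct=st.floats(20, 100),
        sd1=st.floats(100, 1000),
        sd2=st.floats(300, 3000),
        bump=st.floats(1, 300),
    )
    def test_monotonicity(self, pct, sd1, sd2, bump):
        """Score never decreases when accuracy rises, never increases when
        spread widens."""
        md = metric.reference_definition()
        base = metric.mental_acuity(
            {"logical_reasoning.correct_pct": pct, "pvt.crt_sd": sd1, "one_back.crt_sd": sd2}, md)
        better_pct = metric.mental_acuity(
            {"logical_reasoning.correct_pct": min(pct + bump, 100), "pvt.crt_sd": sd1,
             "one_back.crt_sd": sd2}, md)
        wider_sd = metric.mental_acuity(
            {"logical_reasoning.correct_pct": pct, "pvt.crt_sd": sd1 + bump,
             "one_back.crt_sd": sd2}, md)
        assert better_pct >= base - 1e-12
        assert wider_sd <= base + 1e-12
        assert base >= 0.0


class TestDefinitionValidation:
    def test_spread_without_lambda_rejected(self):
        with pytest.raises(InputError):
            metric.MetricDefinition(
                features=("pvt.crt_sd",), transforms={"pvt.crt_sd": "reciprocal_spread"}
            )

    def test_round_trips_through_dict(self):
        md = metric.reference_definition()
        again = metric.MetricDefinition.from_dict(md.to_dict())
        assert again == md
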