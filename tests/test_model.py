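import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eyereg.features import FEATURE_NAMES
from eyereg.model import (ClassProbabilities, IregScore, ModelParameters,
                          RegularityModel, RegularityResults, TrainingTable,
                          anova_screen, builtin_parameters, builtin_results,
                          class_probabilities, compare_groups,
                          dispersion_summary, fit_multinomial, ireg,
                          ireg_from_features, linear_predictors, pca_cluster,
                          prune_correlated, robustness_check, stepwise_select)
from eyereg.synthetic import simulate_model_features
from oracles import kruskal_h_by_hand

# published coefficient matrix (classes 0-3 rows; intercept, distm,
# distskew, lognnvar columns)
TABLE_COEFS = np.array([
    [84.366, -13.681, 20.391, -17.321],
    [60.004, -11.097, 15.005, -6.976],
    [29.07, -4.448, 7.663, -3.308],
    [1.299, 0.242, -17.746, -0.104],
])


def feature_frame(n, rng, informative=None):
    data = pd.DataFrame(rng.normal(0, 1, (n, 18)), columns=FEATURE_NAMES)
    if informative is not None:
        for col, vals in informative.items():
            data[col] = vals
    return data


class TestLinearPredictors:
    def test_zero_coefficients(self):
        params = ModelParameters(np.zeros((4, 4)))
        assert np.allclose(linear_predictors([1.0, 2.0, 3.0], params), 0.0)

    def test_intercept_column_at_origin(self):
        a = linear_predictors([0.0, 0.0, 0.0])
        assert np.allclose(a, TABLE_COEFS[:, 0])

    def test_hand_arithmetic_triple(self):
        # frozen before implementation: a_i at (1.0, 0.5, -1.0)
        a = linear_predictors([1.0, 0.5, -1.0])
        assert np.allclose(a, [98.2015, 63.3855, 31.7615, -7.228], atol=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            linear_predictors([np.nan, 0.0, 0.0])


class TestClassProbabilities:
    def test_uniform_when_all_predictors_zero(self):
        params = ModelParameters(np.zeros((4, 4)))
        pp = class_probabilities([0.0, 0.0, 0.0], params)
        assert np.allclose(pp.pp, 0.2)

    def test_dominant_intercept_gives_class0(self):
        pp = class_probabilities([0.0, 0.0, 0.0])
        # a_0 = 84.366 dwarfs the rest; direct evaluation of the
        # softmax gives PP_0 = 1 to double precision
        assert pp.pp[0] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("triple", [
        (1.0, 0.5, -1.0), (5.0, 0.0, 2.0), (-3.0, 1.5, 4.0), (100.0, -50.0, 80.0)])
    def test_simplex_sum(self, triple):
        pp = class_probabilities(list(triple))
        assert pp.pp.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pp.pp >= 0).all()

    def test_overflow_safety(self):
        # predictors of order +-1e4 must not overflow
        pp = class_probabilities([-1000.0, 0.0, -1000.0])
        assert np.isfinite(pp.pp).all()
        assert pp.pp.sum() == pytest.approx(1.0, abs=1e-12)

    def test_simplex_validation(self):
        with pytest.raises(ValueError):
            ClassProbabilities(np.array([0.5, 0.5, 0.5, 0.0, 0.0]))


class TestIreg:
    @pytest.mark.parametrize("pp,expected", [
        ([1, 0, 0, 0, 0], 1.0),
        ([0, 0, 0, 0, 1], 0.0),
        ([0.2, 0.2, 0.2, 0.2, 0.2], 0.5),
        ([0, 1, 0, 0, 0], 0.75),
        ([0, 0, 0, 1, 0], 0.25),
    ])
    def test_weighting_formula(self, pp, expected):
        assert ireg(np.array(pp, float)).ireg == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5),
           st.integers(0, 3))
    def test_monotone_in_mass_shift(self, raw, src):
        # moving probability mass from a more-degenerate class to a
        # less-degenerate one never decreases the index
        p = np.array(raw) / np.sum(raw)
        for dst in range(src + 1, 5):
            q = p.copy()
            delta = q[dst] / 2
            q[dst] -= delta
            q[src] += delta
            assert ireg(q).ireg >= ireg(p).ireg - 1e-12

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            IregScore(1.5)


class TestModelParameters:
    def test_builtin_matches_published_table(self):
        params = builtin_parameters()
        assert np.allclose(params.coefficients, TABLE_COEFS)
        assert params.n_free == 16

    def test_reference_row_is_zero(self):
        frame = builtin_parameters().as_frame()
        assert frame.shape == (5, 4)
        assert np.allclose(frame.loc[4], 0.0)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ModelParameters(np.zeros((5, 4)))

    def test_results_predicts_like_functional_api(self, rng):
        res = builtin_results()
        X = rng.normal(0, 2, (10, 3))
        for x in X:
            assert res.predict_proba(x)[0] == pytest.approx(
                class_probabilities(x).pp, abs=1e-12)
            assert res.predict_ireg(x)[0] == pytest.approx(
                ireg_from_features(x), abs=1e-12)

    def test_summary_smoke(self):
        text = builtin_results().summary()
        assert "reference class 4" in text
        assert "84.366" in text


class TestPruneCorrelated:
    def test_identical_columns_reduced(self, rng):
        data = feature_frame(40, rng)
        data["MPCVAR"] = data["MPCM"]
        kept = prune_correlated(data, threshold=0.9)
        assert ("MPCM" in kept) != ("MPCVAR" in kept)

    def test_independent_columns_survive(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            data = feature_frame(200, rng)
            assert prune_correlated(data, threshold=0.9) == FEATURE_NAMES

    def test_planted_pair_detected(self, rng):
        cols = FEATURE_NAMES[:5]
        data = pd.DataFrame(rng.normal(0, 1, (300, 5)), columns=cols)
        data[cols[3]] = 0.95 * data[cols[1]] + \
            np.sqrt(1 - 0.95 ** 2) * rng.normal(0, 1, 300)
        # exhaustive all-pairs check: exactly one pair above threshold
        corr = np.corrcoef(data.to_numpy().T)
        hot = [(i, j) for i in range(5) for j in range(i + 1, 5)
               if abs(corr[i, j]) > 0.9]
        assert hot == [(1, 3)]
        kept = prune_correlated(data, threshold=0.9)
        assert len(kept) == 4
        assert (cols[1] in kept) != (cols[3] in kept)

    def test_constant_column_warned_and_dropped(self, rng):
        data = feature_frame(30, rng)
        data["TOTMAX"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            kept = prune_correlated(data)
        assert "TOTMAX" not in kept


class TestAnovaScreen:
    def test_hand_computed_toy(self):
        # groups {1,2,3} and {5,7,9}: SS_b=37.5, SS_w=10, F=15
        data = pd.DataFrame({"v": [1.0, 2.0, 3.0, 5.0, 7.0, 9.0]})
        groups = pd.Series(["a", "a", "a", "b", "b", "b"])
        rep = anova_screen(data, groups)
        assert rep.loc["v", "ss_between"] == pytest.approx(37.5)
        assert rep.loc["v", "ss_within"] == pytest.approx(10.0)
        assert rep.loc["v", "df_between"] == 1
        assert rep.loc["v", "df_within"] == 4
        assert rep.loc["v", "F"] == pytest.approx(15.0)

    def test_zero_within_variance_infinite_f(self):
        data = pd.DataFrame({"v": [1.0, 1.0, 2.0, 2.0]})
        rep = anova_screen(data, pd.Series(["a", "a", "b", "b"]))
        assert np.isinf(rep.loc["v", "F"])
        assert rep.loc["v", "p"] == 0.0

    def test_all_identical_zero_f(self):
        data = pd.DataFrame({"v": [3.0] * 6})
        rep = anova_screen(data, pd.Series(["a"] * 3 + ["b"] * 3))
        assert rep.loc["v", "F"] == 0.0

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            anova_screen(pd.DataFrame({"v": [1.0, 2.0, 3.0]}),
                         pd.Series(["a", "a", "b"]))


class TestPcaCluster:
    def test_separated_blobs_recovered(self, rng):
        centers = [-8.0, -4.0, 0.0, 4.0, 8.0]
        rows, truth = [], []
        for ci, c in enumerate(centers):
            for _ in range(12):
                rows.append({"DISTM": c + rng.normal(0, 0.3),
                             "LOGNNVAR": c + rng.normal(0, 0.3)})
                truth.append(ci)
        data = pd.DataFrame(rows)
        labels, evr = pca_cluster(data, n_classes=5)
        assert (labels.to_numpy() == np.array(truth)).all()
        assert evr[0] > 0.9

    def test_single_class(self, rng):
        data = pd.DataFrame({"DISTM": rng.normal(0, 1, 10),
                             "LOGNNVAR": rng.normal(0, 1, 10)})
        labels, _ = pca_cluster(data, n_classes=1)
        assert (labels == 0).all()

    def test_deterministic_on_duplicate_input(self, rng):
        data = pd.DataFrame({"DISTM": rng.normal(0, 3, 40),
                             "DISTSKEW": rng.normal(0, 1, 40),
                             "LOGNNVAR": rng.normal(0, 3, 40)})
        l1, _ = pca_cluster(data, 5)
        l2, _ = pca_cluster(data.copy(), 5)
        assert (l1 == l2).all()

    def test_orientation_class0_is_regular(self, rng):
        # class 0 must sit at the low-DISTM (regular) end
        rows, _ = [], None
        for c in [0.5, 2.0, 4.0, 6.0, 8.0]:
            for _ in range(10):
                rows.append({"DISTM": c + rng.normal(0, 0.2),
                             "LOGNNVAR": c + rng.normal(0, 0.2)})
        data = pd.DataFrame(rows)
        labels, _ = pca_cluster(data, 5)
        assert data.loc[labels == 0, "DISTM"].mean() < \
            data.loc[labels == 4, "DISTM"].mean()

    def test_too_few_rows(self, rng):
        data = pd.DataFrame({"DISTM": [1.0, 2.0], "LOGNNVAR": [0.0, 1.0]})
        with pytest.raises(ValueError):
            pca_cluster(data, 5)


class TestFitMultinomial:
    def test_refit_self_consistency(self):
        table = simulate_model_features(600, seed=3)
        res = fit_multinomial(table)
        X = table.data[["DISTM", "DISTSKEW", "LOGNNVAR"]].to_numpy()
        pred1 = res.predict_proba(X).argmax(axis=1)
        # refit on its own predicted classes: same classification back
        # (deterministic labels are separable, so a separation warning
        # is expected; the partition must still be reproduced)
        table2 = TrainingTable(data=table.data, cls=pd.Series(pred1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2 = fit_multinomial(table2)
        pred2 = res2.predict_proba(X).argmax(axis=1)
        assert (pred1 == pred2).mean() > 0.98

    def test_separation_flagged(self, rng):
        # a feature that separates the classes perfectly
        n = 100
        y = np.repeat(np.arange(5), n // 5)
        data = feature_frame(n, rng)
        data["DISTM"] = y * 10.0
        table = TrainingTable(data=data, cls=pd.Series(y))
        with pytest.warns(UserWarning, match="separation"):
            res = fit_multinomial(table, ["DISTM"])
        assert res.separation_flag

    def test_missing_class_rejected(self, rng):
        data = feature_frame(40, rng)
        table = TrainingTable(data=data, cls=pd.Series([0, 1, 2, 3] * 10))
        with pytest.raises(ValueError, match="5 classes"):
            fit_multinomial(table)

    def test_holdout_accuracy_reported(self):
        table = simulate_model_features(500, seed=4)
        model = RegularityModel(table)
        model.split(0.7, seed=1)
        res = model.fit()
        assert res.holdout_accuracy is not None
        assert res.holdout_accuracy > 0.7


class TestStepwise:
    def test_informative_variable_selected(self):
        hits = 0
        for seed in range(20):
            table = simulate_model_features(200, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            for noise_col in ("MPCM", "KURTM", "SKEWM", "MPCVAR"):
                table.data[noise_col] = rng.normal(0, 1, len(table.data))
            sel = stepwise_select(
                table, ["DISTM", "MPCM", "KURTM", "SKEWM", "MPCVAR"])
            if "DISTM" in sel and len(sel) <= 2:
                hits += 1
        assert hits >= 18

    def test_single_strong_candidate(self):
        table = simulate_model_features(300, seed=0)
        assert stepwise_select(table, ["DISTM"]) == ["DISTM"]

    def test_pure_noise_rarely_selected(self):
        overpicks = 0
        for seed in range(20):
            table = simulate_model_features(150, seed=seed)
            rng = np.random.default_rng(2000 + seed)
            noise_cols = ["MPCM", "KURTM", "SKEWM", "MPCVAR", "TOTMAX"]
            for c in noise_cols:
                table.data[c] = rng.normal(0, 1, len(table.data))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # empty selection warns
                sel = stepwise_select(table, noise_cols)
            if len(sel) > 1:
                overpicks += 1
        assert overpicks <= 2


class TestRobustness:
    def test_full_train_split_gives_zero_dispersion(self):
        table = simulate_model_features(400, seed=6)
        per = robustness_check(table, n_splits=3, seed=1, train_fraction=1.0)
        summ = dispersion_summary(per)
        # identical (full) training sets: refits coincide exactly
        assert summ["max_across_split_diff"] == pytest.approx(0.0, abs=1e-12)

    def test_single_split_dispersion_undefined(self):
        table = simulate_model_features(400, seed=6)
        per = robustness_check(table, n_splits=1, seed=1)
        assert np.isnan(dispersion_summary(per)["max_across_split_diff"])

    def test_group_separation_dwarfs_split_noise(self):
        table = simulate_model_features(450, seed=5)
        per = robustness_check(table, n_splits=3, seed=7)
        summ = dispersion_summary(per)
        assert summ["max_across_split_diff"] * 10 < summ["between_group_diff"]


class TestCompareGroups:
    def test_hand_rank_arithmetic(self):
        groups = {"a": np.array([1.0, 2.0, 3.0]),
                  "b": np.array([10.0, 11.0, 12.0]),
                  "c": np.array([20.0, 21.0, 22.0])}
        rep = compare_groups(groups)
        # rank sums 6, 15, 24 -> H = 12/90 * (36+225+576)/3 - 30 = 7.2
        assert rep["H"] == pytest.approx(7.2)
        assert rep["H"] == pytest.approx(
            kruskal_h_by_hand(list(groups.values())))

    def test_identical_groups_not_significant(self):
        rep = compare_groups({"a": np.array([1.0, 1.0, 1.0]),
                              "b": np.array([1.0, 1.0, 1.0])})
        assert rep["H"] == 0.0
        assert rep["p"] == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 12)
        r1 = compare_groups({"a": a, "b": b})
        r2 = compare_groups({"a": a + 100.0, "b": b + 100.0})
        assert r1["H"] == pytest.approx(r2["H"])

    def test_separated_groups_significant(self, rng):
        rep = compare_groups({"lo": rng.normal(0, 0.1, 15),
                              "hi": rng.normal(5, 0.1, 15)})
        assert rep["p"] < 0.01
        assert rep["pairwise"][0]["significant"]

    def test_adjustment_orders_p_values(self, rng):
        groups = {g: rng.normal(i, 1.0, 10) for i, g in enumerate("abcd")}
        raw = compare_groups(groups, adjust="none")
        bonf = compare_groups(groups, adjust="bonferroni")
        for p_raw, p_adj in zip(raw["pairwise"], bonf["pairwise"]):
            assert p_adj["p_adjusted"] >= p_raw["p_adjusted"] - 1e-15

    def test_input_validation(self):
        with pytest.raises(ValueError):
            compare_groups({"a": np.array([1.0])})
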