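"""Nearest-shrunken-centroid fit, shrinkage, prediction and CV."""

import math

import numpy as np
import pandas as pd
import pytest

from lncsig import nsc, simulate


@pytest.fixture
def worked_example():
    """One feature, classes A={1,3} and B={5,7}: every quantity is derivable
    by hand (d = -/+sqrt(2), m_k = 0.5, s0 = sqrt(2))."""
    X = pd.DataFrame([[1.0, 3.0, 5.0, 7.0]], index=["f1"],
                     columns=["a1", "a2", "b1", "b2"])
    y = pd.Series(["A", "A", "B", "B"], index=X.columns)
    return X, y


@pytest.fixture
def random_instance():
    rng = np.random.default_rng(12)
    X = pd.DataFrame(
        rng.normal(0, 1, size=(30, 12)),
        index=[f"f{i:02d}" for i in range(30)],
        columns=[f"s{i:02d}" for i in range(12)],
    )
    y = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=X.columns)
    return X, y


class TestFit:
    def test_hand_worked_quantities(self, worked_example):
        m = nsc.fit(*worked_example)
        r2 = math.sqrt(2)
        assert m.centroids[0].tolist() == [2.0, 6.0]
        assert m.overall[0] == 4.0
        assert m.s[0] == pytest.approx(r2, abs=1e-12)
        assert m.s0 == pytest.approx(r2, abs=1e-12)
        assert m.m_k.tolist() == [0.5, 0.5]
        assert m.d[0, 0] == pytest.approx(-r2, abs=1e-12)
        assert m.d[0, 1] == pytest.approx(r2, abs=1e-12)
        assert m.priors.tolist() == [0.5, 0.5]

    def test_sample_and_feature_order_invariance(self, random_instance):
        X, y = random_instance
        m1 = nsc.fit(X, y)
        rng = np.random.default_rng(0)
        cols = rng.permutation(X.columns)
        rows = rng.permutation(X.index)
        m2 = nsc.fit(X.loc[rows, cols], y[cols])
        order = [list(rows).index(f) for f in X.index]
        np.testing.assert_allclose(m1.d, m2.d[order], atol=1e-12)
        np.testing.assert_allclose(m1.s, m2.s[order], atol=1e-12)

    def test_swapping_class_labels_flips_d_signs(self, worked_example):
        X, y = worked_example
        m1 = nsc.fit(X, y)
        swapped = y.map({"A": "B", "B": "A"})
        m2 = nsc.fit(X, swapped)
        np.testing.assert_allclose(m1.d, m2.d[:, ::-1], atol=1e-12)

    def test_singleton_class_rejected(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=list("abc"))
        y = pd.Series(["A", "A", "B"], index=X.columns)
        with pytest.raises(ValueError, match="fewer than 2"):
            nsc.fit(X, y)

    def test_constant_feature_is_tolerated(self, random_instance):
        X, y = random_instance
        X = X.copy()
        X.iloc[0] = 5.0  # zero pooled SD; s0 offset keeps d finite
        m = nsc.fit(X, y)
        assert np.isfinite(m.d).all()

    def test_mk_matches_variance_of_centroid_deviation(self):
        """Monte-Carlo check that Var(xbar_k - xbar) = sigma^2 (1/n_k - 1/n)."""
        rng = np.random.default_rng(9)
        n_k, n, sigma = 5, 20, 1.0
        reps = 20_000
        x = rng.normal(0, sigma, size=(reps, n))
        dev = x[:, :n_k].mean(axis=1) - x.mean(axis=1)
        expected = sigma**2 * (1 / n_k - 1 / n)
        assert dev.var() == pytest.approx(expected, rel=0.05)


class TestShrink:
    def test_soft_threshold_arithmetic(self, worked_example):
        m = nsc.fit(*worked_example)
        m2 = nsc.shrink(m, 0.5)
        assert m2.d_shrunk[0, 0] == pytest.approx(-(math.sqrt(2) - 0.5), abs=1e-12)

    def test_full_shrinkage_collapses_to_overall_centroid(self, random_instance):
        X, y = random_instance
        m = nsc.fit(X, y)
        m2 = nsc.shrink(m, np.abs(m.d).max() + 1e-9)
        np.testing.assert_allclose(
            m2.shrunken_centroids, m.overall[:, None] * np.ones((1, 3)), atol=1e-12
        )

    def test_worked_shrunken_centroid(self, worked_example):
        m = nsc.shrink(nsc.fit(*worked_example), 1.0)
        # A centroid: 4 + 0.5 * (2*sqrt(2)) * -(sqrt(2)-1) = 4 - sqrt(2)*(sqrt(2)-1)
        assert m.shrunken_centroids[0, 0] == pytest.approx(
            4 - math.sqrt(2) * (math.sqrt(2) - 1), abs=1e-12
        )

    def test_shrunk_magnitude_never_exceeds_original(self, random_instance):
        X, y = random_instance
        m = nsc.fit(X, y)
        for delta in [0.0, 0.3, 1.0, 5.0]:
            m2 = nsc.shrink(m, delta)
            assert (np.abs(m2.d_shrunk) <= np.abs(m.d) + 1e-15).all()


class TestPredict:
    def test_sample_at_shrunken_centroid_wins(self, random_instance):
        X, y = random_instance
        m = nsc.shrink(nsc.fit(X, y, priors="uniform"), 0.5)
        probe = pd.DataFrame(
            m.shrunken_centroids[:, 1][:, None], index=X.index, columns=["q"]
        )
        assert nsc.predict(m, probe)["q"] == m.classes[1]

    def test_total_shrinkage_predicts_largest_prior(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            rng.normal(0, 1, size=(20, 9)),
            index=[f"f{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(9)],
        )
        y = pd.Series(["A"] * 5 + ["B"] * 2 + ["C"] * 2, index=X.columns)
        m = nsc.fit(X, y)
        m2 = nsc.shrink(m, np.abs(m.d).max() + 1.0)
        pred = nsc.predict(m2, X)
        assert (pred == "A").all()

    def test_matches_direct_formula_evaluation(self, random_instance):
        X, y = random_instance
        m = nsc.shrink(nsc.fit(X, y), 0.4)
        scores = nsc.discriminant_scores(m, X)
        sc = m.shrunken_centroids
        for si, sample in enumerate(X.columns):
            for j, k in enumerate(m.classes):
                expect = sum(
                    (X.iloc[i, si] - sc[i, j]) ** 2 / (m.s[i] + m.s0) ** 2
                    for i in range(X.shape[0])
                ) - 2 * math.log(m.priors[j])
                assert scores.loc[sample, k] == pytest.approx(expect, rel=1e-10)

    def test_zero_shrinkage_equals_standardized_nearest_centroid(self, random_instance):
        X, y = random_instance
        m = nsc.fit(X, y, priors="uniform")
        pred = nsc.predict(m, X)
        scale = m.s + m.s0
        Z = X.to_numpy() / scale[:, None]
        cz = m.centroids / scale[:, None]
        dist = ((Z[:, None, :] - cz[:, :, None]) ** 2).sum(axis=0)  # classes x samples
        oracle = [m.classes[j] for j in dist.argmin(axis=0)]
        assert list(pred) == oracle

    def test_missing_feature_rejected(self, random_instance):
        X, y = random_instance
        m = nsc.fit(X, y)
        with pytest.raises(KeyError):
            nsc.predict(m, X.iloc[1:])


class TestCrossValidation:
    def test_separable_classes_reach_zero_error(self):
        classes = {"A": 6, "B": 6}
        X, y, _ = simulate.simulate_signature_matrix(
            100, classes, 10, effect_size=20.0, seed=2
        )
        curve = nsc.cross_validate(X, y, grid=np.array([0.0, 0.5]))
        assert curve["error"].iloc[0] == 0.0

    def test_loo_curve_is_seed_independent(self):
        classes = {"A": 4, "B": 5}
        X, y, _ = simulate.simulate_signature_matrix(60, classes, 5, 3.0, seed=4)
        c1 = nsc.cross_validate(X, y, seed=1)
        c2 = nsc.cross_validate(X, y, seed=99)
        pd.testing.assert_frame_equal(c1, c2)

    def test_stratified_curve_reproducible_for_same_seed(self):
        classes = {"A": 10, "B": 10}
        X, y, _ = simulate.simulate_signature_matrix(80, classes, 5, 2.0, seed=4)
        c1 = nsc.cross_validate(X, y, folds=5, seed=7)
        c2 = nsc.cross_validate(X, y, folds=5, seed=7)
        pd.testing.assert_frame_equal(c1, c2)

    def test_selected_feature_count_non_increasing(self, random_instance):
        X, y = random_instance
        curve = nsc.cross_validate(X, y)
        assert (np.diff(curve["n_genes"]) <= 0).all()

    def test_per_class_errors_reported(self, random_instance):
        X, y = random_instance
        curve = nsc.cross_validate(X, y)
        for k in ["A", "B", "C"]:
            assert f"err_{k}" in curve
            assert curve[f"err_{k}"].between(0, 1).all()


class TestSelectThreshold:
    @pytest.mark.parametrize(
        "errors,expected",
        [
            ([0.3, 0.1, 0.1, 0.4], 2.0),  # largest delta at the minimum
            ([0.1, 0.2, 0.3, 0.4], 0.0),  # monotone increase: first point
            ([0.0, 0.0, 0.0, 0.0], 3.0),  # flat zero: maximal shrinkage
        ],
    )
    def test_rule_forced_curves(self, errors, expected):
        curve = pd.DataFrame({"delta": [0.0, 1.0, 2.0, 3.0], "error": errors})
        assert nsc.select_threshold(curve) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            nsc.select_threshold(pd.DataFrame(columns=["delta", "error"]))


class TestSelectedGenes:
    def test_zero_delta_keeps_everything_nonzero(self, random_instance):
        X, y = random_instance
        m = nsc.fit(X, y)
        sel = nsc.selected_genes(m, 0.0)
        assert len(sel) == (m.d != 0).any(axis=1).sum()

    def test_full_shrinkage_empties_the_signature(self, random_instance):
        X, y = random_instance
        m = nsc.fit(X, y)
        assert nsc.selected_genes(m, np.abs(m.d).max() + 1.0).empty

    def test_four_class_design_recovers_planted_features_at_generous_effect(self):
        """GF/RC/EC/EC-BSH-shaped design at 4-5 samples per class: strong
        planted signatures dominate the surviving feature set."""
        classes = {"GF": 4, "RC": 5, "EC": 4, "EC_BSH": 5}
        X, y, sig = simulate.simulate_signature_matrix(
            500, classes, 5, effect_size=8.0, seed=21
        )
        curve = nsc.cross_validate(X, y, seed=21)
        assert curve["error"].min() == 0.0
        delta = nsc.select_threshold(curve)
        chosen = set(nsc.selected_genes(nsc.fit(X, y), delta).index)
        planted = set().union(*sig.values())
        assert chosen  # signature survives at the operating threshold
        assert chosen <= planted
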