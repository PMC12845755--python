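"""Z-scores, PCA weights, the composite index Q, groups, and radar data."""

import numpy as np
import pandas as pd
import pytest

from pomoct.phantoms import make_quality_table
from pomoct.quality import (PCAResult, QualityTable, QualityWeights,
                            assign_groups, derive_weights, pca, quality_score,
                            radar_export, zscore)


def _table(params: pd.DataFrame, levels=None) -> QualityTable:
    levels = levels or ["x"] * (len(params) // 2) + ["y"] * (len(params)
                                                             - len(params) // 2)
    return QualityTable(params, pd.DataFrame({"f": levels}, index=params.index))


class TestZscore:
    def test_population_mode_hand_computed(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [0.0, 1, 5]})
        z, mu, sd = zscore(df, "population")
        assert list(np.round(z["a"], 4)) == [-1.2247, 0.0, 1.2247]
        assert mu["a"] == 2.0

    def test_columns_center_and_scale(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, (40, 3)), columns=list("abc"))
        for mode, ddof in (("population", 0), ("sample", 1)):
            z, _, _ = zscore(df, mode)
            assert np.allclose(z.mean(), 0.0, atol=1e-12)
            assert np.allclose(z.std(ddof=ddof), 1.0)

    def test_affine_rescaling_leaves_z_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        z1, _, _ = zscore(df)
        z2, _, _ = zscore(df * 7.3 - 41.0)
        assert np.allclose(z1, z2, atol=1e-9)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="zero variance"):
            zscore(df)


class TestPCA:
    def test_perfectly_correlated_pair_loads_one_component(self, rng):
        x = rng.normal(size=50)
        z, _, _ = zscore(pd.DataFrame({"a": x, "b": 3 * x + 1}))
        res = pca(z)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, rng):
        z, _, _ = zscore(pd.DataFrame(rng.normal(size=(30, 5))))
        res = pca(z)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_sign_convention_largest_loading_positive(self, rng):
        z, _, _ = zscore(pd.DataFrame(rng.normal(size=(30, 5))))
        res = pca(z)
        for col in res.loadings:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_planted_two_factor_structure_dominates_first_two_pcs(self):
        qt, _ = make_quality_table(seed=8)
        res = pca(zscore(qt)[0])
        assert res.explained_variance_ratio[:2].sum() > 0.6


def _fabricated_pca(loadings, varfrac):
    cols = [f"PC{i+1}" for i in range(loadings.shape[1])]
    return PCAResult(pd.DataFrame(loadings, columns=cols,
                                  index=[f"p{i}" for i in range(len(loadings))]),
                     np.asarray(varfrac), pd.DataFrame())


class TestWeights:
    def test_printed_single_component_example(self):
        res = _fabricated_pca(np.array([[0.9], [0.3], [0.1]]), [1.0])
        w = derive_weights(res, k=1)
        assert np.allclose(w.weights, [0.6923, 0.2308, 0.0769], atol=1e-4)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dominant_variable_gets_maximum_weight(self):
        res = _fabricated_pca(np.array([[0.9, 0.1], [0.2, 0.3], [0.1, 0.2]]),
                              [0.6, 0.3])
        w = derive_weights(res, k=2)
        assert w.weights.idxmax() == "p0"

    def test_symmetric_variables_share_weight(self):
        res = _fabricated_pca(np.array([[0.7, 0.2], [0.7, 0.2]]), [0.7, 0.3])
        w = derive_weights(res)
        assert w.weights.iloc[0] == pytest.approx(w.weights.iloc[1])

    def test_weights_nonnegative_and_normalized_on_random_tables(self):
        for seed in range(5):
            qt, _ = make_quality_table(seed=seed)
            w = derive_weights(pca(zscore(qt)[0]))
            assert (w.weights >= 0).all()
            assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_weights_rejected_by_container(self):
        with pytest.raises(ValueError):
            QualityWeights(pd.Series([0.5, 0.6]), 1, np.array([1.0]))


class TestQualityScore:
    def test_worked_three_parameter_example(self):
        z = pd.DataFrame([[1.0, -0.5, 2.0]], columns=list("abc"))
        w = QualityWeights(pd.Series([0.5, 0.3, 0.2], index=list("abc")),
                           1, np.array([1.0]))
        assert quality_score(z, w).q.iloc[0] == pytest.approx(0.75)

    def test_zero_row_scores_zero_and_one_hot_selects(self):
        z = pd.DataFrame([[0.0, 0.0], [1.3, -2.0]], columns=list("ab"))
        w = QualityWeights(pd.Series([0.0, 1.0], index=list("ab")),
                           1, np.array([1.0]))
        q = quality_score(z, w).q
        assert q.iloc[0] == 0.0 and q.iloc[1] == pytest.approx(-2.0)

    def test_parameter_mismatch_rejected(self):
        z = pd.DataFrame([[1.0]], columns=["a"])
        w = QualityWeights(pd.Series([1.0], index=["b"]), 1, np.array([1.0]))
        with pytest.raises(ValueError, match="mismatch"):
            quality_score(z, w)

    def test_q_invariant_under_affine_trait_rescaling(self, rng):
        qt, _ = make_quality_table(seed=4)
        z1, _, _ = zscore(qt)
        w = derive_weights(pca(z1))
        q1 = quality_score(z1, w).q
        scaled = qt.params * rng.uniform(0.5, 20, qt.params.shape[1]) \
            + rng.uniform(-100, 100, qt.params.shape[1])
        z2, _, _ = zscore(scaled)
        q2 = quality_score(z2, w).q
        assert np.max(np.abs(q1 - q2)) <= 1e-9

    def test_mean_q_is_zero_for_standardized_input(self):
        qt, _ = make_quality_table(seed=6)
        z, _, _ = zscore(qt)
        q = quality_score(z, derive_weights(pca(z))).q
        assert abs(q.mean()) < 1e-9


class TestGroupAssignment:
    @pytest.mark.parametrize("l1,l2,expected", [
        (0.9, 0.1, "A"), (0.1, 0.9, "C"), (0.5, 0.45, "B")])
    def test_dominance_rule(self, l1, l2, expected):
        res = _fabricated_pca(np.array([[l1, l2], [0.2, 0.2]]), [0.6, 0.3])
        assert assign_groups(res, dominance_margin=0.2)["p0"] == expected


class TestRadar:
    def test_best_level_scales_to_one(self):
        params = pd.DataFrame({"a": [1.0, 1, 5, 5], "b": [2.0, 2, 1, 1]},
                              index=list("wxyz"))
        qt = _table(params, ["lo", "lo", "hi", "hi"])
        radar = radar_export(qt, {"a": "A", "b": "C"}, "f")
        assert radar.values.loc["hi", "a"] == 1.0
        assert radar.values.loc["lo", "b"] == 1.0
        assert radar.axis_order == ["a", "b"]

    def test_equal_level_means_flagged_degenerate(self):
        params = pd.DataFrame({"a": [1.0, 2, 5, 6], "b": [3.0, 3, 3, 3]},
                              index=list("wxyz"))
        qt = _table(params, ["lo", "lo", "hi", "hi"])
        radar = radar_export(qt, {"a": "A", "b": "B"}, "f")
        assert radar.degenerate_axes == ["b"]
        assert np.all(radar.values["b"] == 0.0)

    def test_single_level_rejected(self):
        params = pd.DataFrame({"a": [1.0, 2], "b": [3.0, 4]}, index=list("xy"))
        qt = _table(params, ["only", "only"])
        with pytest.raises(ValueError, match="nothing to compare"):
            radar_export(qt, {"a": "A", "b": "B"}, "f")

    def test_planted_best_level_tops_its_group_axes(self):
        treatments = {"cond": {"poor": (-1.0, -1.0), "good": (1.0, 1.0)}}
        qt, truth = make_quality_table(n_per_level=50, treatments=treatments,
                                       seed=13)
        groups = truth.groups
        radar = radar_export(qt, groups, "cond")
        a_axes = [t for t, g in groups.items() if g == "A"]
        c_axes = [t for t, g in groups.items() if g == "C"]
        # factor shifts raise both latent factors for 'good'
        assert np.all(radar.values.loc["good", a_axes] == 1.0)
        assert np.all(radar.values.loc["good", c_axes] == 1.0)
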