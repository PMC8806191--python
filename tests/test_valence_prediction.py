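"""Latent-variable valence prediction: structure, fits, CV, weighting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from walisar.synthetic_data import generate_odor_panel
from walisar.valence_prediction import (
    OdorPanel, fit_latent_model, exploratory_structure, regress_valence,
    cross_validate, correlation_weights, learning_curve, adjusted_r2,
)


@pytest.fixture(scope="module")
def clean_panel():
    firing, valence, labels, _ = generate_odor_panel(
        n_odors=110, n_orns=23, n_latent=8, noise_sd=0.0, seed=0)
    return OdorPanel(firing=firing, valence=valence, class_label=labels)


@pytest.fixture(scope="module")
def noise_panel():
    rng = np.random.default_rng(1)
    firing = pd.DataFrame(rng.normal(100, 20, size=(60, 12)),
                          columns=[f"ORN_{j}" for j in range(12)])
    valence = pd.Series(rng.normal(size=60), index=firing.index)
    return OdorPanel(firing=firing, valence=valence)


class TestExploratoryStructure:
    def test_symmetric_unit_diagonal(self, clean_panel):
        corr, _ = exploratory_structure(clean_panel)
        c = corr.to_numpy()
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)

    def test_duplicated_column_merges_first(self, noise_panel):
        firing = noise_panel.firing.copy()
        firing["dup"] = firing["ORN_0"]
        panel = OdorPanel(firing=firing, valence=noise_panel.valence)
        corr, tree = exploratory_structure(panel)
        assert corr.loc["ORN_0", "dup"] == pytest.approx(1.0)
        # the first merge in the tree is at ~zero correlation distance
        assert tree[0, 2] == pytest.approx(0.0, abs=1e-10)

    def test_independent_columns_near_zero(self, noise_panel):
        corr, _ = exploratory_structure(noise_panel)
        off = corr.to_numpy()[~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 0.45

    def test_constant_column_flagged(self, noise_panel):
        firing = noise_panel.firing.copy()
        firing["flat"] = 7.0
        panel = OdorPanel(firing=firing, valence=noise_panel.valence)
        with pytest.warns(UserWarning, match="constant"):
            corr, _ = exploratory_structure(panel)
        assert corr["flat"].drop("flat").isna().all()


class TestLatentModel:
    def test_separated_classes_separate_on_lv1(self):
        rng = np.random.default_rng(2)
        n = 60
        labels = np.where(np.arange(n) < n // 2, "attractive", "aversive")
        shift = np.where(labels == "attractive", 3.0, -3.0)
        firing = pd.DataFrame(rng.normal(size=(n, 10)) + shift[:, None])
        panel = OdorPanel(firing=firing,
                          valence=pd.Series(shift, index=firing.index),
                          class_label=pd.Series(labels, index=firing.index))
        lm = fit_latent_model(panel, n_components=2)
        r = stats.pointbiserialr(labels == "attractive", lm.scores[:, 0])
        assert abs(r.statistic) > 0.8

    def test_permuted_labels_do_not_separate(self, clean_panel):
        rng = np.random.default_rng(3)
        perm = OdorPanel(
            firing=clean_panel.firing, valence=clean_panel.valence,
            class_label=pd.Series(
                rng.permutation(clean_panel.class_label.to_numpy()),
                index=clean_panel.firing.index))
        lm = fit_latent_model(perm, n_components=2)
        r = stats.pointbiserialr(perm.class_label == "attractive",
                                 lm.scores[:, 0])
        assert abs(r.statistic) < 0.35

    def test_single_class_rejected(self, noise_panel):
        panel = OdorPanel(firing=noise_panel.firing,
                          valence=pd.Series(1.0, index=noise_panel.firing.index))
        with pytest.raises(ValueError):
            fit_latent_model(panel)

    def test_component_bound(self, noise_panel):
        with pytest.raises(ValueError):
            fit_latent_model(noise_panel, n_components=13)


class TestRegressValence:
    def test_exact_linear_valence(self, clean_panel):
        lm = fit_latent_model(clean_panel, n_components=8)
        _, adj = regress_valence(lm, clean_panel, regressor="linear")
        assert adj > 0.99

    def test_equal_weights_match_unweighted(self, clean_panel):
        lm = fit_latent_model(clean_panel, n_components=8)
        _, a = regress_valence(lm, clean_panel, weights_on=False)
        _, b = regress_valence(lm, clean_panel, weights_on=True)  # all 1.0
        assert a == pytest.approx(b)

    def test_adjusted_r2_formula(self):
        assert adjusted_r2(0.5, 11, 1) == pytest.approx(1 - 0.5 * 10 / 9)
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 9, 8)

    def test_unknown_regressor_rejected(self, clean_panel):
        lm = fit_latent_model(clean_panel, n_components=2)
        with pytest.raises(ValueError):
            regress_valence(lm, clean_panel, regressor="forest")


class TestCrossValidate:
    def test_noiseless_linear_near_zero_rmse(self, clean_panel):
        _, mean, _ = cross_validate(clean_panel, n_components=8, seed=4)
        assert mean < 0.05 * clean_panel.valence.std()

    def test_noise_valence_rmse_matches_sd(self, noise_panel):
        _, mean, _ = cross_validate(noise_panel, n_components=4, seed=5)
        assert mean == pytest.approx(noise_panel.valence.std(), rel=0.35)

    def test_split_determinism(self, clean_panel):
        a = cross_validate(clean_panel, n_components=4, seed=6)
        b = cross_validate(clean_panel, n_components=4, seed=6)
        assert list(a[0]) == list(b[0])

    def test_too_few_odors_rejected(self, noise_panel):
        small = OdorPanel(firing=noise_panel.firing.iloc[:5],
                          valence=noise_panel.valence.iloc[:5])
        with pytest.raises(ValueError):
            cross_validate(small, folds=10)

    def test_no_projection_leakage_optimism(self):
        # optimism canary: pure-noise target on a small panel; the in-sample
        # (everything-leaks) error must be optimistic while proper CV stays
        # at the noise floor
        rng = np.random.default_rng(7)
        firing = pd.DataFrame(rng.normal(size=(30, 23)))
        valence = pd.Series(rng.normal(size=30), index=firing.index)
        panel = OdorPanel(firing=firing, valence=valence)
        lm = fit_latent_model(panel, n_components=8)
        reg, _ = regress_valence(lm, panel)
        insample = float(np.sqrt(np.mean(
            (valence.to_numpy() - reg.predict(lm.scores)) ** 2)))
        _, cv_rmse, _ = cross_validate(panel, n_components=8, folds=10,
                                       test_size=0.2, seed=7)
        assert insample < 0.8 * cv_rmse  # leaky view is optimistic
        assert cv_rmse > 0.7 * valence.std()  # honest view is not


class TestCorrelationWeights:
    def test_proportional_profile_full_weight(self):
        v = np.array([1.0, -2.0, 0.5, 3.0])
        firing = pd.DataFrame([2 * v + 1, -0.5 * v])
        w = correlation_weights(firing, v)
        assert w.to_numpy() == pytest.approx([1.0, 1.0])

    def test_orthogonal_profile_zero_weight(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=10)
        x = rng.normal(size=10)
        vc = v - v.mean()
        xc = x - x.mean()
        ortho = xc - (xc @ vc) / (vc @ vc) * vc  # Gram–Schmidt vs centred v
        w = correlation_weights(pd.DataFrame([ortho]), v)
        assert w.iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(9)
        firing = pd.DataFrame(rng.normal(size=(25, 8)))
        w = correlation_weights(firing, rng.normal(size=8))
        assert ((w >= 0) & (w <= 1)).all()

    def test_constant_profile_warned_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            w = correlation_weights(pd.DataFrame([[1.0, 1.0, 1.0]]),
                                    [0.1, 0.2, 0.3])
        assert w.iloc[0] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlation_weights(pd.DataFrame([[1.0, 2.0]]), [1.0, 2.0, 3.0])


class TestLearningCurve:
    def test_expressive_kernel_overfits_small_n(self, noise_panel):
        curve = learning_curve(noise_panel, train_sizes=[10, 40],
                               n_components=4, regressor="svr_rbf", seed=10)
        small = curve[curve["train_size"] == 10]
        assert small["val_rmse"].mean() > 2 * small["train_rmse"].mean()

    def test_linear_model_converges(self, clean_panel):
        curve = learning_curve(clean_panel, train_sizes=[20, 80],
                               n_components=8, regressor="linear", seed=11)
        big = curve[curve["train_size"] == 80]
        gap = big["val_rmse"].mean() - big["train_rmse"].mean()
        assert gap < 0.1 * clean_panel.valence.std()

    def test_oversized_train_rejected(self, noise_panel):
        with pytest.raises(ValueError):
            learning_curve(noise_panel, train_sizes=[59])
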