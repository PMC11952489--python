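"""Feature engineering, resampled LASSO, sensitivity labels, Kozak scoring."""

import numpy as np
import pandas as pd
import pytest

from isodeg.features import (
    encode_features,
    example_pssm,
    kozak_score,
    label_sensitivity,
    lasso_classify,
    lasso_regress,
)


class TestEncodeFeatures:
    def test_numeric_standardization(self, rng):
        raw = pd.DataFrame({"x": rng.normal(5, 2, 500)})
        enc, _ = encode_features(raw, pd.Series(rng.normal(size=500)))
        assert abs(enc["x"].mean()) < 1e-9
        assert enc["x"].std(ddof=0) == pytest.approx(1.0)

    def test_constant_column_dropped_with_warning(self, rng):
        raw = pd.DataFrame({"x": np.ones(50), "y": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="constant"):
            enc, _ = encode_features(raw, pd.Series(rng.normal(size=50)))
        assert list(enc.columns) == ["y"]

    def test_wide_range_feature_log_transformed(self, rng):
        vals = 10.0 ** rng.uniform(0, 6, 300)
        raw = pd.DataFrame({"x": vals})
        enc, encoder = encode_features(raw, pd.Series(rng.normal(size=300)))
        assert encoder.numeric_stats_["x"][2]  # log flag
        expected = np.log10(vals)
        expected = (expected - expected.mean()) / expected.std(ddof=0)
        np.testing.assert_allclose(enc["x"], expected)

    def test_three_level_categorical_rank_zscores(self):
        raw = pd.DataFrame({"c": ["a"] * 10 + ["b"] * 10 + ["c"] * 10})
        outcome = pd.Series([1.0] * 10 + [2.0] * 10 + [3.0] * 10)
        enc, _ = encode_features(raw, outcome, categorical=["c"])
        got = sorted(enc["c"].unique())
        np.testing.assert_allclose(got, [-1.2247, 0.0, 1.2247], atol=1e-3)

    def test_many_level_categorical_pooled_to_ten_groups(self, rng):
        levels = [f"l{i}" for i in range(15)]
        raw = pd.DataFrame({"c": rng.choice(levels, 600)})
        outcome = pd.Series(rng.normal(size=600))
        _, encoder = encode_features(raw, outcome, categorical=["c"])
        assert len(set(encoder.category_ranks_["c"].values())) <= 10

    def test_unseen_level_gets_mean_rank_with_warning(self, rng):
        raw = pd.DataFrame({"c": ["a"] * 20 + ["b"] * 20})
        outcome = pd.Series(np.r_[np.zeros(20), np.ones(20)])
        _, encoder = encode_features(raw, outcome, categorical=["c"])
        with pytest.warns(UserWarning, match="unseen"):
            out = encoder.transform(pd.DataFrame({"c": ["zzz"]}))
        assert np.isfinite(out["c"].iloc[0])

    def test_idempotent_on_standardized_numeric(self, rng):
        raw = pd.DataFrame({"x": rng.normal(size=400)})
        enc1, _ = encode_features(raw, pd.Series(rng.normal(size=400)))
        enc2, _ = encode_features(enc1, pd.Series(rng.normal(size=400)))
        np.testing.assert_allclose(enc1["x"], enc2["x"], atol=1e-9)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(5)
    n = 800
    x = pd.DataFrame(
        rng.normal(size=(n, 6)), columns=["x1"] + [f"d{i}" for i in range(5)]
    )
    y = 2.0 * x["x1"] + rng.normal(0, 1, n)
    return x, pd.Series(y)


class TestLassoRegress:
    def test_planted_signal_recovered(self, planted):
        x, y = planted
        coefs = lasso_regress(x, y, n_boot=25, seed=1)
        assert 1.6 < coefs["x1"].median() < 2.4
        decoys = coefs.drop(columns="x1").abs().median()
        assert (decoys < 0.1).sum() >= 4

    def test_pure_noise_outcome_is_flat(self, planted):
        x, _ = planted
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(size=len(x)))
        coefs = lasso_regress(x, y, n_boot=25, seed=2)
        assert (coefs.abs().median() < 0.1).all()

    def test_duplicated_feature_splits_weight(self, planted):
        x, y = planted
        xdup = x.copy()
        xdup["x1_copy"] = x["x1"]
        single = lasso_regress(x, y, n_boot=10, seed=3)
        dup = lasso_regress(xdup, y, n_boot=10, seed=3)
        combined = (dup["x1"] + dup["x1_copy"]).median()
        assert combined == pytest.approx(single["x1"].median(), abs=0.3)

    def test_underdetermined_warns(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 6)), columns=[f"f{i}" for i in range(6)])
        y = pd.Series(rng.normal(size=30))
        with pytest.warns(UserWarning, match="unstable"):
            lasso_regress(x, y, n_boot=2, seed=0)


class TestLabelSensitivity:
    @staticmethod
    def _diff(l2fc):
        return pd.DataFrame(
            {
                "L2FC_kdeg": [l2fc],
                "mean_log_kdeg_A": [0.0],
                "mean_log_kdeg_B": [l2fc * np.log(2)],
                "se_L2FC": [0.1],
            }
        )

    def test_strong_stabilization_is_sensitive(self):
        # L2FC = -1.2 -> kdeg ratio 2^-1.2 = 0.44 < 0.65
        assert label_sensitivity(self._diff(-1.2)).iloc[0] == "sensitive"

    def test_moderate_l2fc_failing_ratio_rule_excluded(self):
        d = self._diff(-0.8)
        d["mean_log_kdeg_B"] = np.log(0.70)  # ratio 0.70 > 0.65
        assert label_sensitivity(d).iloc[0] == "excluded"

    def test_near_zero_change_is_insensitive(self):
        assert label_sensitivity(self._diff(0.1)).iloc[0] == "insensitive"

    def test_missing_uncertainty_excluded(self):
        d = self._diff(-1.2)
        d["se_L2FC"] = np.nan
        assert label_sensitivity(d).iloc[0] == "excluded"


@pytest.fixture(scope="module")
def logistic_data():
    rng = np.random.default_rng(8)
    n = 600
    x = pd.DataFrame(
        rng.normal(size=(n, 4)), columns=["x1", "d1", "d2", "d3"]
    )
    p = 1 / (1 + np.exp(-(2.5 * x["x1"])))
    labels = pd.Series(
        np.where(rng.random(n) < p, "sensitive", "insensitive")
    )
    return x, labels


class TestLassoClassify:
    def test_dominant_feature_sign_consistent(self, logistic_data):
        x, labels = logistic_data
        coefs = lasso_classify(x, labels, n_downsample=40, seed=1)
        assert (coefs["x1"] > 0).mean() >= 0.95
        assert coefs.abs().median().idxmax() == "x1"

    def test_label_swap_flips_sign(self, logistic_data):
        x, labels = logistic_data
        swapped = labels.map(
            {"sensitive": "insensitive", "insensitive": "sensitive"}
        )
        a = lasso_classify(x, labels, n_downsample=10, seed=2)
        b = lasso_classify(x, swapped, n_downsample=10, seed=2)
        assert np.sign(a["x1"].median()) == -np.sign(b["x1"].median())

    def test_shuffled_labels_flat(self, logistic_data):
        x, labels = logistic_data
        rng = np.random.default_rng(9)
        shuffled = pd.Series(rng.permutation(labels.to_numpy()))
        coefs = lasso_classify(x, shuffled, n_downsample=25, seed=3)
        assert (coefs.abs().median() < 0.1).all()

    def test_too_few_sensitive_refused(self, logistic_data):
        x, _ = logistic_data
        labels = pd.Series(
            ["sensitive"] * 5 + ["insensitive"] * (len(x) - 5)
        )
        with pytest.raises(ValueError, match="refusing"):
            lasso_classify(x, labels)


class TestKozakScore:
    def test_zero_matrix_scores_zero(self):
        assert kozak_score("ACGTACGTAC", np.zeros((10, 4))) == 0.0

    def test_one_hot_match_scores_ten(self):
        window = "GCCGCCACCA"
        pssm = np.zeros((10, 4))
        for i, b in enumerate(window):
            pssm[i, "ACGT".index(b)] = 1.0
        assert kozak_score(window, pssm) == 10.0

    def test_random_window_matches_positionwise_sum(self, rng):
        pssm = example_pssm()
        window = "".join(rng.choice(list("ACGT"), 10))
        expected = sum(pssm[i, "ACGT".index(b)] for i, b in enumerate(window))
        assert kozak_score(window, pssm) == pytest.approx(expected)

    def test_ambiguous_base_contributes_zero_with_warning(self):
        pssm = np.ones((10, 4))
        with pytest.warns(UserWarning, match="contribute 0"):
            assert kozak_score("ACGTNACGTA", pssm) == 9.0

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError):
            kozak_score("ACGT", np.zeros((10, 4)))
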