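"""Ensemble SDM machinery: splits, AUC/TSS, GLM+RF members, weighting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from riversdm import sdm_ensemble
from riversdm.sdm_ensemble import (
    PolyDesign,
    SdmConfig,
    auc,
    auc_band,
    fit_sdm,
    make_splits,
    predict_ensemble,
    tss,
    tss_band,
)


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def exhaustive_tss(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = -1.0
    u = np.unique(scores)
    for thr in np.concatenate([[u[0] - 1], (u[:-1] + u[1:]) / 2, [u[-1] + 1]]):
        pred = scores >= thr
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        best = max(best, sens + spec - 1)
    return best


class TestSplits:
    def test_fraction_respected(self):
        s = make_splits([f"s{i}" for i in range(100)], n_splits=10, seed=0)
        for train, test in s:
            assert len(train) == 80 and len(test) == 20
            assert set(train).isdisjoint(test)
            assert len(set(train) | set(test)) == 100

    def test_same_seed_identical(self):
        ids = [f"s{i}" for i in range(40)]
        a = make_splits(ids, n_splits=5, seed=7)
        b = make_splits(ids, n_splits=5, seed=7)
        for (ta, _), (tb, _) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)

    def test_site_test_appearances_binomial(self):
        """Each of 259 sites lands in the test fold ~10 times across 50
        splits; all counts within 3 binomial SD."""
        ids = [f"s{i}" for i in range(259)]
        s = make_splits(ids, n_splits=50, train_frac=0.8, seed=3)
        counts = pd.Series(0, index=ids)
        for _, test in s:
            counts.loc[test] += 1
        frac = 1 - round(0.8 * 259) / 259
        mean, sd = 50 * frac, np.sqrt(50 * frac * (1 - frac))
        assert counts.mean() == pytest.approx(mean, rel=1e-9)
        # binomial tails: a rare site may sit just past 3 SD, but not many
        assert ((counts - mean).abs() > 3 * sd).mean() <= 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_splits(list("abc"), seed=0)
        with pytest.raises(ValueError):
            make_splits([f"s{i}" for i in range(20)], train_frac=1.5, seed=0)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_worked_example(self):
        # positives {0.9, 0.4}, negatives {0.5, 0.1}: 3 of 4 pairs concordant
        assert auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.round(rng.uniform(0, 1, 20), 2), size=n)  # with ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_single_class_fails(self):
        with pytest.raises(ValueError, match="single class"):
            auc([0.1, 0.9], [1, 1])


class TestTss:
    def test_perfect_classifier(self):
        assert tss([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_two_point_example(self):
        assert tss([0.2, 0.8], [0, 1]) == pytest.approx(1.0)

    def test_null_scores_near_zero(self, rng):
        scores = rng.uniform(0, 1, 2000)
        labels = rng.integers(0, 2, 2000)
        assert abs(tss(scores, labels)) < 0.1

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 150))
            scores = rng.choice(np.round(rng.uniform(0, 1, 15), 2), size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert tss(scores, labels) == pytest.approx(
                exhaustive_tss(scores, labels), abs=1e-12
            )


class TestBands:
    @pytest.mark.parametrize(
        "value,band",
        [(0.91, "excellent"), (0.85, "good"), (0.75, "fair"), (0.65, "poor"), (0.5, "fail")],
    )
    def test_auc_bands(self, value, band):
        assert auc_band(value) == band

    @pytest.mark.parametrize("value,band", [(0.8, "excellent"), (0.5, "good"), (0.39, "poor")])
    def test_tss_bands(self, value, band):
        assert tss_band(value) == band


class TestPolyDesign:
    def test_orthogonal_basis_on_training_data(self, rng):
        X = pd.DataFrame({"a": rng.uniform(0, 10, 200), "ev1": rng.normal(size=200)})
        d = PolyDesign(["a"], ["ev1"], degree=2).fit(X)
        B = d.transform(X)
        # polynomial columns are orthogonal to each other and to the constant
        assert abs(B["a_p1"] @ B["a_p2"]) < 1e-8
        assert abs(B["a_p1"].sum()) < 1e-8

    def test_transform_consistent_on_new_data(self, rng):
        X = pd.DataFrame({"a": rng.uniform(0, 10, 100)})
        d = PolyDesign(["a"], [], degree=2).fit(X)
        B_all = d.transform(X)
        B_head = d.transform(X.head(10))
        np.testing.assert_allclose(B_head.to_numpy(), B_all.head(10).to_numpy())


def _simulated_species(rng, n=300):
    """Sites along a thermal gradient and a species with a unimodal response."""
    X = pd.DataFrame(
        {
            "t": rng.uniform(0, 12, n),
            "q": rng.normal(0, 1, n),
            "ev1": rng.normal(0, 1, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    p = 0.95 * np.exp(-((X["t"] - 6) ** 2) / (2 * 2.0**2))
    y = pd.Series((rng.random(n) < p).astype(int), index=X.index)
    return X, y


class TestFitSdm:
    def test_constant_labels_rejected(self, rng):
        X, y = _simulated_species(rng)
        with pytest.raises(ValueError, match="constant"):
            fit_sdm(X, pd.Series(1, index=X.index), make_splits(X.index, 3, seed=0),
                    ["t", "q"], ["ev1"])

    def test_weights_normalised_and_nonnegative(self, rng):
        X, y = _simulated_species(rng)
        splits = make_splits(X.index.to_numpy(), 5, seed=1)
        ens = fit_sdm(X, y, splits, ["t", "q"], ["ev1"],
                      config=SdmConfig(n_trees=50), seed=2)
        assert ens.weights[0] >= 0 and ens.weights[1] >= 0
        assert sum(ens.weights) == pytest.approx(1.0)

    def test_ensemble_is_convex_combination(self, rng):
        X, y = _simulated_species(rng)
        splits = make_splits(X.index.to_numpy(), 3, seed=1)
        ens = fit_sdm(X, y, splits, ["t", "q"], ["ev1"],
                      config=SdmConfig(n_trees=50), seed=2)
        p_a = ens.glm.predict(X)
        p_b = sdm_ensemble._rf_predict(ens.rf, X)
        p = predict_ensemble(ens, X)
        assert (p >= np.minimum(p_a, p_b) - 1e-12).all()
        assert (p <= np.maximum(p_a, p_b) + 1e-12).all()

    def test_zero_weight_member_gives_other_member(self, rng):
        X, y = _simulated_species(rng)
        splits = make_splits(X.index.to_numpy(), 3, seed=1)
        ens = fit_sdm(X, y, splits, ["t", "q"], ["ev1"],
                      config=SdmConfig(n_trees=50), seed=2)
        ens.weights = (1.0, 0.0)
        np.testing.assert_allclose(predict_ensemble(ens, X), ens.glm.predict(X))

    def test_identical_members_equal_ensemble_for_any_weights(self, rng):
        """With identical member predictions the weights cannot matter."""
        X, y = _simulated_species(rng)
        splits = make_splits(X.index.to_numpy(), 3, seed=1)
        ens = fit_sdm(X, y, splits, ["t", "q"], ["ev1"],
                      config=SdmConfig(n_trees=50), seed=2)
        p_a = ens.glm.predict(X)
        for w in [(0.5, 0.5), (0.9, 0.1)]:
            combined = (w[0] * p_a + w[1] * p_a) / sum(w)
            np.testing.assert_allclose(combined, p_a)

    def test_duplicate_row_equals_frequency_weighted_fit(self, rng):
        """Appending a copy of a training row is the same as giving that row
        frequency weight 2 in the likelihood."""
        X, y = _simulated_species(rng, n=150)
        dup_X = pd.concat([X, X.iloc[[0]].set_index(pd.Index(["dup"]))])
        dup_y = pd.concat([y, pd.Series([y.iloc[0]], index=["dup"])])
        member, _ = sdm_ensemble._fit_glm(dup_X, dup_y.to_numpy(), ["t", "q"], ["ev1"],
                                          SdmConfig())
        design = PolyDesign(["t", "q"], ["ev1"], degree=2).fit(dup_X)
        D = sm.add_constant(design.transform(X), has_constant="add")
        w = np.ones(len(X))
        w[0] = 2.0
        res = sm.GLM(y.to_numpy(), sm.add_constant(design.transform(X), has_constant="add"),
                     family=sm.families.Binomial(), freq_weights=w).fit()
        # same design basis (fitted on the duplicated frame) -> same optimum
        np.testing.assert_allclose(member.params, np.asarray(res.params), atol=1e-6)

    def test_strong_species_scores_high_auc(self, rng):
        """A high-prevalence, sharply structured species is discriminated
        with median ensemble AUC >= 0.85 across splits."""
        X, y = _simulated_species(rng, n=300)
        splits = make_splits(X.index.to_numpy(), 10, seed=4)
        ens = fit_sdm(X, y, splits, ["t", "q"], ["ev1"],
                      config=SdmConfig(n_trees=100), seed=5)
        ok = ens.eval_records[~ens.eval_records["skipped"]]
        assert ok["auc_ensemble"].median() >= 0.85

    def test_glm_coefficient_recovery_within_2se(self, rng):
        """Data generated from the member-A family: most orthogonal-basis
        coefficients fall within 2 SE of their mapped true values."""
        n = 2000
        x = rng.uniform(0, 10, n)
        z = rng.normal(0, 1, n)
        eta = -3.0 + 1.0 * x - 0.08 * x**2 + 0.6 * z
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        X = pd.DataFrame({"a": x, "ev1": z})
        design = PolyDesign(["a"], ["ev1"], degree=2).fit(X)
        D = sm.add_constant(design.transform(X), has_constant="add")
        res = sm.GLM(y, D, family=sm.families.Binomial()).fit()
        R = np.linalg.inv(design._r_inv["a"])
        t = R @ np.array([-3.0, 1.0, -0.08])
        truths = {"a_p1": t[1], "a_p2": t[2], "ev1": 0.6}
        hits = sum(
            abs(res.params[k] - v) <= 2 * res.bse[k] for k, v in truths.items()
        )
        assert hits >= 2
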