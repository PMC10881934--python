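import numpy as np
import pytest

from tacfit import (
    BEF,
    MEF,
    BoostedParameterRegressor,
    DatasetSpec,
    SoftVotingTACClassifier,
    TACModelChain,
    build_features,
    cross_validate_classifier,
    delta_tau,
    generate_dataset,
)
from tacfit.ml import dataset_features
from tacfit.models import PARAM_INTERVALS


class TestFeatures:
    def test_lengths(self, small_noisy_dataset):
        tac = small_noisy_dataset[0]
        assert build_features(tac).size == 2 * tac.n
        assert build_features(tac, MEF).size == 2 * tac.n + 1

    def test_layout_and_class_codes(self, small_noisy_dataset):
        tac = small_noisy_dataset[0]
        v = build_features(tac, BEF)
        np.testing.assert_array_equal(v[: tac.n], tac.times)
        np.testing.assert_array_equal(v[tac.n : 2 * tac.n], tac.fia)
        assert v[-1] == 1.0
        assert build_features(tac, MEF)[-1] == 0.0

    def test_determinism(self, small_noisy_dataset):
        tac = small_noisy_dataset[3]
        np.testing.assert_array_equal(build_features(tac), build_features(tac))

    def test_dataset_features_match_per_curve(self, small_noisy_dataset):
        X = dataset_features(small_noisy_dataset, with_class=True)
        for i in (0, len(small_noisy_dataset) - 1):
            kind = str(small_noisy_dataset.kinds[i])
            np.testing.assert_array_equal(
                X[i], build_features(small_noisy_dataset[i], kind)
            )


def toy_classes(n=40, gap=5.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(gap, 1, (n, 3))])
    y = np.array([MEF] * n + [BEF] * n)
    return X, y


class TestClassifier:
    def test_separable_toy_problem(self):
        X, y = toy_classes()
        clf = SoftVotingTACClassifier(random_state=0).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_probabilities_sum_to_one(self):
        X, y = toy_classes()
        proba = SoftVotingTACClassifier(random_state=0).fit(X, y).predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_single_class_rejected(self):
        X, y = toy_classes()
        with pytest.raises(ValueError):
            SoftVotingTACClassifier().fit(X, np.full_like(y, MEF))

    def test_same_seed_same_predictions(self, small_clean_dataset):
        X = dataset_features(small_clean_dataset)
        y = np.array([str(k) for k in small_clean_dataset.kinds])
        p1 = SoftVotingTACClassifier(random_state=3).fit(X, y).predict_proba(X)
        p2 = SoftVotingTACClassifier(random_state=3).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_learns_band_structure(self):
        """On noise-free in-band curves the voters separate the two
        families well above chance (accuracy grows with training size as
        the regularised logistic loss overcomes its penalty)."""
        ds = generate_dataset(DatasetSpec(8, 1000, 1000, 0.0, seed=11))
        X = dataset_features(ds)
        y = np.array([str(k) for k in ds.kinds])
        clf = SoftVotingTACClassifier(random_state=0).fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.70


@pytest.fixture(scope="module")
def trained():
    train = generate_dataset(DatasetSpec(8, 250, 0, 0.0, seed=13))
    X = dataset_features(train, with_class=True)
    return BoostedParameterRegressor(
        gbr_n_estimators=60, ada_n_estimators=2, random_state=0
    ).fit(X, train.truth_matrix[:, :2])


class TestRegressor:
    def test_holdout_mono_tau_error_small(self, trained):
        test = generate_dataset(DatasetSpec(8, 120, 0, 0.0, seed=14))
        Xt = dataset_features(test, with_class=True)
        pred = trained.predict(Xt)
        tau_hat = pred[:, 0] / pred[:, 1]
        d = np.abs(delta_tau(tau_hat, test.true_tau()))
        assert np.median(d) < 2.0

    def test_predictions_stay_near_band(self, trained):
        test = generate_dataset(DatasetSpec(8, 150, 0, 0.05, seed=15))
        pred = trained.predict(dataset_features(test, with_class=True))
        for j, name in enumerate(("A1", "lambda1")):
            lo, hi = PARAM_INTERVALS[MEF][name]
            pad = 0.01 * (hi - lo)
            assert pred[:, j].min() >= lo - pad
            assert pred[:, j].max() <= hi + pad

    def test_same_seed_same_model(self):
        train = generate_dataset(DatasetSpec(6, 60, 0, 0.0, seed=2))
        X = dataset_features(train, with_class=True)
        y = train.truth_matrix[:, :2]
        kw = dict(gbr_n_estimators=20, ada_n_estimators=2, random_state=7)
        p1 = BoostedParameterRegressor(**kw).fit(X, y).predict(X)
        p2 = BoostedParameterRegressor(**kw).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestChain:
    def test_rejects_other_point_counts(self, tiny_chain):
        other = generate_dataset(DatasetSpec(8, 3, 3, 0.0, seed=1))
        chain = tiny_chain[6]
        with pytest.raises(ValueError):
            chain.classify(other[0])
        with pytest.raises(ValueError):
            chain.predict_parameters(other[0], MEF)

    def test_classify_returns_probabilities(self, tiny_chain, tiny_config):
        test = generate_dataset(tiny_config.test_spec(6))
        sel = tiny_chain[6].classify(test[0])
        assert sel.method == "ML"
        assert sel.class_probs[0] + sel.class_probs[1] == pytest.approx(1.0)
        assert sel.chosen in (MEF, BEF)

    def test_parameter_counts_and_ordering(self, tiny_chain, tiny_config):
        test = generate_dataset(tiny_config.test_spec(6))
        chain = tiny_chain[6]
        p_me = chain.predict_parameters(test[0], MEF)
        p_be = chain.predict_parameters(test[0], BEF)
        assert p_me.k == 2
        assert p_be.k == 4 and p_be.rates[0] > p_be.rates[1]

    def test_batch_matches_single(self, tiny_chain, tiny_config):
        test = generate_dataset(tiny_config.test_spec(6))
        chain = tiny_chain[6]
        kinds = np.array([str(k) for k in test.kinds])
        batch = chain.predict_parameters_batch(test, kinds)
        single = chain.predict_parameters(test[0], kinds[0])
        np.testing.assert_allclose(batch[0, :2], single.as_array()[:2])

    def test_persistence_roundtrip(self, tiny_chain, tiny_config, tmp_path):
        chain = tiny_chain[6]
        chain.save(tmp_path)
        loaded = TACModelChain.load(tmp_path, 6)
        test = generate_dataset(tiny_config.test_spec(6))
        kinds = np.array([str(k) for k in test.kinds])
        np.testing.assert_array_equal(
            chain.predict_parameters_batch(test, kinds),
            loaded.predict_parameters_batch(test, kinds),
        )
        assert (tmp_path / "chain_N6.json").exists()


class TestCrossValidation:
    def test_accuracies_shape_and_range(self, small_clean_dataset):
        accs = cross_validate_classifier(small_clean_dataset, seed=1)
        assert len(accs) == 10
        assert all(0.0 <= a <= 1.0 for a in accs)

    def test_reproducible(self, small_clean_dataset):
        a = cross_validate_classifier(small_clean_dataset, seed=4)
        b = cross_validate_classifier(small_clean_dataset, seed=4)
        assert a == b
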