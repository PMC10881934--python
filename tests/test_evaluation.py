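import numpy as np
import pytest

from tacfit import (
    BEF,
    MEF,
    DatasetSpec,
    ExperimentConfig,
    classification_accuracy,
    delta_tau,
    generate_dataset,
    run_test1_known_class,
    run_test2_full_chains,
    summarize_deltas,
)
from tacfit.evaluation import derive_seed
from tacfit.ml import dataset_features
from tacfit import SoftVotingTACClassifier


class TestClassificationAccuracy:
    def test_all_correct(self):
        y = np.array([MEF, BEF, MEF])
        assert classification_accuracy(y, y) == 100.0

    def test_partial(self):
        # 1000 correct MEf + 960 correct BEf out of 2000 -> 98 %
        truth = np.array([MEF] * 1000 + [BEF] * 1000)
        pred = truth.copy()
        pred[1000:1040] = MEF
        assert classification_accuracy(pred, truth) == pytest.approx(98.0)

    def test_all_wrong(self):
        truth = np.array([MEF, BEF])
        assert classification_accuracy(truth[::-1], truth) == 0.0

    def test_equals_mean_recall_when_balanced(self, rng):
        truth = np.array([MEF] * 500 + [BEF] * 500)
        pred = np.where(rng.random(1000) < 0.8, truth, np.where(truth == MEF, BEF, MEF))
        recall_me = np.mean(pred[:500] == MEF)
        recall_be = np.mean(pred[500:] == BEF)
        assert classification_accuracy(pred, truth) == pytest.approx(
            100 * (recall_me + recall_be) / 2
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_accuracy(np.array([MEF]), np.array([MEF, BEF]))


class TestDeltaTau:
    @pytest.mark.parametrize(
        "est, true, expected", [(100.0, 100.0, 0.0), (75.0, 100.0, -25.0), (120.0, 100.0, 20.0)]
    )
    def test_signed_percentages(self, est, true, expected):
        assert delta_tau(est, true) == expected

    def test_vectorised(self):
        np.testing.assert_allclose(
            delta_tau([75.0, 120.0], [100.0, 100.0]), [-25.0, 20.0]
        )

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError):
            delta_tau(1.0, 0.0)


class TestSummaries:
    def test_three_values(self):
        s = summarize_deltas([-1.0, 0.0, 1.0])
        assert s.median == 0.0 and s.mer == (-1.0, 1.0)

    def test_constant_sample(self):
        s = summarize_deltas([2.5] * 9)
        assert s.median == 2.5 and s.iqr_width == 0.0 and s.mer == (2.5, 2.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_deltas([])

    def test_quartiles_match_sort_based_oracle(self, rng):
        """Linear-interpolation quantiles recomputed from first principles."""

        def quantile_oracle(sorted_x, q):
            pos = q * (len(sorted_x) - 1)
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            return sorted_x[lo] + (pos - lo) * (sorted_x[hi] - sorted_x[lo])

        for _ in range(1000):
            x = rng.normal(0, 10, size=int(rng.integers(2, 40)))
            s = summarize_deltas(x)
            xs = np.sort(x)
            assert s.q1 == pytest.approx(quantile_oracle(xs, 0.25), abs=1e-12)
            assert s.median == pytest.approx(quantile_oracle(xs, 0.50), abs=1e-12)
            assert s.q3 == pytest.approx(quantile_oracle(xs, 0.75), abs=1e-12)
            assert s.mer == (xs[0], xs[-1])
            assert s.q1 <= s.median <= s.q3


class TestSeedDerivation:
    def test_distinct_streams(self):
        seeds = {derive_seed(1, n, role) for n in (4, 10, 20) for role in ("train", "test", "ml")}
        assert len(seeds) == 9

    def test_deterministic_and_31_bit(self):
        s = derive_seed(42, 10, "test")
        assert s == derive_seed(42, 10, "test")
        assert 0 <= s < 2**31


class TestBenchmarks:
    def test_test1_summary_invariants(self, tiny_config, tiny_chain):
        rep = run_test1_known_class(tiny_config, tiny_chain)
        chains = {s.chain for s in rep.summaries}
        assert chains == {"fit_only", "ml2_only"}
        for s in rep.summaries:
            assert s.q1 <= s.median <= s.q3
            assert s.mer[0] <= s.q1 and s.mer[1] >= s.q3
            assert s.n_curves == tiny_config.test_me + tiny_config.test_be

    def test_test2_chains_and_accuracies(self, tiny_config, tiny_chain):
        rep = run_test2_full_chains(tiny_config, tiny_chain)
        assert {s.chain for s in rep.summaries} == {
            "ml1_ml2", "fit_ftest", "fit_aicc", "fit_aiccw",
        }
        for v in rep.accuracies.values():
            assert 0.0 <= v <= 100.0

    def test_applicability_thresholds_respected(self, tiny_chain):
        cfg = ExperimentConfig(
            n_set=(4,), train_me=60, train_be=60, test_me=15, test_be=15, seed=5,
            regressor_params={"gbr_n_estimators": 10, "ada_n_estimators": 2},
        )
        rep = run_test2_full_chains(cfg)
        # below N=5 no analytic chain applies; only the ML chain reports
        assert {s.chain for s in rep.summaries} == {"ml1_ml2"}
        assert set(rep.accuracies) == {(4, "ml1_ml2")}
        # same for the known-class test: the 4-parameter fit needs N >= 5
        rep1 = run_test1_known_class(cfg)
        assert {s.chain for s in rep1.summaries} == {"ml2_only"}

    def test_reports_deterministic(self, tiny_config, tiny_chain):
        r1 = run_test2_full_chains(tiny_config, tiny_chain)
        r2 = run_test2_full_chains(tiny_config, tiny_chain)
        assert r1.accuracies == r2.accuracies
        assert [s.median for s in r1.summaries] == [s.median for s in r2.summaries]

    def test_noise_free_test_sets_collapse_fit_deltas(self, tiny_chain):
        cfg = ExperimentConfig(
            n_set=(6,), train_me=120, train_be=120, test_me=40, test_be=40,
            noise=1e-12, seed=5,
            regressor_params={"gbr_n_estimators": 25, "ada_n_estimators": 2},
        )
        rep = run_test2_full_chains(cfg, tiny_chain)
        for chain in ("fit_ftest", "fit_aicc", "fit_aiccw"):
            s = rep.summary(6, chain)
            assert max(abs(s.mer[0]), abs(s.mer[1])) < 1.0

    def test_training_on_noisy_data_warns(self, tiny_config):
        """The chain flags noisy training sets (noise-free training is the
        intended protocol)."""
        from tacfit.ml import TACModelChain

        noisy = generate_dataset(DatasetSpec(6, 60, 60, 0.05, seed=2))
        chain = TACModelChain.from_config(
            6, random_state=0, gbr_n_estimators=10, ada_n_estimators=2
        )
        with pytest.warns(UserWarning, match="noisy"):
            chain.fit(noisy)
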