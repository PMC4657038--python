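import math

import numpy as np
import pytest

from dualscreen import bayes, synthdata
from dualscreen.bayes import (
    BayesModel,
    DegenerateFitError,
    TrainingError,
    cross_validate,
    est_p_good,
    load_model,
    save_model,
    score,
    train,
)
from dualscreen.compounds import LabeledDataset

from conftest import random_labeled_dataset


def brute_force_score(data: LabeledDataset, fp) -> float:
    """Independent recomputation of the Laplacian-corrected score from raw
    count tables."""
    n = len(data)
    prior = sum(data.labels) / n
    total = 0.0
    for f in fp:
        a_f = sum(1 for fpi, lab in zip(data.fingerprints, data.labels) if lab and f in fpi)
        t_f = sum(1 for fpi in data.fingerprints if f in fpi)
        total += math.log((a_f + 1) / (t_f * prior + 1))
    return total


def make_model(mu_a, sd_a, mu_i, sd_i, prior=0.5) -> BayesModel:
    return BayesModel(
        n_total=10,
        n_active=int(round(prior * 10)),
        prior=prior,
        feature_stats={},
        weights={},
        mu_active=mu_a,
        sigma_active=sd_a,
        mu_inactive=mu_i,
        sigma_inactive=sd_i,
        class_threshold=0.0,
    )


class TestTrain:
    def test_hand_derived_weights(self, tiny_dataset):
        # N=4, 2 actives, prior 0.5
        model = train(tiny_dataset)
        assert model.prior == 0.5
        # feature 1: one active + one inactive -> ln(2/2) = 0
        assert model.weights[1] == pytest.approx(0.0)
        # feature 2: both actives only -> ln(3/2)
        assert model.weights[2] == pytest.approx(math.log(1.5))
        assert model.feature_stats[2] == (2, 2)

    def test_unseen_feature_is_neutral(self, tiny_dataset):
        model = train(tiny_dataset)
        assert score(model, {999}) == 0.0

    def test_single_class_raises(self):
        data = LabeledDataset(
            ids=["a", "b"],
            fingerprints=[frozenset({1}), frozenset({2})],
            labels=[True, True],
        )
        with pytest.raises(TrainingError):
            train(data)

    def test_weights_depend_only_on_counts_and_prior(self, tiny_dataset):
        # adding a featureless compound changes weights only through the prior
        model = train(tiny_dataset)
        extended = LabeledDataset(
            ids=tiny_dataset.ids + ["empty"],
            fingerprints=tiny_dataset.fingerprints + [frozenset()],
            labels=tiny_dataset.labels + [False],
        )
        model2 = train(extended)
        for f, (a_f, t_f) in model.feature_stats.items():
            assert model2.feature_stats[f] == (a_f, t_f)
            expected = math.log((a_f + 1) / (t_f * model2.prior + 1))
            assert model2.weights[f] == pytest.approx(expected)


class TestScore:
    def test_empty_fingerprint_scores_zero(self, tiny_dataset):
        assert score(train(tiny_dataset), frozenset()) == 0.0

    def test_additive_over_disjoint_fingerprints(self, tiny_dataset):
        model = train(tiny_dataset)
        a, b = {1}, {2, 3}
        assert score(model, a | b) == pytest.approx(score(model, a) + score(model, b))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            data = random_labeled_dataset(rng)
            model = train(data)
            fp = data.fingerprints[int(rng.integers(len(data)))] | {9999}
            assert score(model, fp) == pytest.approx(
                brute_force_score(data, fp), abs=1e-12
            )


class TestEstPGood:
    def test_symmetric_gaussians_midpoint(self):
        model = make_model(2.0, 1.0, -2.0, 1.0)
        assert est_p_good(model, 0.0) == pytest.approx(0.5)

    def test_gaussian_density_ratio_by_hand(self):
        # s=1: log ratio = [−(1−2)²/2] − [−(1+2)²/2] = 4 → p = 1/(1+e^−4)
        model = make_model(2.0, 1.0, -2.0, 1.0)
        assert est_p_good(model, 1.0) == pytest.approx(1.0 / (1.0 + math.exp(-4.0)))

    def test_limits_and_bounds(self):
        model = make_model(2.0, 1.0, -2.0, 1.0)
        assert est_p_good(model, 1e3) == pytest.approx(1.0)
        assert est_p_good(model, -1e3) == pytest.approx(0.0)
        for s in np.linspace(-5, 5, 21):
            assert 0.0 <= est_p_good(model, s) <= 1.0

    def test_monotone_when_active_mean_higher(self):
        model = make_model(2.0, 1.0, -2.0, 1.0)
        probs = [est_p_good(model, s) for s in np.linspace(-6, 6, 50)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_identical_gaussians_return_prior(self):
        model = make_model(0.0, 1.0, 0.0, 1.0, prior=0.3)
        assert est_p_good(model, 1.7) == pytest.approx(0.3)

    def test_degenerate_sigma_raises(self):
        model = make_model(1.0, 0.0, -1.0, 1.0)
        with pytest.raises(DegenerateFitError):
            est_p_good(model, 0.0)


class TestClassThreshold:
    def test_minimizes_errors_with_sensitive_tie_break(self):
        # scores: actives {2, 4}, inactives {1, 3}; one error is unavoidable.
        # thresholds between 1 and 2 and between 3 and 4 both give FP+FN=1;
        # the tie must break toward the lower (more sensitive) threshold.
        scores = np.array([2.0, 4.0, 1.0, 3.0])
        labels = np.array([True, True, False, False])
        t = bayes._choose_threshold(scores, labels)
        assert 1.0 < t <= 2.0

    def test_separable_scores_split_perfectly(self, planted_dataset):
        model = bayes.train(planted_dataset)
        raw = np.array(
            [score(model, fp) for fp in planted_dataset.fingerprints]
        )
        labels = np.asarray(planted_dataset.labels)
        pred = raw >= model.class_threshold
        errors = int(np.sum(pred != labels))
        # threshold chosen to minimize training FP+FN on a separable signal
        assert errors <= 0.02 * len(labels)


class TestCrossValidate:
    def test_planted_signal_is_separable(self, planted_dataset):
        report = cross_validate(planted_dataset, n_runs=5, seed=1)
        assert report.roc_mean >= 0.95
        assert all(0.0 <= r <= 1.0 for r in report.roc_scores)

    def test_permuted_labels_have_no_signal(self, planted_dataset):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(planted_dataset))
        shuffled = LabeledDataset(
            ids=planted_dataset.ids,
            fingerprints=planted_dataset.fingerprints,
            labels=[planted_dataset.labels[i] for i in perm],
        )
        report = cross_validate(shuffled, n_runs=10, seed=3)
        assert report.roc_mean == pytest.approx(0.5, abs=0.1)

    def test_deterministic_under_seed(self, planted_dataset):
        r1 = cross_validate(planted_dataset, n_runs=3, seed=7)
        r2 = cross_validate(planted_dataset, n_runs=3, seed=7)
        assert r1.roc_scores == r2.roc_scores
        assert r1.ef == r2.ef

    def test_too_few_actives_raises(self):
        data = LabeledDataset(
            ids=["a", "b", "c"],
            fingerprints=[frozenset({1})] * 3,
            labels=[True, False, False],
        )
        with pytest.raises(TrainingError):
            cross_validate(data, n_runs=2, seed=0)


class TestLeaveOneOut:
    def test_scores_separate_classes_on_tiny_planted_set(self):
        cfg = synthdata.GeneratorConfig(seed=5, n_active=15, n_inactive=45)
        data = synthdata.gen_labeled_compounds(cfg)
        loo = bayes.leave_one_out(data)
        act = np.mean([s for s, l in zip(loo, data.labels) if l])
        inact = np.mean([s for s, l in zip(loo, data.labels) if not l])
        assert act > inact


class TestPersistence:
    def test_roundtrip_is_bit_exact_on_scores(self, planted_dataset, tmp_path):
        model = train(planted_dataset)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        for fp in planted_dataset.fingerprints[:50]:
            assert score(loaded, fp) == score(model, fp)
            assert est_p_good(loaded, score(loaded, fp)) == est_p_good(
                model, score(model, fp)
            )
        assert loaded.class_threshold == model.class_threshold
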