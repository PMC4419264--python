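import dataclasses

import numpy as np
import pytest

from eegfsel import classifier, synthetic
from eegfsel.classifier import (
    FuzzyRule,
    Model,
    Normalization,
    build_models,
    fit,
    intermediate_model,
    predict_batch,
    predict_sample,
    prune,
    vote_counts,
    vote_predict,
)
from eegfsel.session import FeatureSession


def _session(features, labels, session_id="s"):
    return FeatureSession(
        features=np.asarray(features, dtype=float),
        labels=np.asarray(labels, dtype=int),
        session_id=session_id,
    )


def _manual_model(rules, gamma=0.1, d=None):
    d = d if d is not None else rules[0].core_lo.size
    norm = Normalization(lo=np.zeros(d), hi=np.ones(d))
    return Model(rules=rules, rho_v=0.75, gamma_f=gamma, normalization=norm)


class TestFit:
    def test_singletons_are_memorized(self):
        sess = _session([[0.1, 0.9], [0.9, 0.1], [0.5, 0.5]], [2, 3, 7])
        model = fit(sess)
        for x, y in zip(sess.features, sess.labels):
            assert predict_sample(model, x) == y

    def test_max_vigilance_one_rule_per_distinct_sample(self):
        X = [[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [0.2, 0.8]]
        sess = _session(X, [2, 2, 2, 3])
        model = fit(sess, rho_v=1.0)
        assert len(model.rules) == 3  # duplicate sample absorbed

    def test_deterministic(self, tiny_sessions):
        m1 = fit(tiny_sessions[0])
        m2 = fit(tiny_sessions[0])
        assert len(m1.rules) == len(m2.rules)
        for r1, r2 in zip(m1.rules, m2.rules):
            np.testing.assert_array_equal(r1.core_lo, r2.core_lo)
            np.testing.assert_array_equal(r1.core_hi, r2.core_hi)
            assert r1.class_label == r2.class_label

    def test_missing_class_rejected(self):
        sess = _session(np.ones((0, 2)).tolist() or [[1, 1]], [2])
        # single-class session is fine; empty class only arises via an
        # explicitly empty session which the loader already rejects
        assert fit(sess).class_labels == (2,)

    def test_at_least_one_rule_per_class(self, tiny_sessions):
        model = fit(tiny_sessions[0])
        assert model.class_labels == tiny_sessions[0].label_set

    def test_separated_clusters_high_heldout_accuracy(self):
        hits = 0
        for seed in range(20):
            spec = synthetic.SyntheticSpec(
                n_features=6,
                informative=(1, 2, 3),
                effect_size=6.0,
                block_seconds=5,
                session_minutes=0.25,
                ar_coeff=0.0,  # clean i.i.d. clusters
                seed=seed,
            )
            train, test = synthetic.generate_sessions(spec, 2)
            # wide memberships: held-out points should rarely fall outside
            # every rule's support on well-separated clusters
            model = fit(train, gamma_f=0.3)
            acc = np.mean(predict_batch(model, test.features) == test.labels)
            hits += acc >= 0.95
        assert hits >= 18

    def test_train_accuracy_100_at_max_vigilance(self, rng):
        X = rng.random((30, 3))
        y = rng.integers(0, 3, size=30) + 1
        y[:3] = [1, 2, 3]  # ensure all classes present
        sess = _session(X, y)
        model = fit(sess, rho_v=1.0)
        assert np.all(predict_batch(model, X) == y)


class TestPredict:
    def test_inside_unique_core(self):
        rules = [
            FuzzyRule(np.array([0.0, 0.0]), np.array([0.4, 0.4]), 2),
            FuzzyRule(np.array([0.6, 0.6]), np.array([1.0, 1.0]), 3),
        ]
        model = _manual_model(rules)
        assert predict_sample(model, np.array([0.2, 0.2])) == 2
        assert predict_sample(model, np.array([0.8, 0.8])) == 3

    def test_outside_all_supports_lowest_rule_index_wins(self):
        rules = [
            FuzzyRule(np.array([0.0]), np.array([0.1]), 3),
            FuzzyRule(np.array([0.9]), np.array([1.0]), 2),
        ]
        model = _manual_model(rules, gamma=0.05, d=1)
        # activation 0 for both; tie -> rule 0 -> class 3
        assert predict_sample(model, np.array([0.5])) == 3

    def test_agrees_with_bruteforce_scan(self, rng):
        rules = []
        for _ in range(12):
            lo = rng.random(4) * 0.8
            hi = lo + rng.random(4) * 0.2
            rules.append(FuzzyRule(lo, hi, int(rng.integers(2, 5))))
        model = _manual_model(rules, gamma=0.15, d=4)
        for _ in range(50):
            x = rng.random(4)
            acts = []
            for r in rules:
                mus = []
                for j in range(4):
                    resid = max(r.core_lo[j] - x[j], x[j] - r.core_hi[j], 0.0)
                    mus.append(max(0.0, min(1.0, 1.0 - resid / 0.15)))
                acts.append(min(mus))
            expected = rules[int(np.argmax(acts))].class_label
            assert predict_sample(model, x) == expected

    def test_arity_mismatch(self):
        model = _manual_model([FuzzyRule(np.zeros(3), np.ones(3), 2)])
        with pytest.raises(ValueError):
            predict_sample(model, np.zeros(4))


class TestPrune:
    def _counted_model(self):
        rules = [
            FuzzyRule(np.array([0.0]), np.array([0.4]), 2),
            FuzzyRule(np.array([0.6]), np.array([1.0]), 3),
        ]
        return _manual_model(rules, d=1)

    def test_error_heavy_rule_removed_success_heavy_kept(self):
        # rule 0 (class 2) ends with counts (3, 5) -> removed; rule 1
        # (class 3) ends with (5, 3) -> kept; rule 2 keeps class 2 alive so
        # the per-class guard does not interfere
        rules = [
            FuzzyRule(np.array([0.0]), np.array([0.3]), 2),
            FuzzyRule(np.array([0.6]), np.array([1.0]), 3),
            FuzzyRule(np.array([0.4]), np.array([0.5]), 2),
        ]
        model = _manual_model(rules, d=1)
        X = np.array([[0.2]] * 8 + [[0.8]] * 8 + [[0.45]] * 2)
        y = np.array([2] * 3 + [3] * 5 + [3] * 5 + [2] * 3 + [2] * 2)
        pruned = prune(model, _session(X, y))
        counts = [(r.class_label, r.success_count, r.error_count) for r in pruned.rules]
        assert counts == [(3, 5, 3), (2, 2, 0)]

    def test_tied_counts_kept(self):
        model = self._counted_model()
        X = np.array([[0.2]] * 4 + [[0.8]] * 4)
        y = np.array([2, 2, 3, 3, 3, 3, 2, 2])  # both rules (2,2)
        pruned = prune(model, _session(X, y))
        assert len(pruned.rules) == 2

    def test_never_winning_rule_keeps_zero_counts_and_survives(self):
        rules = [
            FuzzyRule(np.array([0.0]), np.array([0.5]), 2),
            FuzzyRule(np.array([0.2]), np.array([0.3]), 3),  # always loses ties? no:
        ]
        # rule 0 core covers all samples and comes first, so rule 1 never wins
        model = _manual_model(rules, d=1)
        X = np.array([[0.25]] * 6)
        y = np.array([2, 2, 2, 3, 3, 3])
        pruned = prune(model, _session(X, y))
        loser = [r for r in pruned.rules if r.class_label == 3]
        assert len(loser) == 1
        assert loser[0].success_count == 0 and loser[0].error_count == 0

    def test_empty_session_returns_model_unchanged(self):
        model = self._counted_model()
        empty = FeatureSession(
            features=np.empty((0, 1)), labels=np.empty(0, dtype=int)
        )
        assert prune(model, empty) is model

    def test_never_increases_rule_count(self, tiny_sessions):
        model = fit(tiny_sessions[0])
        pruned = prune(model, tiny_sessions[1])
        assert len(pruned.rules) <= len(model.rules)

    def test_class_guard_retains_best_rule(self):
        rules = [
            FuzzyRule(np.array([0.0]), np.array([1.0]), 2),
            FuzzyRule(np.array([0.0]), np.array([1.0]), 3),
        ]
        model = _manual_model(rules, d=1)
        # every sample wins on rule 0 (lowest index); all labeled 3 -> rule 0
        # is all-error, rule 1 never wins; both classes must survive the guard
        X = np.array([[0.5]] * 5)
        y = np.array([3] * 5)
        pruned = prune(model, _session(X, y))
        assert set(r.class_label for r in pruned.rules) == {2, 3}

    def test_prune_does_not_mutate_input_model(self):
        model = self._counted_model()
        X = np.array([[0.2], [0.8]])
        y = np.array([3, 2])
        prune(model, _session(X, y))
        assert all(r.success_count == 0 and r.error_count == 0 for r in model.rules)


class TestBuildModels:
    def test_six_provenance_pairs(self, tiny_sessions):
        models = build_models(tiny_sessions)
        ids = [s.session_id for s in tiny_sessions]
        pairs = {(m.learn_session_id, m.prune_session_id) for m in models}
        expected = {(ids[i], ids[j]) for i in range(3) for j in range(3) if i != j}
        assert len(models) == 6
        assert pairs == expected

    def test_two_sessions_rejected(self, tiny_sessions):
        with pytest.raises(ValueError):
            build_models(tiny_sessions[:2])

    def test_duplicate_ids_rejected(self, tiny_sessions):
        dup = dataclasses.replace(tiny_sessions[1])
        dup.session_id = tiny_sessions[0].session_id
        with pytest.raises(ValueError):
            build_models([tiny_sessions[0], dup, tiny_sessions[2]])

    def test_normalization_from_learn_session_only(self, tiny_sessions):
        models = build_models(tiny_sessions)
        by_id = {s.session_id: s for s in tiny_sessions}
        for m in models:
            learn = by_id[m.learn_session_id]
            np.testing.assert_array_equal(m.normalization.lo, learn.features.min(axis=0))
            np.testing.assert_array_equal(m.normalization.hi, learn.features.max(axis=0))


class TestVoting:
    def _models_voting(self, votes_per_model):
        """Six one-rule models rigged so each predicts a fixed class."""
        models = []
        for c in votes_per_model:
            rule = FuzzyRule(np.array([0.0]), np.array([1.0]), c)
            models.append(_manual_model([rule], d=1))
        return models

    def test_strict_majority(self):
        # 4 models vote LEFT(2), 1 RIGHT(3), 1 WORD(7): 32/8/8 votes
        models = self._models_voting([2, 2, 2, 2, 3, 7])
        window = np.full((8, 1), 0.5)
        assert vote_predict(models, window) == 2

    def test_48_votes_counted(self):
        models = self._models_voting([2, 2, 2, 3, 3, 7])
        counts = vote_counts(models, np.full((8, 1), 0.5))
        assert sum(counts.values()) == 48 == 6 * 8
        assert counts == {2: 24, 3: 16, 7: 8}

    def test_tie_goes_to_previous_decision(self):
        models = self._models_voting([2, 2, 2, 3, 3, 3])  # 24/24
        window = np.full((8, 1), 0.5)
        assert vote_predict(models, window, previous=3) == 3
        assert vote_predict(models, window, previous=2) == 2

    def test_tie_without_previous_goes_to_lowest_label(self):
        models = self._models_voting([2, 2, 2, 7, 7, 7])
        assert vote_predict(models, np.full((8, 1), 0.5)) == 2

    def test_wrong_window_length(self, tiny_sessions):
        models = build_models(tiny_sessions)
        with pytest.raises(ValueError):
            vote_predict(models, tiny_sessions[0].features[:7])

    def test_wrong_model_count(self):
        models = self._models_voting([2, 2, 3])
        with pytest.raises(ValueError):
            vote_predict(models, np.full((8, 1), 0.5))

    def test_invariant_under_vote_permutation(self, rng, tiny_sessions):
        # the decision depends only on the multiset of 48 votes, so shuffling
        # the window vectors (which permutes votes within each model) and the
        # model order never changes the outcome
        models = build_models(tiny_sessions)
        window = tiny_sessions[2].features[:8]
        baseline = vote_predict(models, window)
        for _ in range(10):
            perm_models = [models[i] for i in rng.permutation(6)]
            perm_window = window[rng.permutation(8)]
            assert vote_predict(perm_models, perm_window) == baseline


class TestModelSerialization:
    def test_json_roundtrip_preserves_predictions(self, tmp_path, tiny_sessions):
        model = prune(fit(tiny_sessions[0]), tiny_sessions[1])
        path = tmp_path / "model.json"
        classifier.save_model(model, path)
        back = classifier.load_model(path)
        assert back.learn_session_id == model.learn_session_id
        assert back.prune_session_id == model.prune_session_id
        assert len(back.rules) == len(model.rules)
        X = tiny_sessions[2].features
        np.testing.assert_array_equal(predict_batch(back, X), predict_batch(model, X))


class TestIntermediateModel:
    def test_mean_of_two_cores(self):
        rules = [
            FuzzyRule(np.array([0.0]), np.array([1.0]), 2),
            FuzzyRule(np.array([2.0]), np.array([3.0]), 2),
            FuzzyRule(np.array([5.0]), np.array([6.0]), 3),
        ]
        im = intermediate_model(_manual_model(rules, d=1))
        i2 = im.class_labels.index(2)
        assert im.core_lo[i2, 0] == pytest.approx(1.0)
        assert im.core_hi[i2, 0] == pytest.approx(2.0)

    def test_single_rule_per_class_is_identity(self):
        rules = [
            FuzzyRule(np.array([0.1]), np.array([0.2]), 2),
            FuzzyRule(np.array([0.5]), np.array([0.9]), 3),
        ]
        im = intermediate_model(_manual_model(rules, d=1))
        np.testing.assert_array_equal(im.core_lo, [[0.1], [0.5]])
        np.testing.assert_array_equal(im.core_hi, [[0.2], [0.9]])

    def test_rule_count_equals_class_count(self, tiny_sessions):
        im = intermediate_model(fit(tiny_sessions[0]))
        assert im.core_lo.shape[0] == len(im.class_labels) == 3

    def test_matches_loop_reference(self, rng):
        rules = []
        for _ in range(9):
            lo = rng.random(5)
            rules.append(FuzzyRule(lo, lo + rng.random(5), int(rng.integers(2, 4))))
        model = _manual_model(rules, d=5)
        im = intermediate_model(model)
        for ci, c in enumerate(im.class_labels):
            of_class = [r for r in rules if r.class_label == c]
            for j in range(5):
                assert im.core_lo[ci, j] == pytest.approx(
                    sum(r.core_lo[j] for r in of_class) / len(of_class)
                )
                assert im.core_hi[ci, j] == pytest.approx(
                    sum(r.core_hi[j] for r in of_class) / len(of_class)
                )
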