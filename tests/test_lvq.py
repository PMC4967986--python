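import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from roundlvq import lvq
from roundlvq.data import LabeledDataset, SplitSpec, evaluate, percentage_split, shuffle_instances
from roundlvq.lvq import (
    Codebook,
    LVQConfig,
    decay_alpha,
    euclidean_distance,
    find_bmu,
    init_codebook,
    lvq1_step,
    lvq3_step,
    olvq_step,
    round_distance,
    round_half_away,
)
from roundlvq.synthetic import BlobSpec, make_blobs


class TestDistances:
    def test_three_four_five(self):
        assert euclidean_distance([1, 2], [4, 6]) == pytest.approx(5.0)

    def test_identical_vectors(self):
        assert euclidean_distance([1.5, -2.0], [1.5, -2.0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])

    def test_componentwise_summation_oracle(self, rng):
        for _ in range(100):
            w = rng.normal(size=5)
            x = rng.normal(size=5)
            expected = sum((wi - xi) ** 2 for wi, xi in zip(w, x)) ** 0.5
            assert euclidean_distance(w, x) == pytest.approx(expected, abs=1e-12)

    def test_sqrt2_rounds_to_one(self):
        assert round_distance([0, 0], [1, 1], 0) == 1.0

    def test_round_zero_at_equality(self):
        assert round_distance([3.0, 4.0], [3.0, 4.0]) == 0.0

    def test_half_away_from_zero(self):
        # 0.5 and 2.5 round up, unlike banker's rounding
        assert round_half_away(np.array([0.5, 1.5, 2.5])).tolist() == [1.0, 2.0, 3.0]
        assert round_half_away(np.array([2.45]), 1).tolist() == [2.5]


class TestFindBMU:
    def _codebook(self):
        # unrounded distances from x=(0,0): 1.6, 2.4, 3.7 -> rounded 2, 2, 4
        vectors = np.array([[1.6, 0.0], [2.4, 0.0], [3.7, 0.0]])
        return Codebook(vectors, np.array(["a", "b", "a"], dtype=object))

    def test_rounded_tie_lowest_index(self):
        cb = self._codebook()
        cfg = LVQConfig(distance_mode="rounded", tie_break="lowest_index")
        winner, runner = find_bmu(cb, np.zeros(2), cfg)
        assert winner == 0
        assert runner == 1

    def test_rounded_tie_random_hits_both(self, rng):
        cb = self._codebook()
        cfg = LVQConfig(distance_mode="rounded", tie_break="random")
        winners = {find_bmu(cb, np.zeros(2), cfg, rng)[0] for _ in range(50)}
        assert winners == {0, 1}

    def test_euclidean_strict_minimum(self, rng):
        cb = self._codebook()
        cfg = LVQConfig(distance_mode="euclidean")
        for _ in range(10):
            assert find_bmu(cb, np.zeros(2), cfg, rng)[0] == 0

    def test_exact_prototype_match_wins_in_both_modes(self, rng):
        cb = self._codebook()
        for mode in ("euclidean", "rounded"):
            cfg = LVQConfig(distance_mode=mode)
            winner, _ = find_bmu(cb, np.array([3.7, 0.0]), cfg, rng)
            assert winner == 2

    def test_empty_codebook_rejected(self):
        cb = Codebook(np.empty((0, 2)), np.array([], dtype=object))
        with pytest.raises(ValueError):
            find_bmu(cb, np.zeros(2), LVQConfig())


class TestDecay:
    def test_start_and_midpoint(self):
        assert decay_alpha(0.3, 0, 2000) == pytest.approx(0.3)
        assert decay_alpha(0.3, 1000, 2000) == pytest.approx(0.15)

    def test_last_step(self):
        assert decay_alpha(0.3, 1999, 2000) == pytest.approx(0.00015)

    def test_invalid_T(self):
        with pytest.raises(ValueError):
            decay_alpha(0.3, 0, 0)


class TestInitCodebook:
    def test_balanced_allocation(self, blobs_2c):
        cb = init_codebook(blobs_2c, 40, seed=0)
        assert np.sum(cb.labels == "c0") == 20
        assert np.sum(cb.labels == "c1") == 20

    def test_one_prototype_per_class(self, blobs_2c):
        cb = init_codebook(blobs_2c, 2, seed=0)
        assert sorted(cb.labels) == ["c0", "c1"]

    def test_prototypes_are_training_rows(self, blobs_2c):
        cb = init_codebook(blobs_2c, 10, seed=3)
        for vec, label in zip(cb.vectors, cb.labels):
            match = np.all(blobs_2c.features == vec, axis=1)
            assert match.any()
            assert label in set(blobs_2c.labels[match])

    def test_imbalanced_allocation_proportional(self):
        ds = make_blobs(BlobSpec(classes=2, n_per_class=(30, 10), seed=0))
        cb = init_codebook(ds, 8, seed=0)
        assert np.sum(cb.labels == "c0") == 6
        assert np.sum(cb.labels == "c1") == 2

    def test_too_few_prototypes_rejected(self, blobs_2c):
        with pytest.raises(ValueError):
            init_codebook(blobs_2c, 1, seed=0)


class TestSteps:
    def _single(self, vec, label):
        return Codebook(np.array([vec], dtype=float), np.array([label], dtype=object))

    def test_lvq1_attracts_matching_class(self):
        cb = self._single([0.0, 0.0], "a")
        lvq1_step(cb, np.array([1.0, 0.0]), "a", 0.5, LVQConfig())
        assert np.allclose(cb.vectors[0], [0.5, 0.0])

    def test_lvq1_repels_wrong_class(self):
        cb = self._single([0.0, 0.0], "a")
        lvq1_step(cb, np.array([1.0, 0.0]), "b", 0.5, LVQConfig())
        assert np.allclose(cb.vectors[0], [-0.5, 0.0])

    def test_lvq1_zero_rate_is_identity(self):
        cb = self._single([0.2, 0.3], "a")
        lvq1_step(cb, np.array([1.0, 0.0]), "a", 1e-15, LVQConfig())
        assert np.allclose(cb.vectors[0], [0.2, 0.3], atol=1e-12)

    def test_lvq3_window_threshold_value(self):
        w = 0.3
        assert (1 - w) / (1 + w) == pytest.approx(0.538, abs=1e-3)

    def test_lvq3_both_correct_uses_epsilon(self):
        cb = Codebook(
            np.array([[0.0, 0.0], [1.2, 0.0]]),
            np.array(["a", "a"], dtype=object),
        )
        cfg = LVQConfig(epsilon=0.3)
        lvq3_step(cb, np.array([1.0, 0.0]), "a", 0.1, cfg)
        assert np.allclose(cb.vectors[0], [0.03, 0.0])

    def test_lvq3_outside_window_unchanged(self):
        # d_i/d_j = 0.1 is far below the 0.538 window bound
        cb = Codebook(
            np.array([[0.1, 0.0], [-1.0, 0.0]]),
            np.array(["a", "b"], dtype=object),
        )
        before = cb.vectors.copy()
        lvq3_step(cb, np.zeros(2), "a", 0.1, LVQConfig())
        assert np.array_equal(cb.vectors, before)

    def test_lvq3_inside_window_attracts_and_repels(self):
        cb = Codebook(
            np.array([[1.0, 0.0], [-1.1, 0.0]]),
            np.array(["a", "b"], dtype=object),
        )
        lvq3_step(cb, np.zeros(2), "a", 0.1, LVQConfig())
        assert cb.vectors[0, 0] == pytest.approx(0.9)  # toward x=0
        assert cb.vectors[1, 0] == pytest.approx(-1.21)  # away from x=0

    def test_olvq_rate_shrinks_after_correct(self):
        cb = Codebook(
            np.array([[0.0, 0.0], [5.0, 5.0]]),
            np.array(["a", "b"], dtype=object),
            per_vector_alpha=np.array([0.3, 0.3]),
        )
        olvq_step(cb, np.array([0.1, 0.0]), "a", LVQConfig())
        assert cb.per_vector_alpha[0] == pytest.approx(0.3 / 1.3)

    def test_olvq_rate_grows_after_wrong_but_capped(self):
        cb = Codebook(
            np.array([[0.0, 0.0], [5.0, 5.0]]),
            np.array(["a", "b"], dtype=object),
            per_vector_alpha=np.array([0.3 / 1.3, 0.3]),
        )
        olvq_step(cb, np.array([0.1, 0.0]), "b", LVQConfig(alpha0=0.3))
        # 0.2308 / (1 - 0.2308) = 0.3, exactly at the cap
        assert cb.per_vector_alpha[0] == pytest.approx(0.3)

    def test_olvq_rate_monotone_under_correct_wins(self):
        cb = Codebook(
            np.array([[0.0, 0.0], [5.0, 5.0]]),
            np.array(["a", "b"], dtype=object),
            per_vector_alpha=np.array([0.3, 0.3]),
        )
        rates = []
        for _ in range(5):
            olvq_step(cb, np.array([0.01, 0.0]), "a", LVQConfig())
            rates.append(float(cb.per_vector_alpha[0]))
        assert all(b < a for a, b in zip(rates, rates[1:]))


class TestTrain:
    def test_zero_iterations_returns_initial_codebook(self, blobs_2c):
        cfg = LVQConfig(num_codebooks=4, iterations=0, seed=5)
        model = lvq.train("lvq1", blobs_2c, cfg)
        expected = init_codebook(blobs_2c, 4, seed=5)
        assert np.array_equal(model.codebook.vectors, expected.vectors)

    def test_deterministic_given_seed(self, blobs_2c):
        cfg = LVQConfig(num_codebooks=4, iterations=500, seed=9, distance_mode="rounded")
        a = lvq.train("lvq1", blobs_2c, cfg)
        b = lvq.train("lvq1", blobs_2c, cfg)
        assert np.array_equal(a.codebook.vectors, b.codebook.vectors)

    def test_codebook_labels_never_change(self, blobs_2c):
        cfg = LVQConfig(num_codebooks=4, iterations=300, seed=2)
        init_labels = init_codebook(blobs_2c, 4, seed=2).labels
        model = lvq.train("lvq3", blobs_2c, cfg)
        assert np.array_equal(model.codebook.labels, init_labels)

    def test_unknown_variant_rejected(self, blobs_2c):
        with pytest.raises(ValueError):
            lvq.train("lvq9", blobs_2c, LVQConfig())

    @pytest.mark.parametrize("variant", lvq.VARIANTS)
    def test_separable_blobs_high_accuracy(self, variant, blobs_2c):
        shuffled = shuffle_instances(blobs_2c, 0)
        train_set, test_set = percentage_split(shuffled, SplitSpec())
        cfg = LVQConfig(num_codebooks=4, iterations=2000, seed=0)
        model = lvq.train(variant, train_set, cfg)
        rep = evaluate(
            lvq.predict(model, test_set.features), test_set.labels, blobs_2c.class_names
        )
        assert rep.accuracy >= 0.95


class TestMultipass:
    def test_presentation_counts(self, blobs_2c):
        cfg = LVQConfig(num_codebooks=40)
        model = lvq.train_multipass(blobs_2c, cfg)
        assert model.meta["pass1_presentations"] == 1600
        assert model.meta["pass2_presentations"] == 16000

    def test_zero_rate_second_pass_equals_first_pass(self, blobs_2c):
        cfg = dataclasses.replace(
            LVQConfig(num_codebooks=4), multipass_alpha2=0.0
        )
        two_pass = lvq.train_multipass(blobs_2c, cfg)
        cfg1 = LVQConfig(
            num_codebooks=4,
            alpha0=cfg.multipass_alpha1,
            iterations=cfg.multipass_length_factor * 4,
        )
        one_pass = lvq.train("olvq1", blobs_2c, cfg1)
        assert np.allclose(two_pass.codebook.vectors, one_pass.codebook.vectors)

    def test_fast_second_pass_warns(self, blobs_2c):
        cfg = dataclasses.replace(LVQConfig(num_codebooks=4), multipass_alpha2=0.2)
        with pytest.warns(UserWarning):
            lvq.train_multipass(blobs_2c, cfg)


class TestHLVQ:
    def test_single_class_dataset_always_predicts_it(self):
        features = np.random.default_rng(0).normal(size=(30, 2))
        ds = LabeledDataset.from_arrays(features, ["only"] * 30)
        model = lvq.train_hlvq(ds, LVQConfig(num_codebooks=4, iterations=200))
        pred = lvq.predict(model, features)
        assert set(pred) == {"only"}

    def test_comparable_to_flat_lvq1_on_blobs(self):
        diffs = []
        for seed in range(5):
            ds = make_blobs(BlobSpec(classes=3, n_per_class=60, seed=seed))
            shuffled = shuffle_instances(ds, seed)
            train_set, test_set = percentage_split(shuffled, SplitSpec())
            cfg = LVQConfig(num_codebooks=6, iterations=1000, seed=seed)
            flat = lvq.train("lvq1", train_set, cfg)
            hier = lvq.train("hlvq", train_set, cfg)
            acc_flat = evaluate(
                lvq.predict(flat, test_set.features), test_set.labels, ds.class_names
            ).accuracy
            acc_hier = evaluate(
                lvq.predict(hier, test_set.features), test_set.labels, ds.class_names
            ).accuracy
            diffs.append(acc_hier - acc_flat)
        assert min(diffs) >= -0.02


class TestPredict:
    def test_prototype_row_returns_its_label(self, blobs_2c):
        model = lvq.train("lvq1", blobs_2c, LVQConfig(num_codebooks=4, iterations=0))
        cb = model.codebook
        pred = lvq.predict(model, cb.vectors)
        assert np.array_equal(pred, cb.labels)

    def test_empty_input(self, blobs_2c):
        model = lvq.train("lvq1", blobs_2c, LVQConfig(num_codebooks=4, iterations=0))
        assert len(lvq.predict(model, np.empty((0, 2)))) == 0

    def test_duplicate_rows_get_identical_predictions(self, blobs_2c):
        model = lvq.train(
            "lvq1", blobs_2c, LVQConfig(num_codebooks=4, iterations=100, distance_mode="rounded")
        )
        x = blobs_2c.features[0]
        pred = lvq.predict(model, np.array([x, x, x]))
        assert len(set(pred)) == 1

    def test_dimension_mismatch_rejected(self, blobs_2c):
        model = lvq.train("lvq1", blobs_2c, LVQConfig(num_codebooks=4, iterations=0))
        with pytest.raises(ValueError):
            lvq.predict(model, np.zeros((1, 5)))


class TestSerialization:
    @pytest.mark.parametrize("variant", ["lvq1", "olvq1", "hlvq"])
    def test_round_trip_preserves_predictions(self, variant, blobs_2c, tmp_path):
        cfg = LVQConfig(num_codebooks=4, iterations=200, distance_mode="rounded")
        model = lvq.train(variant, blobs_2c, cfg)
        path = tmp_path / "model.json"
        lvq.save_model(model, path)
        back = lvq.load_model(path)
        X = blobs_2c.features[:20]
        assert np.array_equal(lvq.predict(model, X), lvq.predict(back, X))
        assert np.array_equal(back.codebook.vectors, model.codebook.vectors)

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text('{"hello": 1}')
        with pytest.raises(ValueError):
            lvq.load_model(path)


def test_rounded_mode_spreads_wins_on_dense_ties(rng):
    """Rounding creates ties among near-equidistant prototypes, so random
    tie-breaking lets more prototypes win than strict Euclidean selection."""
    vectors = np.array([[1.6, 0.0], [2.4, 0.0]])
    labels = np.array(["a", "a"], dtype=object)
    x = np.zeros(2)
    euclid_winners = set()
    rounded_winners = set()
    cfg_e = LVQConfig(distance_mode="euclidean")
    cfg_r = LVQConfig(distance_mode="rounded", tie_break="random")
    for _ in range(100):
        cb = Codebook(vectors.copy(), labels.copy())
        euclid_winners.add(find_bmu(cb, x, cfg_e, rng)[0])
        rounded_winners.add(find_bmu(cb, x, cfg_r, rng)[0])
    assert len(rounded_winners) >= len(euclid_winners)
    assert rounded_winners == {0, 1}
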