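import numpy as np
import pytest

from nuva.posteriorgram import PhoneInventory, Posteriorgram
from nuva.verifier import (LOG_FLOOR, combination_auc, distance_matrix, dtw,
                           local_distance, verify)

from ._oracles import brute_force_dtw
from .conftest import random_posteriorgram

INV = PhoneInventory.default()


def onehot_sequence(indices):
    probs = np.zeros((len(indices), 45))
    for t, i in enumerate(indices):
        probs[t, i] = 1.0
    return Posteriorgram(probs, INV)


class TestLocalDistance:
    def test_identical_onehots_give_zero(self):
        row = np.zeros(45)
        row[7] = 1.0
        assert local_distance(row, row) == 0.0

    def test_orthogonal_onehots_hit_the_floor(self):
        a, b = np.zeros(45), np.zeros(45)
        a[0], b[1] = 1.0, 1.0
        assert local_distance(a, b) == pytest.approx(-np.log(LOG_FLOOR))

    def test_uniform_rows_closed_form(self):
        u = np.full(45, 1.0 / 45)
        # inner product = 45 * (1/45)^2 = 1/45
        assert local_distance(u, u) == pytest.approx(np.log(45.0), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            local_distance(np.ones(45) / 45, np.ones(44) / 44)


class TestDtw:
    def test_identical_onehot_sequences_align_on_diagonal(self):
        pg = onehot_sequence([0, 1, 2, 3])
        res = dtw(pg, pg)
        assert res.accumulated == 0.0
        assert res.normalized == 0.0
        assert res.path == tuple((i, i) for i in range(4))

    def test_single_frame_case_equals_local_distance(self, rng):
        a = random_posteriorgram(rng, 1)
        b = random_posteriorgram(rng, 1)
        res = dtw(a, b)
        expected = local_distance(a.probs[0], b.probs[0])
        assert res.accumulated == pytest.approx(expected)
        assert res.normalized == pytest.approx(expected)

    def test_inventory_mismatch_rejected(self, rng):
        other = PhoneInventory(tuple(f"p{i}" for i in range(44)) + ("sil",))
        a = random_posteriorgram(rng, 3)
        probs = np.full((3, 45), 1.0 / 45)
        b = Posteriorgram(probs, other)
        with pytest.raises(ValueError, match="inventor"):
            dtw(a, b)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(100):
            n, m = rng.integers(1, 7, size=2)
            a = random_posteriorgram(rng, int(n))
            b = random_posteriorgram(rng, int(m))
            local = distance_matrix(a, b)
            res = dtw(a, b)
            assert res.accumulated == pytest.approx(brute_force_dtw(local),
                                                    abs=1e-9)

    def test_symmetric_in_arguments(self, rng):
        for _ in range(20):
            a = random_posteriorgram(rng, int(rng.integers(2, 10)))
            b = random_posteriorgram(rng, int(rng.integers(2, 10)))
            assert dtw(a, b).accumulated == pytest.approx(
                dtw(b, a).accumulated, abs=1e-9)

    def test_path_is_monotone_and_spans_corners(self, rng):
        a = random_posteriorgram(rng, 6)
        b = random_posteriorgram(rng, 9)
        path = dtw(a, b).path
        assert path[0] == (0, 0) and path[-1] == (5, 8)
        for (i0, j0), (i1, j1) in zip(path, path[1:]):
            assert (i1 - i0, j1 - j0) in {(1, 0), (0, 1), (1, 1)}


class TestVerify:
    def test_attempt_equal_to_a_template_is_correct(self, rng):
        attempt = onehot_sequence([0, 1, 2])
        other = random_posteriorgram(rng, 5)
        verdict = verify(attempt, [other, attempt], threshold=0.675, word="w")
        assert verdict.min_distance == 0.0
        assert verdict.decision == "correct"
        assert verdict.min_distance == min(verdict.per_template)

    def test_minimum_under_example_threshold_is_correct(self, rng):
        # two templates: one matching (distance 0), one far away
        attempt = onehot_sequence([3, 4])
        far = onehot_sequence([10, 11])
        verdict = verify(attempt, [far, attempt], threshold=0.675)
        assert verdict.per_template[0] > 0.675 > verdict.per_template[1]
        assert verdict.decision == "correct"

    def test_distance_exactly_at_threshold_is_incorrect(self, rng):
        attempt = random_posteriorgram(rng, 4)
        template = random_posteriorgram(rng, 5)
        d = verify(attempt, [template], threshold=1e9).min_distance
        assert verify(attempt, [template], threshold=d).decision == "incorrect"

    def test_no_templates_rejected(self, rng):
        with pytest.raises(ValueError, match="no templates"):
            verify(random_posteriorgram(rng, 3), [], threshold=0.5)

    def test_adding_a_template_never_increases_min_distance(self, rng):
        attempt = random_posteriorgram(rng, 4)
        t1 = random_posteriorgram(rng, 5)
        t2 = random_posteriorgram(rng, 6)
        one = verify(attempt, [t1], threshold=1.0).min_distance
        two = verify(attempt, [t1, t2], threshold=1.0).min_distance
        assert two <= one

    def test_decision_monotone_in_threshold(self, rng):
        attempt = random_posteriorgram(rng, 4)
        template = random_posteriorgram(rng, 5)
        d = verify(attempt, [template], threshold=1e9).min_distance
        assert verify(attempt, [template], threshold=d * 0.9).decision == "incorrect"
        assert verify(attempt, [template], threshold=d * 1.1).decision == "correct"


class TestCombinationAuc:
    def test_perfect_separation_gives_auc_one(self):
        d = np.array([[0.1, 0.2], [0.2, 0.1], [0.9, 1.0], [1.0, 0.8]])
        labels = [1, 1, 0, 0]
        assert combination_auc(d, labels)["min"] == 1.0

    def test_random_labels_give_auc_near_half(self, rng):
        d = rng.uniform(0, 1, size=(2000, 2))
        labels = rng.integers(0, 2, size=2000)
        aucs = combination_auc(d, labels)
        for value in aucs.values():
            assert abs(value - 0.5) < 0.05

    def test_min_beats_single_template_when_attempts_match_one_speaker(self, rng):
        # each correct attempt is close to exactly one of the two templates
        n = 400
        labels = rng.integers(0, 2, size=n)
        which = rng.integers(0, 2, size=n)
        d = rng.uniform(0.8, 1.2, size=(n, 2))
        close = rng.uniform(0.0, 0.2, size=n)
        correct = labels == 1
        d[correct, which[correct]] = close[correct]
        aucs = combination_auc(d, labels)
        assert aucs["min"] >= aucs["first"]
        assert aucs["min"] > 0.95

    def test_single_class_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="both label classes"):
            combination_auc(rng.uniform(size=(10, 2)), np.ones(10))
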