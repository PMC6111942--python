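import numpy as np
import pytest

from deltamem import (
    MemoryConfig,
    classify,
    dynamic_threshold,
    learn,
    recall_fundamental,
)
from deltamem.delta_am import classify_many, difference_scores
from deltamem.errors import (
    DimensionMismatchError,
    FingerprintMismatchError,
    SchemaError,
)

from _oracle import oracle_classify
from conftest import make_fs, random_conflict_free_fs


@pytest.fixture
def two_point_memory():
    return learn(make_fs([[0, 0], [10, 10]], [0, 1], class_names=["classA", "classB"]))


class TestLearn:
    def test_stores_every_association(self, tiny_fs):
        mem = learn(tiny_fs)
        assert mem.p == 4 and mem.n == 2
        assert sorted(np.bincount(mem.labels).tolist()) == [2, 2]

    def test_single_class_is_error(self):
        fs = make_fs([[1], [2]], [0, 0], class_names=["only"])
        with pytest.raises(SchemaError):
            learn(fs)

    def test_learning_is_deterministic(self, tiny_fs):
        a, b = learn(tiny_fs), learn(tiny_fs)
        np.testing.assert_array_equal(a.stored, b.stored)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.source_fingerprint == b.source_fingerprint

    def test_learning_never_modifies_input(self, tiny_fs):
        before = tiny_fs.X.copy()
        mem = learn(tiny_fs)
        mem.stored[0, 0] = 999.0
        np.testing.assert_array_equal(tiny_fs.X, before)

    def test_conflicting_duplicate_logs_warning(self, caplog):
        fs = make_fs([[1, 1], [1, 1]], [0, 1], class_names=["a", "b"])
        with caplog.at_level("WARNING", logger="deltamem.delta_am"):
            learn(fs)
        assert any("conflicting" in r.message for r in caplog.records)


class TestDynamicThreshold:
    def test_minimum_attained_difference(self, two_point_memory):
        assert dynamic_threshold(two_point_memory, [1, 1]) == 2.0

    def test_zero_for_stored_pattern(self, two_point_memory):
        assert dynamic_threshold(two_point_memory, [0, 0]) == 0.0

    def test_equidistant_query(self, two_point_memory):
        assert dynamic_threshold(two_point_memory, [5, 5]) == 10.0

    def test_dimension_mismatch(self, two_point_memory):
        with pytest.raises(DimensionMismatchError):
            dynamic_threshold(two_point_memory, [1, 2, 3])

    def test_minimality_over_stored_patterns(self, rng):
        fs = random_conflict_free_fs(rng, p_max=40, n_max=8)
        mem = learn(fs)
        for _ in range(20):
            x = rng.integers(-25, 26, size=fs.n).astype(float)
            theta = dynamic_threshold(mem, x)
            d = difference_scores(mem, x)
            assert np.all(theta <= d) and np.any(theta == d)


class TestClassify:
    def test_unique_minimum(self, two_point_memory):
        res = classify(two_point_memory, [1, 1])
        assert res.label.name == "classA"
        assert res.threshold == 2.0
        assert res.candidate_count == 1

    def test_stored_pattern_recalls_own_label(self, tiny_fs):
        mem = learn(tiny_fs)
        res = classify(mem, tiny_fs.X[2])
        assert res.threshold == 0.0
        assert res.label.index == tiny_fs.y[2]

    def test_two_way_tie_breaks_to_smallest_class_index(self):
        mem = learn(make_fs([[0, 0], [2, 2]], [0, 1], class_names=["classA", "classB"]))
        res = classify(mem, [1, 1])
        assert res.threshold == 2.0
        assert res.candidate_count == 2
        assert res.label.name == "classA"

    def test_majority_beats_tie_break(self):
        # two classB candidates vs one classA at the same difference
        mem = learn(
            make_fs([[0, 0], [2, 0], [0, 2]], [0, 1, 1], class_names=["classA", "classB"])
        )
        res = classify(mem, [1, 0])
        # d = [1, 1, 3]: candidates are one of each class -> tie -> classA
        assert res.candidate_count == 2 and res.label.name == "classA"
        res2 = classify(mem, [1, 1])
        # d = [2, 2, 2]: one classA vs two classB -> majority classB
        assert res2.candidate_count == 3 and res2.label.name == "classB"

    def test_class_relabelling_symmetry(self, rng):
        """Permuting class indices permutes predictions identically."""
        fs = random_conflict_free_fs(rng, p_max=30, n_max=6)
        perm = {0: 1, 1: 0}
        swapped = make_fs(
            fs.X, [perm[c] for c in fs.y], class_names=[fs.class_names[1], fs.class_names[0]]
        )
        mem, mem_swapped = learn(fs), learn(swapped)
        for _ in range(30):
            x = rng.integers(-25, 26, size=fs.n).astype(float)
            a, b = classify(mem, x), classify(mem_swapped, x)
            assert a.threshold == b.threshold
            assert a.candidate_count == b.candidate_count
            d = difference_scores(mem, x)
            cand = np.flatnonzero(d == d.min())
            votes = np.bincount(fs.y[cand], minlength=2)
            if votes[0] != votes[1]:
                # no hidden class preference: same majority under relabelling
                assert a.label.name == b.label.name
            else:
                # the documented tie-break picks the smallest class index,
                # which names different classes after the swap
                assert a.label.index == b.label.index == 0

    def test_reject_when_threshold_exceeds_magnitude_bound(self):
        config = MemoryConfig(reject_enabled=True, tau=0.5)
        mem = learn(make_fs([[0, 0], [1, 1]], [0, 1], class_names=["a", "b"]), config)
        far = classify(mem, [100, 100])  # theta=198 > 0.5*100
        assert far.rejected and far.label is None and far.candidate_count == 0
        near = classify(mem, [1, 1])  # theta=0 <= bound
        assert not near.rejected

    def test_scaled_magnitude_policy_threshold(self):
        config = MemoryConfig(threshold_policy="scaled-magnitude", tau=2.0)
        mem = learn(make_fs([[0, 0], [10, 10]], [0, 1], class_names=["a", "b"]), config)
        res = classify(mem, [1, 1])  # bound = 2*1 = 2; only [0,0] within it
        assert res.threshold == 2.0
        assert res.label.name == "a" and res.candidate_count == 1

    def test_classify_many_matches_single(self, two_point_memory):
        X = np.array([[1, 1], [9, 9], [5, 5]], dtype=float)
        singles = [classify(two_point_memory, row) for row in X]
        batch = classify_many(two_point_memory, X)
        assert [r.label.name for r in batch] == [r.label.name for r in singles]


class TestRecallFundamental:
    def test_conflict_free_set_recalls_perfectly(self, rng):
        for _ in range(10):
            fs = random_conflict_free_fs(rng, p_max=60, n_max=8)
            assert recall_fundamental(learn(fs), fs) == 1.0

    def test_conflicting_duplicate_two_pattern_case(self):
        # identical pattern under both classes, p=2: the candidate set is
        # always {both}, tie -> class 0, so exactly one of the two
        # associations is recalled (hand-enumerated oracle).
        fs = make_fs([[3, 3], [3, 3]], [0, 1], class_names=["a", "b"])
        assert recall_fundamental(learn(fs), fs) == 0.5

    def test_one_pattern_per_class(self):
        fs = make_fs([[0], [9]], [0, 1], class_names=["a", "b"])
        assert recall_fundamental(learn(fs), fs) == 1.0

    def test_fingerprint_mismatch_rejected(self, tiny_fs):
        mem = learn(tiny_fs)
        other = make_fs(tiny_fs.X + 1.0, tiny_fs.y, class_names=tiny_fs.class_names)
        with pytest.raises(FingerprintMismatchError):
            recall_fundamental(mem, other)


def test_oracle_agreement_small_instances(rng):
    """Vectorised classifier agrees exactly with the loop oracle."""
    for _ in range(50):
        fs = random_conflict_free_fs(rng, p_max=25, n_max=6)
        mem = learn(fs)
        for _ in range(5):
            x = rng.integers(-25, 26, size=fs.n).astype(float)
            res = classify(mem, x)
            w, theta, count = oracle_classify(
                fs.X.tolist(), fs.y.tolist(), fs.n_classes, x.tolist()
            )
            assert res.label.index == w
            assert res.threshold == theta
            assert res.candidate_count == count
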