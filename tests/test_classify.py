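"""Random-forest classification: separability, determinism, stratified CV,
chance-level guard, merge monotonicity."""

import itertools

import numpy as np
import pytest

from morphoquant.classify import (CELL_CYCLE_MERGE, ImageClassifier,
                                  cross_validate, merge_classes,
                                  merge_labels)
from morphoquant.synth import (SyntheticSpec, default_cell_cycle_specs,
                               generate_classed_dataset)


@pytest.fixture(scope="module")
def two_class_dataset():
    """1 large particle vs 40 small ones: maximally separated classes."""
    specs = {
        "one_big": SyntheticSpec(width=96, height=96, n_particles=1,
                                 axis_range=(18, 22), seed=0),
        "many_small": SyntheticSpec(width=96, height=96, n_particles=40,
                                    axis_range=(2, 4), seed=0),
    }
    return generate_classed_dataset(specs, n_per_class=12, seed=21)


@pytest.fixture(scope="module")
def seven_class_dataset():
    specs = default_cell_cycle_specs(96)
    return generate_classed_dataset(specs, n_per_class=9, seed=33)


@pytest.fixture(scope="module")
def seven_class_features(seven_class_dataset):
    images, labels = seven_class_dataset
    model = ImageClassifier(n_trees=100, random_state=0)
    return model.extract_features(images), np.asarray(labels)


class TestImageClassifier:
    def test_separable_classes_perfect_training_accuracy(self,
                                                         two_class_dataset):
        images, labels = two_class_dataset
        model = ImageClassifier(n_trees=100, random_state=0)
        model.fit(images, labels)
        assert np.mean(model.predict(images) == np.asarray(labels)) == 1.0

    def test_deterministic_given_seed(self, two_class_dataset):
        images, labels = two_class_dataset
        probe, probe_labels = images[::3], labels[::3]
        train = [im for i, im in enumerate(images) if i % 3]
        train_y = [l for i, l in enumerate(labels) if i % 3]
        p1 = ImageClassifier(n_trees=50, random_state=7).fit(train, train_y).predict(probe)
        p2 = ImageClassifier(n_trees=50, random_state=7).fit(train, train_y).predict(probe)
        assert np.array_equal(p1, p2)

    def test_column_permutation_with_name_mapping_preserves_predictions(
            self, seven_class_features):
        F, y = seven_class_features
        rng = np.random.default_rng(0)
        perm = rng.permutation(F.shape[1])
        m1 = ImageClassifier(n_trees=50, random_state=3)
        m1.fit_features(F, y)
        m2 = ImageClassifier(n_trees=50, random_state=3)
        m2.fit_features(F[:, perm], y,
                        feature_names=[f"f{i}" for i in perm])
        # name-keyed realignment: feeding columns in each model's own
        # training order must give identical predictions
        order2 = np.argsort(perm)  # maps m2's schema back to m1's
        p1 = m1.predict_features(F)
        p2 = m2.predict_features(F[:, perm])
        assert np.array_equal(p1, p2)
        assert [m2.feature_names_[i] for i in order2] == \
               [f"f{i}" for i in range(F.shape[1])]

    def test_single_class_rejected(self, two_class_dataset):
        images, labels = two_class_dataset
        model = ImageClassifier(n_trees=10)
        with pytest.raises(ValueError):
            model.fit(images, ["same"] * len(images))

    def test_save_load_round_trip(self, tmp_path, two_class_dataset):
        images, labels = two_class_dataset
        model = ImageClassifier(n_trees=30, random_state=1).fit(images, labels)
        model.save(tmp_path / "model.pkl")
        back = ImageClassifier.load(tmp_path / "model.pkl")
        assert np.array_equal(back.predict(images), model.predict(images))
        assert back.feature_names_ == model.feature_names_


class TestCrossValidate:
    def test_separable_dataset_high_accuracy(self, two_class_dataset):
        images, labels = two_class_dataset
        rep = cross_validate(images, labels, k=3, seed=0,
                             model=ImageClassifier(n_trees=100))
        assert rep.mean_accuracy >= 0.95
        assert len(rep.fold_accuracies) == 3

    def test_report_invariants(self, seven_class_features):
        F, y = seven_class_features
        rep = cross_validate(None, y, k=3, seed=1,
                             model=ImageClassifier(n_trees=100),
                             precomputed_features=F)
        assert rep.mean_accuracy == pytest.approx(
            np.mean(rep.fold_accuracies))
        assert rep.confusion.sum() == len(y)
        # confusion row sums = class counts
        classes, counts = np.unique(y, return_counts=True)
        assert np.array_equal(rep.confusion.sum(axis=1), counts)
        assert all(0 <= v <= 1 for v in rep.per_class_accuracy.values())

    def test_folds_partition_and_stratify(self, seven_class_features):
        F, y = seven_class_features
        rep = cross_validate(None, y, k=3, seed=5,
                             model=ImageClassifier(n_trees=10),
                             precomputed_features=F)
        # every sample in exactly one fold
        assert np.all((rep.fold_of >= 0) & (rep.fold_of < 3))
        for cls in np.unique(y):
            per_fold = [np.sum((y == cls) & (rep.fold_of == f))
                        for f in range(3)]
            ideal = np.sum(y == cls) / 3
            assert all(abs(n - ideal) <= 1 for n in per_fold)

    def test_chance_level_on_shuffled_labels(self, seven_class_features):
        # leakage guard: with labels randomly shuffled, accuracy must sit
        # at chance (1/7) over repeated seeds
        F, y = seven_class_features
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y_shuf = rng.permutation(y)
            rep = cross_validate(None, y_shuf, k=3, seed=seed,
                                 model=ImageClassifier(n_trees=60),
                                 precomputed_features=F)
            accs.append(rep.mean_accuracy)
        mean, sd = np.mean(accs), np.std(accs, ddof=1)
        assert abs(mean - 1 / 7) <= 3 * max(sd, 1e-6)

    def test_small_class_rejected_with_name(self, seven_class_features):
        F, y = seven_class_features
        y2 = y.copy()
        y2[y2 == "prophase"] = "anaphase"
        y2[:2] = "prophase"  # only 2 members now
        with pytest.raises(ValueError, match="prophase"):
            cross_validate(None, y2, k=3, precomputed_features=F,
                           model=ImageClassifier(n_trees=10))

    def test_k_below_two_rejected(self, seven_class_features):
        F, y = seven_class_features
        with pytest.raises(ValueError):
            cross_validate(None, y, k=1, precomputed_features=F)


SEVEN = ["s_g2", "prophase", "prometaphase", "metaphase", "anaphase",
         "telophase", "interphase"]


class TestMergeClasses:
    def test_builtin_mapping_collapses_seven_to_four(self):
        merged = merge_labels(SEVEN)
        assert sorted(set(merged)) == ["early_mitotic", "interphase",
                                       "late_mitotic", "s_g2"]
        assert merge_labels(["prophase"])[0] == "early_mitotic"
        assert merge_labels(["telophase"])[0] == "late_mitotic"

    def test_identity_mapping_leaves_report_unchanged(self,
                                                      seven_class_features):
        F, y = seven_class_features
        rep = cross_validate(None, y, k=3, seed=2,
                             model=ImageClassifier(n_trees=60),
                             precomputed_features=F)
        ident = {c: c for c in np.unique(y)}
        same = merge_classes(rep, ident)
        assert same.mean_accuracy == rep.mean_accuracy
        assert np.array_equal(same.confusion, rep.confusion)

    def test_partial_explicit_mapping_rejected(self):
        with pytest.raises(ValueError, match="not total"):
            merge_labels(SEVEN, {"prophase": "early"})

    def test_merged_cv_accuracy_never_decreases(self, seven_class_features):
        F, y = seven_class_features
        rep = cross_validate(None, y, k=3, seed=4,
                             model=ImageClassifier(n_trees=60),
                             precomputed_features=F)
        merged = merge_classes(rep)
        assert merged.mean_accuracy >= rep.mean_accuracy
        assert sorted(merged.classes) != sorted(rep.classes)

    def test_merge_monotonicity_exhaustive_per_position(self):
        # accuracy is a mean of per-position indicators, so it suffices to
        # check every (truth, prediction) pair: merging maps equal pairs to
        # equal pairs (a function of the label), never breaking a match
        for t, p in itertools.product(SEVEN, repeat=2):
            mt, mp = merge_labels([t])[0], merge_labels([p])[0]
            if t == p:
                assert mt == mp

    def test_merge_monotonicity_exhaustive_short_vectors(self):
        # joint enumeration of all 49^3 (truth, prediction) vectors of
        # length 3: per-position pair matches are precomputed, vector
        # accuracies compared by broadcasting
        names = np.asarray(SEVEN)
        merged_names = merge_labels(SEVEN)
        pairs = list(itertools.product(range(7), repeat=2))
        base = np.array([names[a] == names[b] for a, b in pairs], dtype=int)
        merged = np.array([merged_names[a] == merged_names[b]
                           for a, b in pairs], dtype=int)
        B = base[:, None, None] + base[None, :, None] + base[None, None, :]
        M = (merged[:, None, None] + merged[None, :, None]
             + merged[None, None, :])
        assert B.size == 49 ** 3
        assert np.all(M >= B)

    @pytest.mark.parametrize("seed", range(3))
    def test_merge_monotonicity_random_length6_vectors(self, seed):
        rng = np.random.default_rng(seed)
        names = np.asarray(SEVEN)
        for _ in range(200):
            t = names[rng.integers(0, 7, 6)]
            p = names[rng.integers(0, 7, 6)]
            acc = np.mean(t == p)
            macc = np.mean(merge_labels(t) == merge_labels(p))
            assert macc >= acc
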