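import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboblock import (ClassifierSpec, CVConfig, build_feature_matrix,
                       cross_validate, generate_family, train_predict,
                       vfold_split, FamilySpec, PlantedBlock)
from riboblock.classifiers import pnn_posteriors, _predict_knn, _standardize
from riboblock.features import FeatureMatrix

from conftest import demo_block

KINDS = ("lda", "pnn", "tree", "knn")


def make_fm(values, families):
    values = np.asarray(values)
    blocks = [demo_block("AAA", j + 1) for j in range(values.shape[1])]
    return FeatureMatrix(
        observation_ids=[f"o{i}" for i in range(values.shape[0])],
        families=list(families), block_order=blocks, values=values,
    )


class TestVfoldSplit:
    def test_808_observations_split_80_81(self):
        labels = (["Lys"] * 47 + ["Cob"] * 430 + ["Gly"] * 44 + ["SAMa"] * 40
                  + ["SAM4"] * 40 + ["cdG"] * 155 + ["SAH"] * 52)
        folds = vfold_split(808, labels, CVConfig(v=10, seed=3))
        sizes = sorted(len(f) for f in folds)
        assert sizes == [80, 80] + [81] * 8

    def test_leave_one_out_singletons(self):
        folds = vfold_split(10, ["a", "b"] * 5, CVConfig(v=10, seed=0))
        assert sorted(len(f) for f in folds) == [1] * 10

    def test_deterministic_given_seed(self):
        labels = ["a"] * 17 + ["b"] * 13
        f1 = vfold_split(30, labels, CVConfig(v=7, seed=42))
        f2 = vfold_split(30, labels, CVConfig(v=7, seed=42))
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_n_smaller_than_v_is_error(self):
        with pytest.raises(ValueError, match="smaller"):
            vfold_split(5, ["a"] * 5, CVConfig(v=10))

    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=12, max_size=60),
           st.integers(2, 10))
    @settings(max_examples=60, derandomize=True)
    def test_partition_properties(self, labels, v):
        n = len(labels)
        if n < v:
            return
        folds = vfold_split(n, labels, CVConfig(v=v, seed=1))
        flat = np.concatenate(folds)
        assert len(flat) == n and len(set(flat.tolist())) == n  # disjoint cover
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        labels_arr = np.array(labels)
        for cls in set(labels):
            per_fold = [np.count_nonzero(labels_arr[f] == cls) for f in folds]
            assert max(per_fold) - min(per_fold) <= 1  # stratification

    def test_unstratified_also_balanced(self):
        folds = vfold_split(23, None, CVConfig(v=4, seed=9, stratified=False))
        sizes = sorted(len(f) for f in folds)
        assert sizes == [5, 6, 6, 6]


@pytest.fixture(scope="module")
def separated_fm():
    """Two classes whose single planted block sits at 10 vs 80 (no jitter)."""
    specs = [
        FamilySpec(name="near", n_members=30, mean_length=120, length_sd=3,
                   planted=(PlantedBlock("GGAUCC", 10, 1.0, 0),)),
        FamilySpec(name="far", n_members=30, mean_length=120, length_sd=3,
                   planted=(PlantedBlock("GGAUCC", 80, 1.0, 0),)),
    ]
    datasets = [generate_family(s, seed=21 + i) for i, s in enumerate(specs)]
    blocks = [demo_block("GGAUCC", 10, "near"), demo_block("GGAUCC", 80, "far")]
    return build_feature_matrix(datasets, blocks)


class TestTrainPredict:
    @pytest.mark.parametrize("kind", KINDS)
    def test_separable_classes_are_perfect(self, separated_fm, kind):
        res = cross_validate(ClassifierSpec(kind=kind), separated_fm,
                             CVConfig(v=10, seed=2))
        assert res.fold_ccrs == [1.0] * 10
        assert np.array_equal(np.diag(np.diag(res.confusion.counts)),
                              res.confusion.counts)

    def test_knn_k1_recovers_training_point(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        y = np.array(["a", "b"] * 6)
        preds = train_predict(ClassifierSpec(kind="knn", k=1), X, y, X)
        assert np.array_equal(preds, y)

    def test_knn_tie_goes_to_nearest_tied_class(self):
        X = np.array([[0.1], [0.2], [5.0], [5.1]])
        y = np.array(["a", "a", "b", "b"])
        # K=4: two votes each; the nearest neighbour of 0.0 is class a
        preds = _predict_knn(ClassifierSpec(kind="knn", k=4),
                             X, y, np.array([[0.0]]))
        assert preds.tolist() == ["a"]

    def test_knn_matches_sklearn_when_tie_free(self):
        from sklearn.neighbors import KNeighborsClassifier
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        y = np.array(["a", "b"] * 20)  # odd k + 2 classes: no voting ties
        Xt = rng.normal(size=(15, 4))
        ours = _predict_knn(ClassifierSpec(kind="knn", k=3), X, y, Xt)
        theirs = KNeighborsClassifier(n_neighbors=3).fit(X, y).predict(Xt)
        assert np.array_equal(ours, theirs)

    def test_pnn_posteriors_sum_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        y = np.array(["a", "b", "c", "d"] * 5)
        _, post = pnn_posteriors(X, y, rng.normal(size=(7, 4)), sigma=0.7)
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_pnn_small_sigma_degenerates_to_1nn(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [4, 4], [5, 4], [4, 5]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        Xt = np.array([[0.4, 0.1], [4.6, 4.2], [2.0, 2.1], [0.9, 0.2]])
        pnn = train_predict(ClassifierSpec(kind="pnn", sigma=1e-4), X, y, Xt)
        knn1 = train_predict(ClassifierSpec(kind="knn", k=1), X, y, Xt)
        assert np.array_equal(pnn, knn1)

    def test_lda_matches_sklearn_on_well_conditioned_data(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 1, size=(25, 3)),
                       rng.normal(2.5, 1, size=(25, 3))])
        y = np.array(["a"] * 25 + ["b"] * 25)
        Xt = rng.normal(1.2, 1.5, size=(30, 3))
        ours = train_predict(ClassifierSpec(kind="lda"), X, y, Xt)
        Xs, Xts = _standardize(X, Xt)
        ref = LinearDiscriminantAnalysis(solver="lsqr", priors=[0.5, 0.5])
        theirs = ref.fit(Xs, y).predict(Xts)
        assert np.array_equal(ours, theirs)

    def test_lda_midpoint_boundary_one_feature(self):
        X = np.array([[-1.2], [-1.0], [-0.8], [0.8], [1.0], [1.2]])
        y = np.array(["neg", "neg", "neg", "pos", "pos", "pos"])
        preds = train_predict(ClassifierSpec(kind="lda"), X, y,
                              np.array([[-0.05], [0.05]]))
        assert preds.tolist() == ["neg", "pos"]

    def test_single_class_training_is_error(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="single class"):
            train_predict(ClassifierSpec(kind="lda"), X, ["a"] * 5, X)

    def test_zero_variance_feature_is_tolerated(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.normal(size=16), np.full(16, 7.0)])
        y = np.array(["a", "b"] * 8)
        for kind in KINDS:
            preds = train_predict(ClassifierSpec(kind=kind), X, y, X[:4])
            assert len(preds) == 4

    def test_standardize_uses_training_statistics(self):
        Xtr = np.array([[0.0], [2.0]])
        Xte = np.array([[1.0]])
        a, b = _standardize(Xtr, Xte)
        assert np.allclose(a.ravel(), [-1, 1])
        assert np.allclose(b.ravel(), [0])


class TestCrossValidate:
    def test_every_observation_predicted_once(self, separated_fm):
        res = cross_validate(ClassifierSpec(kind="knn"), separated_fm,
                             CVConfig(v=10, seed=5))
        assert res.confusion.counts.sum() == separated_fm.n_observations

    @pytest.mark.parametrize("kind", KINDS)
    def test_deterministic_given_seed(self, separated_fm, kind):
        r1 = cross_validate(ClassifierSpec(kind=kind), separated_fm, CVConfig(v=5, seed=8))
        r2 = cross_validate(ClassifierSpec(kind=kind), separated_fm, CVConfig(v=5, seed=8))
        assert np.array_equal(r1.confusion.counts, r2.confusion.counts)
        assert r1.fold_ccrs == r2.fold_ccrs

    def test_fold_missing_class_warns_but_runs(self, caplog):
        rng = np.random.default_rng(4)
        values = rng.integers(0, 50, size=(9, 2))
        fams = ["a"] * 4 + ["b"] * 4 + ["rare"]
        fm = make_fm(values, fams)
        with caplog.at_level("WARNING"):
            res = cross_validate(ClassifierSpec(kind="knn"), fm, CVConfig(v=3, seed=0))
        assert any("lacks class" in r.message for r in caplog.records)
        assert res.confusion.counts.sum() == 9

    def test_ccr_mean_equals_pooled_for_equal_folds(self, separated_fm):
        res = cross_validate(ClassifierSpec(kind="tree"), separated_fm,
                             CVConfig(v=10, seed=6))
        assert res.ccr_mean == pytest.approx(res.ccr_pooled)
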