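import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import make_feature_matrix
from smrna import model
from smrna.features import FEATURE_NAMES


def gaussian_classes(rng, n_per_class, shifts, noise=1.0):
    """Stack of N(shift_c, noise) class clouds over all 25 features."""
    X, y = [], []
    for cls, shift in shifts.items():
        block = rng.standard_normal((n_per_class, len(FEATURE_NAMES))) * noise
        block[:, 0] += shift
        X.append(block)
        y.extend([cls] * n_per_class)
    return make_feature_matrix(np.vstack(X), y)


class TestTrainForest:
    def test_separated_classes_low_oob_error(self):
        rng = np.random.default_rng(0)
        fm = gaussian_classes(rng, 100, {"a": 0.0, "b": 8.0}, noise=0.5)
        mdl = model.train_forest(fm, ntree=200, seed=1)
        assert mdl.oob_error <= 0.05

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        fm = gaussian_classes(rng, 150, {"a": 0.0, "b": 0.0, "c": 0.0})
        mdl = model.train_forest(fm, ntree=200, seed=2)
        # expected accuracy under independence: sum_k p_k * q_k = 1/3
        n = 450
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs((1 - mdl.oob_error) - 1 / 3) <= 3 * se

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(2)
        fm = gaussian_classes(rng, 50, {"a": 0.0, "b": 2.0})
        m1 = model.train_forest(fm, ntree=100, seed=7)
        m2 = model.train_forest(fm, ntree=100, seed=7)
        assert np.array_equal(m1.predict(fm), m2.predict(fm))
        assert m1.oob_error == m2.oob_error

    def test_single_class_raises(self):
        rng = np.random.default_rng(3)
        fm = gaussian_classes(rng, 20, {"a": 0.0})
        with pytest.raises(ValueError):
            model.train_forest(fm, ntree=50, seed=0)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        fm = gaussian_classes(rng, 40, {"a": 0.0, "b": 3.0})
        mdl = model.train_forest(fm, ntree=50, seed=5)
        mdl.save(tmp_path / "model")
        back = model.ForestModel.load(tmp_path / "model")
        assert back.selected_features == mdl.selected_features
        assert np.array_equal(back.predict(fm), mdl.predict(fm))


class TestSelectFeatures:
    def test_informative_feature_found_among_noise(self):
        rng = np.random.default_rng(10)
        fm = gaussian_classes(rng, 100, {"a": 0.0, "b": 6.0}, noise=0.5)
        res = model.select_features(fm.data, fm.y, ntree=80, seed=11)
        assert FEATURE_NAMES[0] in res.selected
        assert len(res.selected) <= 4

    def test_pure_noise_flat_trace_small_set_optimistic_bias(self):
        rng = np.random.default_rng(12)
        n = 160
        fm = gaussian_classes(rng, n // 2, {"a": 0.0, "b": 0.0})
        res = model.select_features(fm.data, fm.y, ntree=60, seed=13)
        # the 1-SE rule lands on one of the smallest sets in the trace
        assert len(res.selected) <= 4
        errors = np.array([e for _, e in res.trace])
        se = np.sqrt(0.25 / n)
        # honest full-feature OOB error is chance-level...
        assert abs(errors[0] - 0.5) <= 3 * se
        # ...while repeatedly keeping "important" noise features biases the
        # apparent error optimistically (the pooled-selection signature)
        assert errors.min() < errors[0]

    def test_trace_sets_are_nested_and_shrinking(self):
        rng = np.random.default_rng(14)
        fm = gaussian_classes(rng, 60, {"a": 0.0, "b": 2.0})
        res = model.select_features(fm.data, fm.y, ntree=50, seed=15)
        sets = [set(fs) for fs, _ in res.trace]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller < bigger
        assert len(sets[-1]) == 2

    def test_noise_column_does_not_displace_signal(self):
        # adding pure-noise columns never evicts the informative feature
        rng = np.random.default_rng(16)
        fm = gaussian_classes(rng, 100, {"a": 0.0, "b": 6.0}, noise=0.5)
        votes = 0
        for rep in range(5):
            res = model.select_features(fm.data, fm.y, ntree=100, seed=100 + rep)
            votes += FEATURE_NAMES[0] in res.selected
        assert votes >= 3


class TestStabilitySelection:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(20)
        fm = gaussian_classes(rng, 40, {"a": 0.0, "b": 4.0}, noise=0.5)
        r1 = model.stability_selection(fm, R=2, seed=21, ntree=40)
        r2 = model.stability_selection(fm, R=2, seed=21, ntree=40)
        assert r1.counts.equals(r2.counts)
        assert r1.signs.equals(r2.signs)

    def test_constant_feature_has_sign_zero(self):
        rng = np.random.default_rng(22)
        fm = gaussian_classes(rng, 30, {"a": 0.0, "b": 3.0}, noise=0.5)
        fm.data.iloc[:, 5] = 1.234  # constant everywhere
        signs = model.feature_signs(fm, ["a", "b"])
        assert (signs.iloc[5] == 0).all()
        assert signs.loc[FEATURE_NAMES[0], "b"] == 1
        assert signs.loc[FEATURE_NAMES[0], "a"] == -1


class TestEvaluationReport:
    def test_worked_three_class_confusion(self):
        conf = np.array([[8, 2, 0], [1, 9, 0], [0, 0, 10]])
        rep = model.EvaluationReport(classes=["a", "b", "c"], confusion=conf)
        assert np.allclose(rep.recall, [0.8, 0.9, 1.0])
        assert np.allclose(rep.ppv, [8 / 9, 9 / 11, 1.0])
        assert rep.overall_accuracy == pytest.approx(27 / 30)

    def test_identity_confusion_perfect_metrics(self):
        rep = model.EvaluationReport(classes=["a", "b"], confusion=np.diag([5, 7]))
        assert np.allclose(rep.recall, 1.0)
        assert np.allclose(rep.ppv, 1.0)
        assert np.allclose(rep.acc_k, 1.0)

    def test_metric_identities_on_random_confusions(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            conf = rng.integers(0, 40, size=(k, k))
            conf[0, 0] += 1  # non-empty
            rep = model.EvaluationReport(classes=[str(i) for i in range(k)], confusion=conf)
            total = conf.sum()
            for i in range(k):
                tp = conf[i, i]
                fn = conf[i].sum() - tp
                fp = conf[:, i].sum() - tp
                tn = total - tp - fn - fp
                if tp + fn:
                    assert rep.recall[i] == pytest.approx(tp / (tp + fn))
                if tp + fp:
                    assert rep.ppv[i] == pytest.approx(tp / (tp + fp))
                assert rep.acc_k[i] == pytest.approx((tp + tn) / total)
            assert rep.overall_accuracy == pytest.approx(np.trace(conf) / total)
            assert np.array_equal(conf.sum(axis=1), rep.confusion.sum(axis=1))


class TestCrossValidate:
    def test_separable_classes_high_accuracy(self):
        rng = np.random.default_rng(40)
        fm = gaussian_classes(rng, 60, {"a": -8.0, "b": 0.0, "c": 8.0}, noise=0.5)
        rep = model.cross_validate(fm, k_folds=5, nested=False, ntree=100, seed=41)
        assert rep.overall_accuracy >= 0.95

    def test_single_member_class_excluded_with_report(self):
        rng = np.random.default_rng(42)
        fm = gaussian_classes(rng, 30, {"a": 0.0, "b": 5.0})
        fm.labels.iloc[0] = "rare"
        rep = model.cross_validate(fm, k_folds=3, nested=False, ntree=50, seed=43)
        assert "rare" in rep.excluded_classes
        assert "rare" not in rep.classes

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(44)
        fm = gaussian_classes(rng, 40, {"a": 0.0, "b": 2.0})
        r1 = model.cross_validate(fm, k_folds=4, nested=False, ntree=60, seed=45)
        r2 = model.cross_validate(fm, k_folds=4, nested=False, ntree=60, seed=45)
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_nested_selection_not_optimistic_on_null_data(self):
        # selecting features on the pooled data before CV leaks information;
        # nesting selection inside the folds must not beat it on null data
        rng = np.random.default_rng(46)
        fm = gaussian_classes(rng, 60, {"a": 0.0, "b": 0.0})
        pooled_cols = model.select_features(fm.data, fm.y, ntree=40, seed=47).selected
        pooled = model.cross_validate(
            fm, k_folds=3, nested=False, ntree=40, seed=48, features=pooled_cols
        )
        nested = model.cross_validate(
            fm, k_folds=3, nested=True, ntree=40, seed=48,
            selection_kwargs=dict(ntree=40),
        )
        assert nested.overall_accuracy <= pooled.overall_accuracy + 0.05


class TestPermutationBaseline:
    def test_two_equal_classes_near_half(self):
        rng = np.random.default_rng(50)
        fm = gaussian_classes(rng, 50, {"a": 0.0, "b": 4.0}, noise=0.5)
        accs = model.permutation_baseline(fm, n_perms=10, k_folds=5, ntree=40, seed=51)
        assert abs(float(np.mean(accs)) - 0.5) <= 0.05

    def test_majority_vote_bound_for_unbalanced_mix(self):
        rng = np.random.default_rng(52)
        fm = gaussian_classes(rng, 40, {"a": 0.0, "b": 3.0})
        fm.labels.iloc[:60] = "a"  # 3:1 imbalance
        accs = model.permutation_baseline(fm, n_perms=10, k_folds=5, ntree=40, seed=53)
        p_max = max(np.mean(fm.y == c) for c in np.unique(fm.y))
        assert float(np.mean(accs)) <= p_max + 0.05

    def test_single_permutation_reproducible(self):
        rng = np.random.default_rng(54)
        fm = gaussian_classes(rng, 30, {"a": 0.0, "b": 2.0})
        a1 = model.permutation_baseline(fm, n_perms=1, k_folds=3, ntree=30, seed=55)
        a2 = model.permutation_baseline(fm, n_perms=1, k_folds=3, ntree=30, seed=55)
        assert a1 == a2


class TestProximityMds:
    def test_equidistant_proximity_gives_equal_distances(self):
        # P = I means d_ij = 1 for i != j: a regular simplex
        rng = np.random.default_rng(60)
        n = 6
        D = np.ones((n, n)) - np.eye(n)
        J = np.eye(n) - 1 / n
        B = -0.5 * J @ (D**2) @ J
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1]
        coords = V[:, order[: n - 1]] * np.sqrt(w[order[: n - 1]])
        dists = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        off = dists[~np.eye(n, dtype=bool)]
        assert np.allclose(off, off[0])
        del rng

    def test_two_clusters_separate_on_first_dimension(self):
        rng = np.random.default_rng(61)
        X = rng.standard_normal((60, 25)) * 0.3
        X[:30, 0] += 6
        fm = make_feature_matrix(X, ["a"] * 30 + ["b"] * 30)
        mdl = model.train_forest(fm, ntree=300, seed=62)
        emb = model.proximity_mds(mdl, fm, dims=2)
        d1 = emb.coordinates[:, 0]
        assert (d1[:30].max() < d1[30:].min()) or (d1[30:].max() < d1[:30].min())

    def test_embedding_preserves_distance_ranks(self):
        rng = np.random.default_rng(63)
        X = rng.standard_normal((20, 25)) * 0.3
        X[10:, 0] += 6
        fm = make_feature_matrix(X, ["a"] * 10 + ["b"] * 10)
        mdl = model.train_forest(fm, ntree=500, seed=64)
        emb = model.proximity_mds(mdl, fm, dims=5)
        D = np.sqrt(np.clip(1 - model.forest_proximity(mdl, fm), 0, None))
        emb_d = np.sqrt(((emb.coordinates[:, None] - emb.coordinates[None, :]) ** 2).sum(-1))
        iu = np.triu_indices(len(D), 1)
        assert spearmanr(D[iu], emb_d[iu]).statistic >= 0.9


class TestCrossDatasetValidate:
    def test_resubstitution_at_least_oob(self):
        rng = np.random.default_rng(70)
        fm = gaussian_classes(rng, 60, {"a": 0.0, "b": 1.5})
        mdl = model.train_forest(fm, ntree=100, seed=71)
        rep = model.cross_dataset_validate(fm, fm, nested=False, ntree=100, seed=71)
        assert rep.overall_accuracy >= (1 - mdl.oob_error) - 1e-9

    def test_class_absent_from_training_dropped(self):
        rng = np.random.default_rng(72)
        train = gaussian_classes(rng, 40, {"a": 0.0, "b": 4.0})
        test = gaussian_classes(rng, 20, {"a": 0.0, "b": 4.0, "novel": 8.0})
        rep = model.cross_dataset_validate(train, test, nested=False, ntree=50, seed=73)
        assert rep.excluded_classes == ["novel"]
        assert rep.total == 40
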