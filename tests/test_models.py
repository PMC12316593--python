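import numpy as np
import pandas as pd
import pytest

from pulsebp.errors import InvalidInputError
from pulsebp.features import FEATURE_NAMES
from pulsebp.models import (
    AugmentedPredictor,
    CvPlan,
    cross_validate,
    make_cv_plan,
    predict,
    sliding_train_mask,
    train_forest,
    train_subject_bank,
)
from pulsebp.simulate import simulate_feature_cohort


@pytest.fixture(scope="module")
def cohort():
    return simulate_feature_cohort(n_subjects=4, sequences_per_subject=60, seed=0)


class TestTrainForest:
    def test_constant_target_predicts_constant(self, cohort):
        X, y, _, _ = cohort
        with pytest.warns(UserWarning):
            model = train_forest(X, np.full(len(X), 100.0), n_trees=10, seed=0)
        np.testing.assert_allclose(model.predict(X.head(20)), 100.0)

    def test_determinism_under_seed(self, cohort):
        X, y, _, _ = cohort
        a = train_forest(X, y, n_trees=20, seed=3)
        b = train_forest(X, y, n_trees=20, seed=3)
        np.testing.assert_array_equal(a.predict(X.head(30)), b.predict(X.head(30)))

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            train_forest(pd.DataFrame(columns=FEATURE_NAMES), np.zeros(0))

    def test_nan_target_rejected(self, cohort):
        X, y, _, _ = cohort
        bad = y.copy()
        bad[0] = np.nan
        with pytest.raises(InvalidInputError):
            train_forest(X, bad)

    def test_nan_features_imputed(self, cohort):
        X, y, _, _ = cohort
        Xn = X.copy()
        Xn.loc[Xn.index[:50], "qtc_1"] = np.nan
        model = train_forest(Xn, y, n_trees=10, seed=0)
        assert np.isfinite(model.predict(Xn.head(60))).all()

    def test_linear_feature_ranks_first_in_oob_importance(self):
        # y is an exact function of 'pat' alone; scaled-down version of
        # the 10k-row property (2000 rows, 60 trees, 10 seeds)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(0, 1, (2000, 48)), columns=FEATURE_NAMES)
            y = 10.0 * X["pat"].to_numpy()
            model = train_forest(X, y, n_trees=60, seed=seed,
                                 compute_importance=True)
            top = max(model.oob_importance, key=model.oob_importance.get)
            wins += top == "pat"
        assert wins == 10

    def test_pure_noise_feature_ranks_low(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.normal(0, 1, (800, 48)), columns=FEATURE_NAMES)
            informative = [n for n in FEATURE_NAMES if n != "fractal_1"]
            y = X[informative].sum(axis=1).to_numpy()
            model = train_forest(X, y, n_trees=40, seed=seed,
                                 compute_importance=True)
            ranked = sorted(FEATURE_NAMES, key=model.oob_importance.get,
                            reverse=True)
            hits += ranked.index("fractal_1") >= 36  # bottom quartile
        assert hits >= 8


class TestSubjectBank:
    def test_bank_size(self, cohort):
        X, y, _, subjects = cohort
        bank = train_subject_bank(X, y, subjects, n_trees=10, seed=0)
        assert set(bank) == set(np.unique(subjects))

    def test_small_subject_skipped(self, cohort):
        X, y, _, subjects = cohort
        subjects = subjects.copy()
        subjects[:len(subjects) - 5] = "big"
        with pytest.warns(UserWarning, match="skipped"):
            bank = train_subject_bank(X, y, subjects, n_trees=10, seed=0)
        assert set(bank) == {"big"}

    def test_constant_subject_predicts_constant(self, cohort):
        X, y, _, subjects = cohort
        y = y.copy()
        sid = subjects[0]
        y[subjects == sid] = 90.0
        bank = train_subject_bank(X, y, subjects, n_trees=10, seed=0)
        rows = X.loc[subjects == sid].head(10)
        np.testing.assert_allclose(bank[sid].predict(rows), 90.0)


class TestAugmentedPooling:
    def test_pooled_mean_identity(self, cohort):
        # augmented = (400a + 100b) / 500 where a/b are the model means
        X, y, _, subjects = cohort
        general = train_forest(X, y, n_trees=40, seed=0)
        sub = train_forest(X.head(100), y[:100], n_trees=10, seed=1,
                           min_rows=20)
        aug = AugmentedPredictor(general=general, bank={"s": sub})
        rows = X.head(25)
        a = general.predict(rows)
        b = sub.predict(rows)
        expected = (40 * a + 10 * b) / 50
        np.testing.assert_allclose(aug.predict(rows, "s"), expected, rtol=1e-10)

    def test_equal_models_identity(self, cohort):
        X, y, _, _ = cohort
        m = train_forest(X, y, n_trees=20, seed=0)
        aug = AugmentedPredictor(general=m, bank={"s": m})
        rows = X.head(10)
        np.testing.assert_allclose(aug.predict(rows, "s"), m.predict(rows),
                                   rtol=1e-10)

    def test_unknown_subject_falls_back_with_warning(self, cohort):
        X, y, _, _ = cohort
        m = train_forest(X, y, n_trees=20, seed=0)
        aug = AugmentedPredictor(general=m, bank={})
        with pytest.warns(UserWarning, match="general"):
            out = aug.predict(X.head(5), "nobody")
        np.testing.assert_array_equal(out, m.predict(X.head(5)))

    def test_augmented_between_general_and_subject(self, cohort):
        X, y, _, subjects = cohort
        general = train_forest(X, y, n_trees=40, seed=0)
        sub = train_forest(X.head(100), y[:100] + 20, n_trees=10, seed=1,
                           min_rows=20)
        aug = AugmentedPredictor(general=general, bank={"s": sub})
        rows = X.head(30)
        a, b = general.predict(rows), sub.predict(rows)
        out = aug.predict(rows, "s")
        assert np.all(out >= np.minimum(a, b) - 1e-9)
        assert np.all(out <= np.maximum(a, b) + 1e-9)

    def test_predict_dispatch(self, cohort):
        X, y, _, subjects = cohort
        general = train_forest(X, y, n_trees=10, seed=0)
        bank = {"s": general}
        aug = AugmentedPredictor(general=general, bank=bank)
        rows = X.head(5)
        np.testing.assert_array_equal(predict(aug, rows, mode="general"),
                                      general.predict(rows))
        np.testing.assert_array_equal(
            predict(aug, rows, "s", mode="subject"), general.predict(rows))
        with pytest.raises(InvalidInputError):
            predict(aug, rows, "nobody", mode="subject")


class TestCvPlan:
    def test_partition(self, cohort):
        X, y, _, subjects = cohort
        plan = make_cv_plan(subjects, y, seed=0)
        assert set(plan.fold) == set(range(5))
        assert len(plan.fold) == len(y)

    def test_subject_bp_range_in_every_training_split(self, cohort):
        X, y, _, subjects = cohort
        plan = make_cv_plan(subjects, y, seed=0)
        for f in range(5):
            train = plan.fold != f
            for sid in np.unique(subjects):
                ytr = y[train & (subjects == sid)]
                yall = y[subjects == sid]
                # training split spans most of the subject's BP range
                assert ytr.min() <= np.quantile(yall, 0.1)
                assert ytr.max() >= np.quantile(yall, 0.9)

    def test_sliding_buffer_exclusion(self):
        # 20 consecutive windows, test = {10} -> train excludes 6..14
        subjects = np.array(["a"] * 20)
        wi = np.arange(20)
        fold = np.zeros(20, dtype=int)
        fold[10] = 1
        for f in range(2, 5):
            fold[f] = f  # dummy folds so n_folds = 5
        plan = CvPlan(fold=fold, mode="sliding", window_index=wi,
                      subjects=subjects)
        train = sliding_train_mask(plan, 1)
        excluded = set(np.where(~train)[0])
        assert excluded == set(range(6, 15))

    def test_sliding_requires_window_index(self):
        with pytest.raises(InvalidInputError):
            make_cv_plan(["a", "a"], [1, 2], mode="sliding")

    def test_non_overlapping_no_extra_exclusions(self, cohort):
        X, y, _, subjects = cohort
        plan = make_cv_plan(subjects, y, seed=0)
        for f in range(5):
            train = sliding_train_mask(plan, f)
            np.testing.assert_array_equal(train, plan.fold != f)


class TestCrossValidate:
    def test_out_of_fold_complete_and_disjoint(self, cohort):
        X, y, _, subjects = cohort
        plan = make_cv_plan(subjects, y, seed=0)
        res = cross_validate(X, y, subjects, plan, modes=("general",),
                             n_trees=10, seed=0)
        assert np.isfinite(res["prediction"]["general"]).all()

    def test_beat_audit_sliding(self):
        X, y, _, subjects = simulate_feature_cohort(
            n_subjects=2, sequences_per_subject=100, seed=1)
        wi = np.concatenate([np.arange(100), np.arange(100)])
        plan = make_cv_plan(subjects, y, mode="sliding", window_index=wi,
                            seed=0)
        for f in range(5):
            train = sliding_train_mask(plan, f)
            test = plan.fold == f
            for sid in np.unique(subjects):
                ti = wi[test & (subjects == sid)]
                tr = wi[train & (subjects == sid)]
                if len(ti) and len(tr):
                    assert np.min(np.abs(tr[:, None] - ti[None, :])) > 4

    def test_fewer_than_5_rows_per_fold_rejected(self):
        X, y, _, subjects = simulate_feature_cohort(
            n_subjects=1, sequences_per_subject=20, seed=2)
        plan = make_cv_plan(subjects, y, seed=0)
        with pytest.raises(InvalidInputError):
            cross_validate(X, y, subjects, plan, n_trees=5)
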