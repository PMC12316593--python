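"""Random-forest regression models for systolic/diastolic BP.

Three predictor flavors:

* general — one 400-tree forest trained on the pooled training rows;
* subject — a bank of 100-tree forests, one per subject;
* augmented — the per-tree pooled mean over the union of the general and
  the subject forest (so with defaults (400*a + 100*b)/500 where a and b
  are the two model means).

The underlying trees come from scikit-learn's RandomForestRegressor with
bagging, p/3 candidate features per split, minimum leaf size 5 and no
depth cap.  (The split-variable selection here is standard
variance-reduction; an unbiased curvature-style association test is not
available in the stack and the predictive contract is unchanged.)
Feature importance is out-of-bag permutation importance computed from
each tree's out-of-bag rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import InvalidInputError
from .features import FEATURE_NAMES

N_TREES_GENERAL = 400
N_TREES_SUBJECT = 100
MIN_SUBJECT_SEQUENCES = 20
SLIDING_BUFFER = 4


@dataclass
class ForestModel:
    target: str
    forest: RandomForestRegressor
    feature_names: tuple
    train_medians: pd.Series
    seed: int
    oob_importance: dict | None = None

    @property
    def n_trees(self) -> int:
        return self.forest.n_estimators

    def impute(self, X: pd.DataFrame) -> np.ndarray:
        X = X.loc[:, list(self.feature_names)]
        return X.fillna(self.train_medians).to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(self.impute(X))

    def tree_prediction_sum(self, X: pd.DataFrame) -> np.ndarray:
        """Sum of per-tree predictions (for per-tree pooling)."""
        A = self.impute(X)
        out = np.zeros(len(A))
        for est in self.forest.estimators_:
            out += est.predict(A)
        return out


def train_forest(
    X: pd.DataFrame,
    y: np.ndarray,
    target: str = "systolic",
    n_trees: int = N_TREES_GENERAL,
    seed: int = 0,
    feature_names=None,
    compute_importance: bool = False,
    min_rows: int = 50,
) -> ForestModel:
    """Fit a bagged regression forest with median imputation of NaNs."""
    if feature_names is None:
        feature_names = tuple(n for n in FEATURE_NAMES if n in X.columns)
    X = X.loc[:, list(feature_names)]
    y = np.asarray(y, dtype=float)
    if len(X) == 0:
        raise InvalidInputError("empty training set")
    if len(X) < min_rows:
        raise InvalidInputError(f"need >= {min_rows} training rows, got {len(X)}")
    if np.any(np.isnan(y)):
        raise InvalidInputError("targets must not contain NaN")
    if np.ptp(y) == 0:
        warnings.warn("constant target: forest is degenerate", stacklevel=2)

    medians = X.median(numeric_only=True)
    medians = medians.fillna(0.0)
    A = X.fillna(medians).to_numpy()
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1.0 / 3.0,
        min_samples_leaf=5,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(A, y)
    model = ForestModel(target=target, forest=forest,
                        feature_names=tuple(feature_names),
                        train_medians=medians, seed=seed)
    if compute_importance:
        model.oob_importance = oob_permutation_importance(model, A, y, seed=seed)
    return model


def oob_permutation_importance(model: ForestModel, A: np.ndarray,
                               y: np.ndarray, seed: int = 0) -> dict:
    """Mean per-tree increase in OOB squared error when one feature is
    permuted among that tree's out-of-bag rows."""
    rng = np.random.default_rng(seed)
    n = len(A)
    p = A.shape[1]
    increases = np.zeros(p)
    counts = np.zeros(p)
    for est, samp in zip(model.forest.estimators_,
                         model.forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), samp, assume_unique=False)
        if len(oob) < 2:
            continue
        Ao = A[oob]
        yo = y[oob]
        base = np.mean((est.predict(Ao) - yo) ** 2)
        perm = rng.permutation(len(oob))
        for j in range(p):
            Ap = Ao.copy()
            Ap[:, j] = Ao[perm, j]
            increases[j] += np.mean((est.predict(Ap) - yo) ** 2) - base
            counts[j] += 1
    counts[counts == 0] = 1
    scores = increases / counts
    return dict(zip(model.feature_names, scores))


def train_subject_bank(
    X: pd.DataFrame,
    y: np.ndarray,
    subjects: np.ndarray,
    target: str = "systolic",
    n_trees: int = N_TREES_SUBJECT,
    seed: int = 0,
    feature_names=None,
) -> dict:
    """One forest per subject, trained only on that subject's rows;
    subjects with fewer than 20 sequences are skipped with a warning."""
    subjects = np.asarray(subjects)
    bank = {}
    for i, sid in enumerate(pd.unique(subjects)):
        mask = subjects == sid
        if mask.sum() < MIN_SUBJECT_SEQUENCES:
            warnings.warn(
                f"subject {sid}: only {int(mask.sum())} sequences, skipped",
                stacklevel=2)
            continue
        bank[sid] = train_forest(
            X.loc[mask], np.asarray(y)[mask], target=target, n_trees=n_trees,
            seed=seed + i, feature_names=feature_names, min_rows=MIN_SUBJECT_SEQUENCES)
    return bank


@dataclass
class AugmentedPredictor:
    general: ForestModel
    bank: dict

    def predict(self, X: pd.DataFrame, subject_id) -> np.ndarray:
        sub = self.bank.get(subject_id)
        if sub is None:
            warnings.warn(
                f"subject {subject_id!r} not in bank: falling back to the "
                "general model", stacklevel=2)
            return self.general.predict(X)
        total = self.general.tree_prediction_sum(X) + sub.tree_prediction_sum(X)
        return total / (self.general.n_trees + sub.n_trees)


def predict(model, X: pd.DataFrame, subject_id=None, mode: str = "general"):
    """Dispatch over the three prediction modes."""
    if mode == "general":
        general = model.general if isinstance(model, AugmentedPredictor) else model
        return general.predict(X)
    if mode == "subject":
        bank = model.bank if isinstance(model, AugmentedPredictor) else model
        if subject_id not in bank:
            raise InvalidInputError(f"unknown subject {subject_id!r}")
        return bank[subject_id].predict(X)
    if mode == "augmented":
        if not isinstance(model, AugmentedPredictor):
            raise InvalidInputError("augmented mode needs an AugmentedPredictor")
        return model.predict(X, subject_id)
    raise InvalidInputError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Cross-validation protocols
# ---------------------------------------------------------------------------

@dataclass
class CvPlan:
    fold: np.ndarray                    # fold id per row
    mode: str = "non_overlapping"
    buffer: int = SLIDING_BUFFER
    window_index: np.ndarray | None = None
    subjects: np.ndarray | None = None

    @property
    def n_folds(self) -> int:
        return int(self.fold.max()) + 1


def make_cv_plan(
    subjects,
    y,
    n_folds: int = 5,
    mode: str = "non_overlapping",
    window_index=None,
    seed: int = 0,
) -> CvPlan:
    """Assign each sequence to one of ``n_folds`` folds.

    Within each subject, sequences are binned into ``n_folds`` quantile
    bins of the target and folds drawn per bin, so every subject's
    training split covers that subject's BP range.  In sliding mode the
    caller must pass per-row window indices for overlap filtering.
    """
    subjects = np.asarray(subjects)
    y = np.asarray(y, dtype=float)
    if mode not in ("non_overlapping", "sliding"):
        raise InvalidInputError(f"unknown CV mode {mode!r}")
    if mode == "sliding" and window_index is None:
        raise InvalidInputError("sliding mode requires window_index")
    rng = np.random.default_rng(seed)
    fold = np.full(len(y), -1, dtype=int)
    for sid in pd.unique(subjects):
        idx = np.where(subjects == sid)[0]
        order = idx[np.argsort(y[idx], kind="stable")]
        # quantile bins of the target; round-robin folds inside each bin
        for b in range(n_folds):
            binned = order[b::n_folds]
            shuffled = rng.permutation(binned)
            for i, row in enumerate(shuffled):
                fold[row] = i % n_folds
    return CvPlan(
        fold=fold, mode=mode,
        window_index=None if window_index is None else np.asarray(window_index),
        subjects=subjects)


def sliding_train_mask(plan: CvPlan, test_fold: int) -> np.ndarray:
    """Training rows for one fold.

    Non-overlapping: everything outside the test fold.  Sliding: rows
    within ``buffer`` window indices of any test row of the same subject
    are additionally rejected.
    """
    test = plan.fold == test_fold
    train = ~test
    if plan.mode == "sliding":
        wi = plan.window_index
        for sid in pd.unique(plan.subjects):
            smask = plan.subjects == sid
            test_wi = wi[smask & test]
            if len(test_wi) == 0:
                continue
            rows = np.where(smask & train)[0]
            for r in rows:
                if np.min(np.abs(test_wi - wi[r])) <= plan.buffer:
                    train[r] = False
    return train


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    subjects,
    plan: CvPlan,
    modes=("general",),
    n_trees: int = N_TREES_GENERAL,
    n_trees_subject: int = N_TREES_SUBJECT,
    seed: int = 0,
    feature_names=None,
    target: str = "systolic",
) -> dict:
    """Out-of-fold predictions for each requested mode.

    Returns ``{"prediction": {mode: array}, "fold": fold ids,
    "n_train": per-fold train sizes}``; predictions are NaN where a mode
    could not be applied (e.g. subject missing from the bank).
    """
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    n_folds = plan.n_folds
    if n_folds < 5:
        raise InvalidInputError("need at least 5 folds")
    for f in range(n_folds):
        if (plan.fold == f).sum() < 5:
            raise InvalidInputError(f"fold {f} has fewer than 5 sequences")

    preds = {m: np.full(len(y), np.nan) for m in modes}
    n_train = []
    need_subject = any(m in ("subject", "augmented") for m in modes)
    for f in range(n_folds):
        test = plan.fold == f
        train = sliding_train_mask(plan, f)
        n_train.append(int(train.sum()))
        general = train_forest(
            X.loc[train], y[train], target=target, n_trees=n_trees,
            seed=seed + f, feature_names=feature_names)
        bank = {}
        if need_subject:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bank = train_subject_bank(
                    X.loc[train], y[train], subjects[train], target=target,
                    n_trees=n_trees_subject, seed=seed + 1000 * (f + 1),
                    feature_names=feature_names)
        aug = AugmentedPredictor(general=general, bank=bank)
        test_rows = np.where(test)[0]
        for m in modes:
            if m == "general":
                preds[m][test_rows] = general.predict(X.iloc[test_rows])
            else:
                for sid in pd.unique(subjects[test_rows]):
                    rows = test_rows[subjects[test_rows] == sid]
                    if m == "subject":
                        if sid in bank:
                            preds[m][rows] = bank[sid].predict(X.iloc[rows])
                    else:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            preds[m][rows] = aug.predict(X.iloc[rows], sid)
    return {"prediction": preds, "fold": plan.fold, "n_train": n_train}
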