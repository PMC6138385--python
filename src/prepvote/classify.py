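"""Five-year outcome labels, stratified splitting, class-balanced tree
ensembles with grid tuning, and shadow-feature (Boruta-style) selection.

The ensemble is bagged CART trees with per-node feature subsampling of size
``mtry`` and a per-tree stratified bootstrap that draws an equal number of
samples from each class, equal to the minority-class count — so the trees
never see the raw class imbalance.  The class probability for a sample is
the fraction of trees voting for that class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.tree import DecisionTreeClassifier

from .config import stage_seed

logger = logging.getLogger(__name__)


def make_binary_outcome(survival: pd.DataFrame, horizon_years: float = 5.0) -> pd.Series:
    """0 = dead by the horizon, 1 = alive at the horizon.

    Events after the horizon are censored at the horizon (label 1); patients
    censored before the horizon are labeled alive (overridable upstream by
    excluding them before calling).
    """
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    dead = (survival["event"] == 1) & (survival["time_years"] <= horizon_years)
    return (~dead).astype(int).rename("alive_at_horizon")


def split_train_test(
    outcome: pd.Series, ratio: float = 0.5, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Random stratified split; per-class train/test counts differ by <= 1.

    Fractional per-class training counts are rounded up or down by a seeded
    coin flip so the expected split matches ``ratio`` exactly.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for level, members in outcome.groupby(outcome):
        ids = members.index.to_numpy()
        if ids.size < 2:
            raise ValueError(f"class {level} has fewer than 2 members; cannot split")
        rng.shuffle(ids)
        exact = ids.size * ratio
        n_train = int(np.floor(exact))
        if rng.random() < exact - n_train:
            n_train += 1
        n_train = min(max(n_train, 1), ids.size - 1)
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    return pd.Index(train_ids), pd.Index(test_ids)


class TreeEnsemble:
    """Bagged decision trees with class-balanced per-tree sampling.

    Matches the classical random-forest recipe with the per-class sample
    size pinned to the minority class.  Probabilities are vote fractions.
    """

    def __init__(self, mtry: int, ntree: int, seed: int = 0):
        if ntree < 1:
            raise ValueError("ntree must be >= 1")
        if mtry < 1:
            raise ValueError("mtry must be >= 1")
        self.mtry = int(mtry)
        self.ntree = int(ntree)
        self.seed = int(seed)
        self.trees_: list[DecisionTreeClassifier] = []
        self.bags_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X, y) -> "TreeEnsemble":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if self.mtry > X.shape[1]:
            raise ValueError(f"mtry={self.mtry} exceeds {X.shape[1]} features")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training labels contain a single class")
        class_idx = [np.flatnonzero(y == c) for c in self.classes_]
        n_draw = min(idx.size for idx in class_idx)
        rng = np.random.default_rng(self.seed)
        self.trees_, self.bags_ = [], []
        for _ in range(self.ntree):
            bag = np.concatenate([rng.choice(idx, size=n_draw, replace=True) for idx in class_idx])
            tree = DecisionTreeClassifier(
                max_features=self.mtry,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[bag], y[bag])
            self.trees_.append(tree)
            self.bags_.append(bag)
        self._X_shape = X.shape
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Columns follow ``classes_``; entries are per-class tree-vote fractions."""
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], self.classes_.size))
        for tree in self.trees_:
            pred = tree.predict(X)
            for j, c in enumerate(self.classes_):
                votes[:, j] += pred == c
        return votes / len(self.trees_)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def oob_accuracy(self, X, y) -> float:
        """Out-of-bag vote accuracy; samples never out of bag are skipped."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        votes = np.zeros((X.shape[0], self.classes_.size))
        for tree, bag in zip(self.trees_, self.bags_):
            oob = np.ones(X.shape[0], dtype=bool)
            oob[bag] = False
            if not oob.any():
                continue
            pred = tree.predict(X[oob])
            for j, c in enumerate(self.classes_):
                votes[oob, j] += pred == c
        voted = votes.sum(axis=1) > 0
        if not voted.any():
            return float("nan")
        pred = self.classes_[np.argmax(votes[voted], axis=1)]
        return float(np.mean(pred == y[voted]))

    def permutation_importance(self, X, y, columns=None, seed: int = 0) -> np.ndarray:
        """Per-tree out-of-bag mean decrease in accuracy, averaged over trees.

        Computed tree by tree (not on the aggregated ensemble prediction) so
        duplicated or correlated features still register importance through
        the trees that happened to use them.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        cols = np.arange(X.shape[1]) if columns is None else np.asarray(columns)
        rng = np.random.default_rng(seed)
        drops = np.zeros(X.shape[1])
        counts = np.zeros(X.shape[1])
        for tree, bag in zip(self.trees_, self.bags_):
            oob = np.ones(X.shape[0], dtype=bool)
            oob[bag] = False
            if not oob.any():
                continue
            X_oob, y_oob = X[oob], y[oob]
            base = np.mean(tree.predict(X_oob) == y_oob)
            used = set(tree.tree_.feature[tree.tree_.feature >= 0])
            for j in cols:
                if j not in used:
                    counts[j] += 1
                    continue
                perm = rng.permutation(X_oob.shape[0])
                X_perm = X_oob.copy()
                X_perm[:, j] = X_oob[perm, j]
                drops[j] += base - np.mean(tree.predict(X_perm) == y_oob)
                counts[j] += 1
        with np.errstate(invalid="ignore"):
            imp = np.where(counts > 0, drops / np.maximum(counts, 1), 0.0)
        return imp[cols] if columns is not None else imp


def train_tree_ensemble(features, labels, mtry: int, ntree: int, seed: int = 0) -> TreeEnsemble:
    """Fit the class-balanced bagged-tree ensemble (functional wrapper)."""
    X = features.to_numpy() if hasattr(features, "to_numpy") else features
    y = labels.to_numpy() if hasattr(labels, "to_numpy") else labels
    return TreeEnsemble(mtry=mtry, ntree=ntree, seed=seed).fit(X, y)


@dataclass
class ClassifierResult:
    """Tuned-classifier output on the evaluation half."""

    mtry: int
    ntree: int
    accuracy: float
    feature_set: str
    seed: int
    predictions: pd.DataFrame = field(repr=False)  # index: patient, cols: predicted, poor_probability
    grid_accuracies: dict = field(default_factory=dict, repr=False)


def tune_grid(
    features: pd.DataFrame,
    labels: pd.Series,
    partition: tuple[pd.Index, pd.Index],
    mtry_grid,
    ntree_grid,
    seed: int = 0,
    feature_set: str = "features",
    evaluation: str = "test",
) -> ClassifierResult:
    """Grid-tune (mtry, ntree) by accuracy and return the best classifier's result.

    ``evaluation='test'`` scores each grid point on the held-out half (the
    published protocol); ``'oob'`` scores on out-of-bag training votes.
    Ties prefer smaller mtry, then smaller ntree; each grid point's seed is
    keyed by its parameter values so the result is invariant to grid order.
    """
    if evaluation not in {"test", "oob"}:
        raise ValueError("evaluation must be 'test' or 'oob'")
    train_ids, test_ids = partition
    p = features.shape[1]
    grid = sorted(
        {(int(m), int(n)) for m in mtry_grid for n in ntree_grid if int(m) <= p}
    )
    if not grid:
        raise ValueError(f"no feasible grid points: all mtry exceed {p} features")
    if len(grid) < len(set(mtry_grid)) * len(set(ntree_grid)):
        logger.info("dropped grid points with mtry > %d features", p)

    X_train = features.loc[train_ids].to_numpy(dtype=float)
    y_train = labels.loc[train_ids].to_numpy()
    X_test = features.loc[test_ids].to_numpy(dtype=float)
    y_test = labels.loc[test_ids].to_numpy()

    best = None
    accuracies = {}
    for mtry, ntree in grid:
        model = TreeEnsemble(mtry, ntree, seed=stage_seed(seed, "tune", mtry, ntree))
        model.fit(X_train, y_train)
        if evaluation == "test":
            acc = float(np.mean(model.predict(X_test) == y_test))
        else:
            acc = model.oob_accuracy(X_train, y_train)
        accuracies[(mtry, ntree)] = acc
        if best is None or acc > best[0]:
            best = (acc, mtry, ntree, model)
    assert best is not None
    _, mtry, ntree, model = best

    # poor prognosis = predicted dead = class 0 on the alive-at-horizon scale
    proba = model.predict_proba(X_test)
    poor_col = int(np.flatnonzero(model.classes_ == 0)[0])
    poor_prob = proba[:, poor_col]
    predicted = np.where(poor_prob > 0.5, 0, 1)
    test_acc = float(np.mean(predicted == y_test))
    predictions = pd.DataFrame(
        {"predicted": predicted, "poor_probability": poor_prob}, index=test_ids
    )
    logger.info(
        "tuned ensemble [%s]: mtry=%d ntree=%d (%s accuracy %.3f, test accuracy %.3f)",
        feature_set, mtry, ntree, evaluation, best[0], test_acc,
    )
    return ClassifierResult(
        mtry=mtry,
        ntree=ntree,
        accuracy=test_acc,
        feature_set=feature_set,
        seed=seed,
        predictions=predictions,
        grid_accuracies=accuracies,
    )


def boruta_select(
    features: pd.DataFrame,
    labels: pd.Series,
    max_iter: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
    ntree: int = 100,
) -> list[str]:
    """All-relevant feature selection against shuffled shadow features.

    Each iteration appends shuffled copies of the undecided features (padded
    to at least five shadows), fits the tree ensemble, and scores per-tree
    out-of-bag permutation importance.  A feature scores a hit when it beats
    the best shadow; two-sided binomial tests on the hit counts confirm or
    reject at level ``alpha``.  Features still undecided after ``max_iter``
    are resolved by comparing their median importance history against the
    median of the per-iteration best-shadow importances.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy()
    names = list(features.columns)

    variable = np.ptp(X, axis=0) > 0
    if not variable.any():
        warnings.warn("all candidate features are constant; selecting nothing")
        return []
    active = [i for i in range(len(names)) if variable[i]]
    if len(active) < len(names):
        warnings.warn(f"ignoring {len(names) - len(active)} constant features")

    rng = np.random.default_rng(seed)
    undecided = set(active)
    confirmed: set[int] = set()
    hits = {i: 0 for i in active}
    imp_history: dict[int, list[float]] = {i: [] for i in active}
    shadow_max_history: list[float] = []

    for it in range(1, max_iter + 1):
        if not undecided:
            break
        model_cols = sorted(confirmed | undecided)
        shadow_src = sorted(undecided)
        n_shadow = max(len(shadow_src), 5)
        shadow_cols = [shadow_src[i % len(shadow_src)] for i in range(n_shadow)]
        shadows = np.column_stack(
            [X[rng.permutation(X.shape[0]), j] for j in shadow_cols]
        )
        X_aug = np.column_stack([X[:, model_cols], shadows])
        p_aug = X_aug.shape[1]
        mtry = max(1, int(np.sqrt(p_aug)))
        model = TreeEnsemble(mtry, ntree, seed=stage_seed(seed, "boruta", it)).fit(X_aug, y)
        imp = model.permutation_importance(X_aug, y, seed=stage_seed(seed, "boruta-perm", it))
        real_imp = dict(zip(model_cols, imp[: len(model_cols)]))
        shadow_max = float(imp[len(model_cols):].max())
        shadow_max_history.append(shadow_max)
        for j in undecided:
            imp_history[j].append(real_imp[j])
            if real_imp[j] > shadow_max:
                hits[j] += 1
        # binomial decisions on the accumulated hit counts
        for j in list(undecided):
            pval = binomtest(hits[j], it, 0.5).pvalue
            if pval < alpha:
                if hits[j] > it / 2:
                    confirmed.add(j)
                    undecided.discard(j)
                else:
                    undecided.discard(j)

    if undecided:
        # tentative rescue: median importance vs median best-shadow importance
        shadow_med = float(np.median(shadow_max_history))
        for j in sorted(undecided):
            if np.median(imp_history[j]) > shadow_med:
                confirmed.add(j)
        logger.info("resolved %d tentative features against median shadow importance", len(undecided))

    selected = [names[j] for j in sorted(confirmed)]
    logger.info("shadow-feature selection confirmed %d/%d features", len(selected), len(active))
    return selected
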