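"""Classifier evaluation machinery.

Everything needed to validate the tuna/no-tuna blob classifier: confusion-
matrix metrics (sensitivity, specificity, Cohen's Kappa), ROC AUC, five
replications of two-fold cross-validation (5x2cv), repeated stratified
k-fold (default 30 runs of 10-fold), the corrected resampled t-test for
comparing runs that share training data, four attribute-selection filters
(chi-squared, information gain, linear-SVM weights, stepwise), and the two
protocol-level experiments built from those pieces.

The classifier backends themselves are thin adapters over scikit-learn
(random forest, RBF SVM, multilayer perceptron, entropy decision tree,
k-nearest neighbours); the tested surface is the protocol around them.
Class-imbalance correction (SMOTE / spread subsampling) is applied inside
the training folds by default, so synthetic minority points never leak
into a test fold; ``whole_table_balance`` rebalances the whole table up
front instead, reproducing the simpler whole-table construction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .balance import smote, spread_subsample
from .morphfeatures import FEATURE_COLUMNS

log = logging.getLogger(__name__)

BACKEND_NAMES = ("rf", "svm", "mlp", "tree", "knn")


# ---------------------------------------------------------------------------
# confusion-matrix metrics


@dataclass
class ConfusionMatrix:
    """Binary confusion counts (positive class = tuna presence)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count TP/FP/FN/TN for binary (0/1) label vectors."""
    t = np.asarray(true_labels).astype(int)
    p = np.asarray(predicted_labels).astype(int)
    if t.shape != p.shape:
        raise ValueError(
            f"label length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN); NaN with a warning when no positives exist."""
    denom = cm.tp + cm.fn
    if denom == 0:
        warnings.warn("sensitivity undefined: no positive instances")
        return math.nan
    return cm.tp / denom


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (FP + TN); NaN with a warning when no negatives exist."""
    denom = cm.fp + cm.tn
    if denom == 0:
        warnings.warn("specificity undefined: no negative instances")
        return math.nan
    return cm.tn / denom


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.total


def kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp)
           + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / (n * n)
    if p_e == 1.0:
        warnings.warn("kappa undefined (p_e = 1); reporting 0.0")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def auc(scores, labels) -> float:
    """Area under the empirical ROC curve.

    Computed as the Mann-Whitney probability that a random positive scores
    above a random negative, with ties counted one half — exactly the area
    of the trapezoidal ROC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        warnings.warn("AUC undefined: one class absent")
        return math.nan
    ranks = stats.rankdata(s)
    return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


# ---------------------------------------------------------------------------
# classifier backends


class ClassifierBackend:
    """Adapter giving every learner a fit / score / predict contract.

    ``score`` returns a probability-like ranking score for the positive
    class (predict_proba when available, decision_function otherwise).
    Deterministic given its seed.
    """

    def __init__(self, name: str, estimator, threshold: float = 0.5):
        self.name = name
        self._proto = estimator
        self._threshold = threshold
        self._est = None

    def fresh(self) -> "ClassifierBackend":
        return ClassifierBackend(self.name, clone(self._proto),
                                 self._threshold)

    def fit(self, X, y) -> "ClassifierBackend":
        self._est = clone(self._proto)
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            self._est.fit(X, y)
        return self

    def score(self, X) -> np.ndarray:
        est = self._est
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            pos = list(est.classes_).index(1) if 1 in est.classes_ else -1
            if pos < 0:  # degenerate: positive class absent in training
                return np.zeros(len(X))
            return proba[:, pos]
        return est.decision_function(X)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self._est.predict(X)).astype(int)


def make_backend(name: str, seed: int = 0, **overrides) -> ClassifierBackend:
    """Build one of the five study backends (plus a 'majority' dummy)."""
    if name == "rf":
        est = RandomForestClassifier(
            n_estimators=overrides.pop("n_estimators", 100),
            random_state=seed, n_jobs=1, **overrides)
    elif name == "svm":
        est = make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", C=overrides.pop("C", 1.0), gamma="scale",
                probability=False, random_state=seed, **overrides))
    elif name == "mlp":
        est = make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=overrides.pop(
                "hidden_layer_sizes", (32,)),
                max_iter=overrides.pop("max_iter", 300),
                random_state=seed, **overrides))
    elif name == "tree":
        est = DecisionTreeClassifier(criterion="entropy", random_state=seed,
                                     **overrides)
    elif name == "knn":
        est = make_pipeline(
            StandardScaler(),
            KNeighborsClassifier(
                n_neighbors=overrides.pop("n_neighbors", 5), **overrides))
    elif name == "majority":
        est = DummyClassifier(strategy="most_frequent")
    else:
        raise ValueError(f"unknown backend {name!r}; "
                         f"choose from {BACKEND_NAMES}")
    return ClassifierBackend(name, est)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldRecord:
    run: int
    fold: int
    n_train: int
    n_test: int
    cm: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    kappa: float
    auc: float


@dataclass
class EvalReport:
    """Per-fold and aggregated validation indices for one classifier on
    one dataset.  Aggregates are plain means over fold records (NaN-aware
    for the occasionally undefined sensitivity/AUC)."""

    classifier: str
    dataset: str
    n_runs: int
    n_folds: int
    seed: int
    folds: list = field(default_factory=list)

    def _mean(self, attr: str) -> float:
        vals = np.array([getattr(f, attr) for f in self.folds], dtype=float)
        return float(np.nanmean(vals)) if len(vals) else math.nan

    @property
    def sensitivity(self) -> float:
        return self._mean("sensitivity")

    @property
    def specificity(self) -> float:
        return self._mean("specificity")

    @property
    def kappa(self) -> float:
        return self._mean("kappa")

    @property
    def auc(self) -> float:
        return self._mean("auc")

    @property
    def accuracy(self) -> float:
        return self._mean("accuracy")

    def summary(self) -> dict:
        return {
            "classifier": self.classifier, "dataset": self.dataset,
            "n_runs": self.n_runs, "n_folds": self.n_folds,
            "seed": self.seed,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "kappa": self.kappa, "auc": self.auc,
            "accuracy": self.accuracy,
        }


def _apply_balance(train_table, mode: str, seed: int):
    if mode in (None, "none"):
        return train_table
    if mode == "smote":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return smote(train_table, percent=100.0, seed=seed)
    if mode == "spread":
        return spread_subsample(train_table, majority_factor=0.5, seed=seed)
    raise ValueError(f"unknown balance mode {mode!r}")


def _eval_fold(table, backend: ClassifierBackend, train_idx, test_idx,
               balance: str, seed: int, run: int, fold: int,
               columns=None) -> FoldRecord:
    train = table.subset(train_idx)
    train = _apply_balance(train, balance, seed)
    cols = list(columns) if columns is not None else FEATURE_COLUMNS
    Xtr = train.df[cols].to_numpy(dtype=float)
    ytr = train.labels()
    test = table.subset(test_idx)
    Xte = test.df[cols].to_numpy(dtype=float)
    yte = test.labels()
    b = backend.fresh().fit(Xtr, ytr)
    pred = b.predict(Xte)
    scores = b.score(Xte)
    cm = confusion(yte, pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return FoldRecord(
            run=run, fold=fold, n_train=len(train_idx), n_test=len(test_idx),
            cm=cm, accuracy=accuracy(cm), sensitivity=sensitivity(cm),
            specificity=specificity(cm), kappa=kappa(cm),
            auc=auc(scores, yte),
        )


def _stratified_partition(labels: np.ndarray, k: int, rng) -> list[np.ndarray]:
    """Random stratified split of indices into k folds (sizes differ by <=1
    overall and per class)."""
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0  # rotate the round-robin start so class remainders do not
    # pile up in the same fold: overall fold sizes then differ by <= 1
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
        offset = (offset + len(idx)) % k
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def make_5x2_partitions(labels: np.ndarray, seed: int):
    """Ten (train_idx, test_idx) pairs: 5 replications of stratified 2-fold.

    Within a replication the two folds are disjoint, exhaustive and differ
    in size by at most one; a partition that leaves a class empty in either
    fold is resampled (logged).
    """
    rng = np.random.default_rng(seed)
    parts = []
    for rep in range(5):
        for attempt in range(20):
            f0, f1 = _stratified_partition(labels, 2, rng)
            if len(np.unique(labels[f0])) > 1 and \
                    len(np.unique(labels[f1])) > 1:
                break
            log.info("5x2cv replication %d: class empty in a fold, resampling",
                     rep)
        parts.append((rep, 0, f1, f0))  # train on f1, test on f0
        parts.append((rep, 1, f0, f1))
    return parts


def five_by_two_cv(table, backend, seed: int = 0, balance: str = "none",
                   columns=None) -> list[FoldRecord]:
    """Five replications of two-fold CV; returns the ten fold records.

    Balancing (if requested) is applied to the training half only.
    """
    if isinstance(backend, str):
        backend = make_backend(backend, seed=seed)
    labels = table.labels()
    if min(np.bincount(labels, minlength=2)) < 2:
        raise ValueError("need at least 2 instances per class for 5x2cv")
    records = []
    for rep, fold, tr, te in make_5x2_partitions(labels, seed):
        records.append(_eval_fold(table, backend, tr, te, balance,
                                  seed + 31 * rep + fold, rep, fold, columns))
    return records


def repeated_kfold(table, backend, runs: int = 30, k: int = 10,
                   seed: int = 0, balance: str = "none",
                   dataset_name: str = "TOTAL",
                   columns=None) -> EvalReport:
    """``runs`` independent rounds of stratified k-fold CV (default 30x10)."""
    if isinstance(backend, str):
        backend = make_backend(backend, seed=seed)
    labels = table.labels()
    if min(np.bincount(labels, minlength=2)) < k and k > 2:
        raise ValueError(
            f"k={k} exceeds the minority class count; stratification "
            "impossible")
    report = EvalReport(classifier=backend.name, dataset=dataset_name,
                        n_runs=runs, n_folds=k, seed=seed)
    rng = np.random.default_rng(seed)
    all_idx = np.arange(len(table.df))
    for run in range(runs):
        folds = _stratified_partition(labels, k, rng)
        assert sum(len(f) for f in folds) == len(all_idx)
        for j, te in enumerate(folds):
            tr = np.setdiff1d(all_idx, te)
            report.folds.append(
                _eval_fold(table, backend, tr, te, balance,
                           seed + 101 * run + j, run, j, columns))
    return report


# ---------------------------------------------------------------------------
# corrected resampled t-test


def corrected_resampled_ttest(diffs, n_train: int, n_test: int
                              ) -> tuple[float, float]:
    """Paired t-test over CV accuracy differences with the variance
    correction for overlapping training sets.

    t = mean(d) / sqrt((1/J + n_test/n_train) * s2_d) with J = len(diffs)
    and s2_d the sample variance; the p-value is two-sided Student-t with
    J - 1 degrees of freedom.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 differences")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("fold sizes must be positive")
    j = len(d)
    mean = float(d.mean())
    s2 = float(d.var(ddof=1))
    if s2 == 0.0 or float(d.max()) == float(d.min()):
        if mean == 0.0:
            return 0.0, 1.0
        log.info("zero variance with nonzero mean: reporting t=+/-inf, p=0")
        return math.copysign(math.inf, mean), 0.0
    t = mean / math.sqrt((1.0 / j + n_test / n_train) * s2)
    p = 2.0 * stats.t.sf(abs(t), df=j - 1)
    return t, float(p)


# ---------------------------------------------------------------------------
# attribute-selection filters


def _label_entropy(y: np.ndarray) -> float:
    return _entropy(np.bincount(y))


def _mdlp_cuts(xs: np.ndarray, ys: np.ndarray, lo: int, hi: int,
               cuts: list[float]) -> None:
    """Fayyad-Irani recursive entropy partitioning on sorted data.

    A binary split is accepted only when its information gain exceeds the
    minimum-description-length cost, so an uninformative feature yields no
    cuts at all (and hence zero chi-squared / information-gain score).
    """
    n = hi - lo
    if n < 4:
        return
    seg_x = xs[lo:hi]
    seg_y = ys[lo:hi]
    ent_s = _label_entropy(seg_y)
    if ent_s == 0.0:
        return
    # candidate boundaries where x changes; prefix class counts
    change = np.flatnonzero(seg_x[1:] != seg_x[:-1]) + 1
    if len(change) == 0:
        return
    pos = np.cumsum(seg_y == 1)
    tot1 = change.astype(float)
    pos1 = pos[change - 1].astype(float)
    tot2 = n - tot1
    pos2 = pos[-1] - pos1

    def h(p_counts, n_counts):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = p_counts / n_counts
            q = 1.0 - p
            out = -(np.where(p > 0, p * np.log2(p), 0.0)
                    + np.where(q > 0, q * np.log2(q), 0.0))
        return out

    h1 = h(pos1, tot1)
    h2 = h(pos2, tot2)
    gains = ent_s - (tot1 / n) * h1 - (tot2 / n) * h2
    best = int(np.argmax(gains))
    gain = float(gains[best])
    i = int(change[best])

    def k_of(sub_y):
        return len(np.unique(sub_y))

    k = k_of(seg_y)
    k1 = k_of(seg_y[:i])
    k2 = k_of(seg_y[i:])
    delta = math.log2(3 ** k - 2) - (k * ent_s - k1 * float(h1[best])
                                     - k2 * float(h2[best]))
    threshold = (math.log2(n - 1) + delta) / n
    if gain <= threshold:
        return
    cuts.append(0.5 * (seg_x[i - 1] + seg_x[i]))
    _mdlp_cuts(xs, ys, lo, lo + i, cuts)
    _mdlp_cuts(xs, ys, lo + i, hi, cuts)


def _supervised_bins(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Discretise a feature by MDL-stopped entropy partitioning."""
    if np.all(x == x[0]):
        return np.zeros(len(x), dtype=int)
    order = np.argsort(x, kind="stable")
    cuts: list[float] = []
    _mdlp_cuts(x[order], y[order], 0, len(x), cuts)
    return np.digitize(x, np.sort(cuts))


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def chi2_score(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson chi-squared statistic of class vs entropy-binned feature."""
    bins = _supervised_bins(x, y)
    obs = pd.crosstab(bins, y).to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 0.0
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def infogain_score(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information (bits) between class and entropy-binned feature."""
    bins = _supervised_bins(x, y)
    n = len(y)
    h_y = _entropy(np.bincount(y))
    cond = 0.0
    for b in np.unique(bins):
        sel = bins == b
        cond += sel.sum() / n * _entropy(np.bincount(y[sel]))
    return max(h_y - cond, 0.0)


def svm_weight_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|weight| per feature from a linear max-margin classifier on
    standardised features."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        svc = LinearSVC(C=1.0, max_iter=5000, random_state=0).fit(Z, y)
    return np.abs(svc.coef_[0])


def rank_features(table, method: str, columns=None) -> list[tuple[str, float]]:
    """Rank features by relevance to the class, best first.

    ``method`` is one of ``chi2``, ``infogain``, ``svm_weight``.  Ties are
    broken by canonical column order (stable sort).
    """
    cols = list(columns) if columns is not None else FEATURE_COLUMNS
    X = table.df[cols].to_numpy(dtype=float)
    y = table.labels()
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to rank features")
    if method == "chi2":
        scores = np.array([chi2_score(X[:, i], y) for i in range(len(cols))])
    elif method == "infogain":
        scores = np.array([infogain_score(X[:, i], y)
                           for i in range(len(cols))])
    elif method == "svm_weight":
        scores = svm_weight_scores(X, y)
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    order = np.argsort(-scores, kind="stable")
    return [(cols[i], float(scores[i])) for i in order]


def stepwise_select(table, criterion: str = "bic", columns=None,
                    max_sweeps: int = 40) -> list[str]:
    """Greedy forward-backward feature selection on a logistic model.

    Candidate moves are scored by an information criterion (BIC or AIC) of
    a regularised logistic regression on standardised features; selection
    stops at the criterion optimum, so the subset size is data-dependent.
    Returns the selected feature names in canonical column order.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import log_loss

    cols = list(columns) if columns is not None else FEATURE_COLUMNS
    X = table.df[cols].to_numpy(dtype=float)
    y = table.labels()
    n = len(y)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    penalty = math.log(n) if criterion == "bic" else 2.0

    def crit(subset: list[int]) -> float:
        k = len(subset) + 1
        if not subset:
            p = np.full(n, y.mean())
            ll = -log_loss(y, np.clip(p, 1e-12, 1 - 1e-12), normalize=False)
        else:
            with warnings.catch_warnings():
                from sklearn.exceptions import ConvergenceWarning

                warnings.simplefilter("ignore", ConvergenceWarning)
                lr = LogisticRegression(C=100.0, max_iter=500,
                                        random_state=0).fit(Z[:, subset], y)
            p = np.clip(lr.predict_proba(Z[:, subset])[:, 1], 1e-12, 1 - 1e-12)
            ll = -log_loss(y, p, normalize=False)
        return -2.0 * ll + penalty * k

    current: list[int] = []
    best = crit(current)
    cache: dict[tuple, float] = {tuple(current): best}

    def scored(subset: list[int]) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = crit(sorted(subset))
        return cache[key]

    for _ in range(max_sweeps):
        changed = False
        # forward
        candidates = [i for i in range(len(cols)) if i not in current]
        if candidates:
            vals = [(scored(current + [i]), i) for i in candidates]
            v, i = min(vals)
            if v < best - 1e-9:
                current.append(i)
                best = v
                changed = True
        # backward
        if len(current) > 1:
            vals = [(scored([j for j in current if j != i]), i)
                    for i in current]
            v, i = min(vals)
            if v < best - 1e-9:
                current.remove(i)
                best = v
                changed = True
        if not changed:
            break
    return [cols[i] for i in sorted(current)]


# ---------------------------------------------------------------------------
# protocol experiments


def evaluate_subset_5x2(table, columns, seed: int = 0, backend="rf",
                        backend_kwargs=None) -> list[FoldRecord]:
    """5x2cv of one feature subset (fixed partitions given the seed, so
    different subsets are paired fold-for-fold)."""
    backend_kwargs = backend_kwargs or {}
    b = make_backend(backend, seed=seed, **backend_kwargs) \
        if isinstance(backend, str) else backend
    return five_by_two_cv(table, b, seed=seed, columns=columns)


def run_experiment1(table, sizes=tuple(range(3, 20, 2)), seed: int = 0,
                    backend: str = "rf", backend_kwargs=None,
                    filters=("chi2", "infogain", "svm_weight")
                    ) -> pd.DataFrame:
    """Reduced-dataset comparison grid.

    For each attribute filter at each subset size (3..19 step 2 by
    default), plus one stepwise row and one full-set row: run 5x2cv with
    the given backend on the reduced table and compare its per-fold
    accuracy to the full 20-feature run with the corrected resampled
    t-test.  Returns a 29-row DataFrame (3 filters x 9 sizes + stepwise +
    full).
    """
    cols = FEATURE_COLUMNS
    full_records = evaluate_subset_5x2(table, cols, seed, backend,
                                       backend_kwargs)
    full_acc = np.array([r.accuracy for r in full_records])
    n_train = full_records[0].n_train
    n_test = full_records[0].n_test

    rows = [{
        "selector": "full", "n_features": len(cols),
        "features": ";".join(cols),
        "kappa": float(np.mean([r.kappa for r in full_records])),
        "accuracy": float(full_acc.mean()),
        "t": 0.0, "p": 1.0,
    }]

    def add_row(selector: str, subset: list[str]) -> None:
        recs = evaluate_subset_5x2(table, subset, seed, backend,
                                   backend_kwargs)
        acc = np.array([r.accuracy for r in recs])
        diffs = acc - full_acc
        if np.allclose(diffs, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = corrected_resampled_ttest(diffs, n_train, n_test)
        rows.append({
            "selector": selector, "n_features": len(subset),
            "features": ";".join(subset),
            "kappa": float(np.mean([r.kappa for r in recs])),
            "accuracy": float(acc.mean()), "t": t, "p": p,
        })

    rankings = {f: [name for name, _ in rank_features(table, f)]
                for f in filters}
    for f in filters:
        for size in sizes:
            add_row(f, rankings[f][:size])
    add_row("stepwise", stepwise_select(table))
    return pd.DataFrame(rows)


def run_experiment2(table, backends=BACKEND_NAMES, runs: int = 30,
                    k: int = 10, seed: int = 0,
                    datasets=("TOTAL", "SMOTE", "SPREAD"),
                    whole_table_balance: bool = False,
                    backend_kwargs=None) -> dict:
    """Dataset x classifier evaluation grid (3 x 5 EvalReports by default).

    ``TOTAL`` uses the table as is; ``SMOTE`` / ``SPREAD`` rebalance within
    the training folds (or the whole table first, with
    ``whole_table_balance``).
    """
    balance_of = {"TOTAL": "none", "SMOTE": "smote", "SPREAD": "spread"}
    backend_kwargs = backend_kwargs or {}
    grid = {}
    for ds in datasets:
        mode = balance_of[ds]
        tab = table
        fold_balance = mode
        if whole_table_balance and mode != "none":
            tab = _apply_balance(table, mode, seed)
            fold_balance = "none"
        for name in backends:
            b = make_backend(name, seed=seed, **backend_kwargs)
            grid[(ds, name)] = repeated_kfold(
                tab, b, runs=runs, k=k, seed=seed, balance=fold_balance,
                dataset_name=ds)
    return grid
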