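"""Module-activity features and the SVM-RFE outcome classifier.

Member-gene measurements are z-scored gene-wise across patients; a module's
activity in a sample is the sum of its member z-scores divided by sqrt(n)
(so activity is on the same scale regardless of module size).  In combined
mode every module yields two feature columns — one from expression, one from
promoter methylation — and a soft-margin SVM with an inhomogeneous quadratic
kernel (x·x' + 1)^2 is trained on them.  Recursive feature elimination drops
the lowest-ranked feature per iteration, ranking by the change in the SVM's
dual objective when a feature is masked (Guyon's criterion), and keeps the
subset with the best cross-validated accuracy.  Accuracy is reported by the
paired leave-one-out scheme: equal positive/negative test panels, each fold
holding out one positive-negative pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import polynomial_kernel
from sklearn.svm import SVC

from .io import NEGATIVE, POSITIVE, OmicsMatrix
from .search import Module

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cohort handling


def select_training_extremes(
    survival: pd.Series,
    k: int = 21,
    upper: float = 2.5,
    lower: float = 0.5,
) -> tuple[list[str], list[str]]:
    """The k longest survivors above ``upper`` and k shortest below ``lower``
    (years).  Ties at the k-th position break by sample id.  Returns
    (long_survivors, short_survivors)."""
    if (survival <= 0).any():
        raise ValueError("survival times must be positive")
    long_pool = survival[survival > upper]
    short_pool = survival[survival < lower]
    if len(long_pool) < k or len(short_pool) < k:
        raise ValueError(
            f"need {k} samples beyond each threshold; have {len(long_pool)} "
            f"above {upper} and {len(short_pool)} below {lower}"
        )
    longest = sorted(long_pool.index, key=lambda s: (-survival[s], s))[:k]
    shortest = sorted(short_pool.index, key=lambda s: (survival[s], s))[:k]
    return list(longest), list(shortest)


def zscore_normalize(matrix: OmicsMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Gene-wise z-scores across samples (sample sd, ddof=1).

    Constant genes become all-zero rows and are returned in the flag list.
    """
    if len(matrix.samples) < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    values = matrix.values
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    flagged = list(values.index[sd == 0])
    safe_sd = sd.replace(0.0, 1.0)
    z = values.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[flagged] = 0.0
    if flagged:
        logger.warning("%d constant gene(s) z-scored to 0", len(flagged))
    return z, flagged


def module_activity(module: Module, z: pd.DataFrame, sample: str) -> float:
    """Activity of one module in one sample: sum of member z-scores / sqrt(n),
    over the member genes present in the z-matrix."""
    present = sorted(module.genes & set(z.index))
    if not present:
        raise ValueError("no member gene of the module is present in the matrix")
    return float(z.loc[present, sample].sum() / math.sqrt(len(present)))


def _activity_row(genes: frozenset, z: pd.DataFrame) -> pd.Series | None:
    present = sorted(genes & set(z.index))
    if not present:
        return None
    if len(present) < len(genes):
        logger.warning(
            "module missing %d member gene(s) in this analyte", len(genes) - len(present)
        )
    return z.loc[present].sum(axis=0) / math.sqrt(len(present))


@dataclass
class ActivityMatrix:
    """Samples × (module, analyte) activity features plus outcome labels."""

    values: pd.DataFrame  # rows = samples, columns = feature ids
    labels: pd.Series  # sample -> "positive" | "negative"

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, samples: Sequence[str] | None = None,
               features: Sequence[str] | None = None) -> "ActivityMatrix":
        vals = self.values
        if samples is not None:
            vals = vals.loc[list(samples)]
        if features is not None:
            vals = vals[list(features)]
        return ActivityMatrix(vals, self.labels)

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        X = self.values.to_numpy(float)
        y = np.array([1 if self.labels[s] == POSITIVE else -1 for s in self.samples])
        return X, y


def build_feature_matrix(
    modules: Sequence[Module],
    expr_z: pd.DataFrame | None,
    meth_z: pd.DataFrame | None,
    samples: Sequence[str],
    labels: pd.Series,
    mode: str = "combined",
) -> ActivityMatrix:
    """One activity column per (module, analyte).

    In ``combined`` mode every module contributes an expression column and a
    methylation column (a column is omitted with a warning when no member
    gene exists in that analyte); single-analyte modes keep only the module's
    native analyte.
    """
    if not modules:
        raise ValueError("no modules to build features from")
    z_by_analyte = {"expression": expr_z, "methylation": meth_z}
    columns: dict[str, pd.Series] = {}
    for i, mod in enumerate(modules):
        name = mod.name or f"module{i + 1:03d}"
        if mode == "combined":
            analytes = ["expression", "methylation"]
        elif mode in ("expression", "methylation"):
            analytes = [mode]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for analyte in analytes:
            z = z_by_analyte[analyte]
            if z is None:
                continue
            row = _activity_row(mod.genes, z)
            if row is None:
                logger.warning("module %s has no member gene in %s; column omitted",
                               name, analyte)
                continue
            columns[f"{name}|{analyte[0]}"] = row.loc[list(samples)]
    if not columns:
        raise ValueError("no computable activity features")
    values = pd.DataFrame(columns, index=list(samples))
    return ActivityMatrix(values=values, labels=labels)


# ---------------------------------------------------------------------------
# SVM, ranking, RFE


@dataclass
class TrainedClassifier:
    kernel: str
    regularization: float
    model: "_StdSVC"
    feature_ids: list[str]
    feature_weights: dict[str, float] = field(default_factory=dict)
    selected_features: list[str] = field(default_factory=list)
    elimination_order: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


class _StdSVC:
    """Soft-margin SVM with per-feature standardisation fitted on the
    training rows.  Activity columns live on widely different scales (a
    strongly deregulated module reaches activities an order of magnitude
    above background), which would dominate the inhomogeneous polynomial
    kernel (x.x' + 1)^2; standardising restores a well-conditioned kernel.
    """

    def __init__(self, kernel: str, C: float):
        if kernel == "quadratic":
            self.svc = SVC(kernel="poly", degree=2, gamma=1.0, coef0=1.0, C=C)
        elif kernel == "linear":
            self.svc = SVC(kernel="linear", C=C)
        else:
            raise ValueError(f"unknown kernel {kernel!r}")

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_StdSVC":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd_ = sd
        self.svc.fit(self.transform(X), y)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self.transform(X))

    @property
    def support_(self):
        return self.svc.support_

    @property
    def dual_coef_(self):
        return self.svc.dual_coef_

    @property
    def coef_(self):
        return self.svc.coef_


def _make_svc(kernel: str, C: float) -> _StdSVC:
    return _StdSVC(kernel, C)


def train_svm(
    features: ActivityMatrix,
    kernel: str = "quadratic",
    regularization: float = 1.0,
) -> TrainedClassifier:
    """Fit the soft-margin SVM on all rows of the feature matrix."""
    X, y = features.xy()
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    model = _make_svc(kernel, regularization)
    model.fit(X, y)
    clf = TrainedClassifier(
        kernel=kernel, regularization=regularization, model=model,
        feature_ids=features.features,
    )
    clf.feature_weights = dict(
        zip(features.features, _feature_criteria(model, X, kernel))
    )
    return clf


def _feature_criteria(model: "_StdSVC", X: np.ndarray, kernel: str) -> np.ndarray:
    """Per-feature ranking criterion.

    Quadratic kernel: Guyon's measure |W² − W²₍₋f₎| — the change in the dual
    objective's margin term αᵀHα when feature f is masked from the support
    vectors, keeping the multipliers fixed.  Linear kernel: |w_f| from the
    primal weight vector.
    """
    if kernel == "linear":
        return np.abs(model.coef_).ravel()
    sv = model.transform(X)[model.support_]
    beta = model.dual_coef_.ravel()  # y_i * alpha_i

    def margin_term(cols: np.ndarray) -> float:
        K = polynomial_kernel(sv[:, cols], degree=2, gamma=1.0, coef0=1.0)
        return float(beta @ K @ beta)

    all_cols = np.arange(X.shape[1])
    w2 = margin_term(all_cols)
    crit = np.empty(X.shape[1])
    for f in range(X.shape[1]):
        crit[f] = abs(w2 - margin_term(np.delete(all_cols, f)))
    return crit


def _cv_accuracy(features: ActivityMatrix, kernel: str, C: float, cv) -> float:
    """Deterministic cross-validated accuracy on the given rows.

    ``cv`` is either "loo" (leave-one-out) or an sklearn-style splitter
    (e.g. RepeatedStratifiedKFold with a fixed random_state).
    """
    X, y = features.xy()
    if cv == "loo":
        correct = 0
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            if len(set(y[mask])) < 2:
                continue
            model = _make_svc(kernel, C)
            model.fit(X[mask], y[mask])
            correct += int(model.predict(X[i : i + 1])[0] == y[i])
        return correct / len(y)
    accs = []
    for train_idx, test_idx in cv.split(X, y):
        model = _make_svc(kernel, C)
        model.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def default_rfe_cv(min_class_count: int = 5):
    """Default CV scheme for feature selection: repeated stratified k-fold
    (k = 5 or the smallest class count, 8 repeats, fixed seed) — a smoother
    accuracy estimate than LOO on the small training panels this design
    uses, hence fewer ties along the elimination path."""
    from sklearn.model_selection import RepeatedStratifiedKFold

    n_splits = max(2, min(5, min_class_count))
    return RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=8, random_state=0)


def rfe_select(
    features: ActivityMatrix,
    kernel: str = "quadratic",
    regularization: float = 1.0,
    cv=None,
) -> tuple[list[str], list[tuple[int, float]], list[str]]:
    """Recursive feature elimination.

    Repeats: estimate cross-validated accuracy with the current feature set,
    rank features by the SVM weight criterion, remove the lowest-ranked —
    down to a single feature.  ``cv`` is "loo" or an sklearn splitter
    (default: repeated stratified 5-fold, :func:`default_rfe_cv`).  Returns
    (best feature subset, accuracy path as (n_features, accuracy) pairs,
    elimination order first-removed-first).  The best subset maximises
    accuracy; ties go to the smaller subset.
    """
    if cv is None:
        counts = features.labels.loc[features.samples].value_counts()
        cv = default_rfe_cv(int(counts.min()))
    current = list(features.features)
    if not current:
        raise ValueError("no features")
    path: list[tuple[int, float]] = []
    snapshots: list[list[str]] = []
    eliminated: list[str] = []
    while current:
        sub = features.subset(features=current)
        acc = _cv_accuracy(sub, kernel, regularization, cv)
        path.append((len(current), acc))
        snapshots.append(list(current))
        if len(current) == 1:
            break
        clf = train_svm(sub, kernel, regularization)
        crit = clf.feature_weights
        worst = min(current, key=lambda f: (crit[f], f))
        eliminated.append(worst)
        current = [f for f in current if f != worst]
    # max accuracy; ties -> smaller subset (later entries are smaller)
    best_idx = max(range(len(path)), key=lambda i: (path[i][1], i))
    return snapshots[best_idx], path, eliminated


def paired_loocv(
    features: ActivityMatrix,
    positives: Sequence[str],
    negative_pool: Sequence[str],
    n_repeats: int = 100,
    seed: int = 0,
    kernel: str = "quadratic",
    regularization: float = 1.0,
    feature_subset: Sequence[str] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Paired leave-one-out cross-validation accuracy.

    Per repeat: draw |positives| negatives from the held-out pool, pair them
    1:1 with the fixed positives by a shuffled index, and run one fold per
    pair — train on the remaining pairs, test on the held-out pair.  Returns
    (mean accuracy, sd, per-repeat accuracies) over ``n_repeats`` panels.
    """
    k = len(positives)
    if len(negative_pool) < k:
        raise ValueError(
            f"negative pool ({len(negative_pool)}) smaller than positive panel ({k})"
        )
    feats = features if feature_subset is None else features.subset(
        features=feature_subset
    )
    rng = np.random.default_rng(seed)
    accs = np.empty(n_repeats)
    pool = list(negative_pool)
    for r in range(n_repeats):
        negs = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        order = rng.permutation(k)
        pairs = [(positives[i], negs[order[i]]) for i in range(k)]
        panel = [s for pair in pairs for s in pair]
        sub = feats.subset(samples=panel)
        X, y = sub.xy()
        correct = 0
        for f in range(k):
            test_idx = [2 * f, 2 * f + 1]
            mask = np.ones(len(panel), dtype=bool)
            mask[test_idx] = False
            model = _make_svc(kernel, regularization)
            model.fit(X[mask], y[mask])
            correct += int((model.predict(X[test_idx]) == y[test_idx]).sum())
        accs[r] = correct / (2 * k)
    return float(accs.mean()), float(accs.std(ddof=1)) if n_repeats > 1 else 0.0, accs


def top_genes_baseline(
    significance: pd.DataFrame, z: pd.DataFrame, n_genes: int,
    samples: Sequence[str], labels: pd.Series,
) -> ActivityMatrix:
    """Size-matched single-gene benchmark: the top differential genes, each as
    its own z-score feature (no network information)."""
    sig = significance.reindex(z.index).copy()
    sig["absd"] = -sig["d"].abs()
    top = sig.sort_values(["q", "absd"]).index[:n_genes]
    values = z.loc[top, list(samples)].T
    return ActivityMatrix(values=values, labels=labels)
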