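"""Condition decoding from connectivity features with leakage-safe
cross-validation.

A random forest is trained to tell drug from placebo sessions using FC or
EC feature vectors. All preprocessing — near-zero-variance and correlation
pruning, covariate residualization — is fitted inside each training fold
and merely applied to the held-out fold, and folds are grouped by subject
so a participant's two sessions can never straddle the train/test split.
Performance is summarised as cross-validated balanced accuracy (BAC), its
significance by a permutation test that flips condition labels within
subject (the paired design's exchangeable transformation), classifiers are
compared with McNemar's test on their pooled out-of-fold predictions, and
feature relevance by the mean decrease in accuracy on permuted out-of-bag
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from .group_stats import CovariateResidualizer

LABELS = ("placebo", "drug")


@dataclass
class ClassifierReport:
    """Pooled out-of-fold decoding results."""

    fold_assignments: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    bac: float
    perm_null: np.ndarray | None = None
    perm_p: float | None = None
    importances: np.ndarray | None = None
    importances_sd: np.ndarray | None = None
    pruned: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class _FoldModel:
    forest: RandomForestClassifier
    kept: np.ndarray
    residualizer: CovariateResidualizer | None
    train_idx: np.ndarray
    test_idx: np.ndarray
    x_train: np.ndarray
    y_train: np.ndarray


def prune_features(
    x: np.ndarray, var_tol: float = 1e-10, corr_tol: float = 0.95
) -> np.ndarray:
    """Training-fold feature pruning; returns indices of kept columns.

    Drops near-zero-variance features, then walks the remaining features in
    order and greedily drops any whose absolute correlation with an
    already-kept feature exceeds ``corr_tol``.
    """
    x = np.asarray(x, float)
    var = x.var(axis=0, ddof=0)
    candidates = np.flatnonzero(var > var_tol)
    if candidates.size == 0:
        raise ValueError("all features pruned: no variance in training fold")
    z = x[:, candidates] - x[:, candidates].mean(axis=0)
    z /= np.sqrt((z**2).sum(axis=0))
    kept: list[int] = []
    for j in range(candidates.size):
        if not kept:
            kept.append(j)
            continue
        corr = np.abs(z[:, kept].T @ z[:, j])
        if corr.max() <= corr_tol:
            kept.append(j)
    return candidates[np.asarray(kept)]


def subject_folds(
    groups: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Group-aware fold assignment: subjects are shuffled and split into k
    folds, so both sessions of a subject share a fold."""
    groups = np.asarray(groups)
    subjects = np.array(sorted(set(groups.tolist())))
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects cannot fill {k} folds")
    order = rng.permutation(len(subjects))
    fold_of_subject = {}
    for fold, chunk in enumerate(np.array_split(subjects[order], k)):
        for s in chunk:
            fold_of_subject[s] = fold
    return np.array([fold_of_subject[g] for g in groups])


def _check_no_split_subjects(folds: np.ndarray, groups: np.ndarray) -> None:
    for s in set(groups.tolist()):
        if len(set(folds[groups == s].tolist())) != 1:
            raise RuntimeError(f"leakage guard: subject {s} spans multiple folds")


def crossval_rf(
    features: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    k: int = 5,
    n_trees: int = 500,
    var_tol: float = 1e-10,
    corr_tol: float = 0.95,
    seed: int | np.random.Generator | None = None,
    keep_models: bool = False,
) -> ClassifierReport:
    """Group-aware k-fold random-forest decoding with embedded preprocessing.

    ``features`` is (sessions x features), ``labels`` the condition of each
    session, ``groups`` the subject id (identical for a subject's two
    sessions). Optional per-session ``covariates`` are residualized out
    using coefficients fitted on the training fold only. Out-of-fold
    predictions are pooled into a single balanced accuracy.
    """
    x = np.asarray(features, float)
    y = np.asarray(labels)
    groups = np.asarray(groups)
    if len(set(y.tolist())) != 2:
        raise ValueError("need exactly two classes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = subject_folds(groups, k, rng)
    _check_no_split_subjects(folds, groups)
    y_pred = np.empty_like(y)
    models: list[_FoldModel] = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        if len(set(y[train].tolist())) < 2:
            raise ValueError(f"training fold {fold} contains a single class")
        x_train, x_test = x[train], x[test]
        resid = None
        if covariates is not None:
            resid = CovariateResidualizer().fit(x_train, covariates[train])
            x_train = resid.transform(x_train, covariates[train])
            x_test = resid.transform(x_test, covariates[test])
        kept = prune_features(x_train, var_tol=var_tol, corr_tol=corr_tol)
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", bootstrap=True,
            random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
        )
        forest.fit(x_train[:, kept], y[train])
        y_pred[test] = forest.predict(x_test[:, kept])
        if keep_models:
            models.append(
                _FoldModel(forest, kept, resid, np.flatnonzero(train),
                           np.flatnonzero(test), x_train[:, kept], y[train])
            )
    bac = float(balanced_accuracy_score(y, y_pred))
    return ClassifierReport(
        fold_assignments=folds, y_true=y, y_pred=y_pred, bac=bac,
        extras={"models": models} if keep_models else {},
    )


def flip_labels_within_subject(
    labels: np.ndarray, groups: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Swap both of a subject's condition labels with probability 1/2."""
    labels = np.asarray(labels).copy()
    groups = np.asarray(groups)
    a, b = LABELS
    swap = {a: b, b: a}
    for s in sorted(set(groups.tolist())):
        if rng.random() < 0.5:
            sel = groups == s
            labels[sel] = [swap.get(v, v) for v in labels[sel]]
    return labels


def permutation_test_bac(
    report_fn,
    labels: np.ndarray,
    groups: np.ndarray,
    observed_bac: float,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Permutation null for balanced accuracy under within-subject flips.

    ``report_fn(permuted_labels)`` must re-run the full embedded pipeline
    (folds, pruning, residualization, forest) and return the BAC. When all
    2^n_subjects flip patterns fit within ``n_perm`` they are enumerated
    exhaustively; p uses the add-one convention.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = np.asarray(groups)
    labels = np.asarray(labels)
    subjects = sorted(set(groups.tolist()))
    a, b = LABELS
    swap = {a: b, b: a}
    null = []
    if len(subjects) <= 30 and 2 ** len(subjects) <= n_perm:
        patterns = (
            [(code >> i) & 1 for i in range(len(subjects))]
            for code in range(2 ** len(subjects))
        )
    else:
        patterns = ((rng.random(len(subjects)) < 0.5) for _ in range(n_perm))
    for pattern in patterns:
        perm = labels.copy()
        for s, f in zip(subjects, pattern):
            if f:
                sel = groups == s
                perm[sel] = [swap.get(v, v) for v in perm[sel]]
        null.append(report_fn(perm))
    null = np.asarray(null)
    p = float((1 + np.sum(null >= observed_bac - 1e-12)) / (1 + len(null)))
    return null, p


def mcnemar_compare(
    preds_a: np.ndarray, preds_b: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """McNemar's test between two classifiers on the same sessions.

    Exact two-sided binomial test on the discordant counts when b + c < 25,
    else the continuity-corrected chi-square. Returns (statistic, p).
    """
    preds_a, preds_b, truth = map(np.asarray, (preds_a, preds_b, truth))
    if not (len(preds_a) == len(preds_b) == len(truth)):
        raise ValueError("prediction/truth vectors differ in length")
    right_a = preds_a == truth
    right_b = preds_b == truth
    b = int(np.sum(right_a & ~right_b))
    c = int(np.sum(~right_a & right_b))
    both = int(np.sum(right_a & right_b))
    neither = int(np.sum(~right_a & ~right_b))
    table = [[both, b], [c, neither]]
    res = sm_mcnemar(table, exact=(b + c < 25), correction=True)
    return float(res.statistic), float(res.pvalue)


def oob_importance(
    report: ClassifierReport,
    features: np.ndarray,
    covariates: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean decrease in accuracy on permuted out-of-bag samples per feature.

    For every tree in every fold's forest: accuracy on the tree's
    out-of-bag training sessions is compared before and after permuting one
    feature's values; the decrease is averaged across trees, then across
    folds. Returns (importance, across-fold sd); features pruned in a fold
    contribute 0 there, and a ``pruned`` flag is set on the report for
    features pruned in every fold.
    """
    models = report.extras.get("models")
    if not models:
        raise ValueError("crossval_rf must be run with keep_models=True")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_features = np.asarray(features).shape[1]
    per_fold = np.zeros((len(models), n_features))
    ever_kept = np.zeros(n_features, bool)
    for f_idx, m in enumerate(models):
        ever_kept[m.kept] = True
        x_tr, y_tr = m.x_train, m.y_train
        n = len(y_tr)
        drops = np.zeros(len(m.kept))
        counts = np.zeros(len(m.kept))
        for tree, samples in zip(m.forest.estimators_, m.forest.estimators_samples_):
            inbag = np.zeros(n, bool)
            inbag[samples] = True
            oob = ~inbag
            if not oob.any():
                continue
            x_oob, y_oob = x_tr[oob], y_tr[oob]
            classes = m.forest.classes_
            base_pred = classes[np.argmax(tree.predict_proba(x_oob), axis=1)]
            base_acc = np.mean(base_pred == y_oob)
            for j in range(len(m.kept)):
                x_perm = x_oob.copy()
                x_perm[:, j] = x_perm[rng.permutation(len(x_perm)), j]
                pred = classes[np.argmax(tree.predict_proba(x_perm), axis=1)]
                drops[j] += base_acc - np.mean(pred == y_oob)
                counts[j] += 1
        with np.errstate(invalid="ignore"):
            per_fold[f_idx, m.kept] = np.where(counts > 0, drops / np.maximum(counts, 1), 0.0)
    importance = per_fold.mean(axis=0)
    sd = per_fold.std(axis=0, ddof=1) if len(models) > 1 else np.zeros(n_features)
    report.importances = importance
    report.importances_sd = sd
    report.pruned = ~ever_kept
    return importance, sd
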