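"""Partial least squares correlation (PLSC) with permutation and bootstrap
inference, for a paired two-condition design.

Task (mean-centred) PLSC: the condition-mean feature matrix, centred on the
grand mean, is decomposed by SVD. Each singular-vector pair is a latent
variable (LV): a brain-wide salience pattern plus condition weights, ordered
by explained covariance. With two conditions the mean-centred rows are exact
negatives of each other, so there are at most two LVs and the second
singular value is identically zero.

Behavioural PLSC: the cross-block vector of feature–behaviour Pearson
correlations plays the role of the matrix; its SVD is the single LV whose
salience maximises the correlation between the latent brain score and the
behavioural score.

Inference respects the cross-over pairing throughout: LV significance comes
from permutations that flip condition labels within subject (task mode) or
permute the behavioural score across subjects (behavioural mode), with the
add-one convention p = (1 + #{null >= observed}) / (1 + n_perm); salience
stability comes from bootstrap resampling of subjects (both sessions of a
subject move together), reported as bootstrap ratios BSR = salience /
bootstrap standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CONDITIONS

#: sentinel replacing an infinite bootstrap ratio (zero bootstrap variance)
BSR_CAP = 1e6


@dataclass
class TaskPlscData:
    """Input of the mean-centred task PLSC: a (subject, condition) x feature
    table, residualized upstream."""

    features: pd.DataFrame
    conditions: tuple = CONDITIONS

    def __post_init__(self) -> None:
        idx = self.features.index
        if not isinstance(idx, pd.MultiIndex) or idx.names != ["subject_id", "condition"]:
            raise ValueError("features must be indexed by (subject_id, condition)")
        for cond in self.conditions:
            n = (idx.get_level_values("condition") == cond).sum()
            if n < 2:
                raise ValueError(f"condition {cond!r} has {n} subjects; need >= 2")
        subj = idx.get_level_values("subject_id")
        for cond in self.conditions:
            have = set(subj[idx.get_level_values("condition") == cond])
            if have != set(subj):
                raise ValueError("all conditions must cover the same subjects")

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.features.index.get_level_values("subject_id")))


@dataclass
class BehaviouralPlscData:
    """Input of the behavioural PLSC: one feature row and one behavioural
    score per subject."""

    features: pd.DataFrame
    behaviour: pd.Series

    def __post_init__(self) -> None:
        if len(self.features) != len(self.behaviour):
            raise ValueError("features and behaviour cover different subjects")
        if len(self.features) < 6:
            raise ValueError("need at least 6 subjects")
        y = self.behaviour.to_numpy(float)
        if np.std(y) == 0:
            raise ValueError("behaviour is constant")
        self.behaviour = self.behaviour.loc[self.features.index]


@dataclass
class PlscResult:
    """SVD factors plus permutation and bootstrap inference."""

    singular_values: np.ndarray
    saliences: np.ndarray
    feature_ids: list[str]
    lv_scores: pd.DataFrame
    condition_scores: pd.DataFrame | None = None
    perm_p: np.ndarray | None = None
    bootstrap_ratios: np.ndarray | None = None
    behav_correlation: float | None = None
    mode: str = "task"
    n_perm: int = 0
    n_boot: int = 0
    extras: dict = field(default_factory=dict)


def _condition_means(
    x: np.ndarray, cond_labels: np.ndarray, conditions: tuple
) -> np.ndarray:
    return np.stack([x[cond_labels == c].mean(axis=0) for c in conditions])


def _task_svd(
    x: np.ndarray, cond_labels: np.ndarray, conditions: tuple
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the grand-mean-centred condition-mean matrix.

    Returns (singular values, saliences F x k, condition weights k x k,
    grand mean); k = number of conditions.
    """
    m = _condition_means(x, cond_labels, conditions)
    grand = m.mean(axis=0)
    mc = m - grand
    u, s, vt = np.linalg.svd(mc, full_matrices=False)
    return s, vt.T, u, grand


def _fix_task_signs(
    s: np.ndarray, v: np.ndarray, u: np.ndarray, conditions: tuple
) -> tuple[np.ndarray, np.ndarray]:
    """Sign convention: the drug condition's weight is non-negative on every
    component, making outputs reproducible across linear-algebra backends."""
    drug_row = conditions.index("drug") if "drug" in conditions else 0
    flip = np.where(u[drug_row] < 0, -1.0, 1.0)
    return v * flip, u * flip


def _behav_svd(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Cross-block correlation vector and its (rank-one) SVD.

    Features and behaviour are z-scored; zero-variance features contribute a
    zero correlation. Returns (singular value, unit salience)."""
    n = len(y)
    sd = x.std(axis=0, ddof=0)
    xm = x.mean(axis=0)
    z = (x - xm) / np.where(sd == 0, 1.0, sd)
    z[:, sd == 0] = 0.0
    zy = (y - y.mean()) / y.std(ddof=0)
    r = z.T @ zy / n
    sv = float(np.linalg.norm(r))
    salience = r / sv if sv > 0 else r
    return sv, salience


def _within_subject_flips(n_subjects: int, n_perm: int, rng: np.random.Generator):
    """Yield condition-flip patterns; exhaustive when 2^n fits in n_perm."""
    if n_subjects <= 30 and 2**n_subjects <= n_perm:
        for code in range(2**n_subjects):
            yield np.array([(code >> i) & 1 for i in range(n_subjects)], bool)
    else:
        for _ in range(n_perm):
            yield rng.random(n_subjects) < 0.5


def permutation_test(
    data: TaskPlscData | BehaviouralPlscData,
    n_perm: int = 2000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Permutation p-values for each LV's singular value.

    Task mode flips condition labels within subject (the exchangeable
    transformation of a cross-over design); when all 2^n flip patterns fit
    within ``n_perm`` they are enumerated exhaustively. Behavioural mode
    permutes the behaviour vector across subjects.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse", stacklevel=2)
    rng = rng or np.random.default_rng()
    if isinstance(data, TaskPlscData):
        x = data.features.to_numpy(float)
        idx = data.features.index
        cond_labels = idx.get_level_values("condition").to_numpy()
        subj_labels = idx.get_level_values("subject_id").to_numpy()
        subjects = data.subjects
        s_obs, *_ = _task_svd(x, cond_labels, data.conditions)
        a, b = data.conditions[0], data.conditions[1]
        swap = {a: b, b: a}
        count = np.zeros_like(s_obs)
        n_done = 0
        for flips in _within_subject_flips(len(subjects), n_perm, rng):
            flip_set = {s for s, f in zip(subjects, flips) if f}
            perm_labels = np.array(
                [swap[c] if s in flip_set else c for s, c in zip(subj_labels, cond_labels)]
            )
            s_perm, *_ = _task_svd(x, perm_labels, data.conditions)
            count += s_perm >= s_obs - 1e-12
            n_done += 1
        return (1.0 + count) / (1.0 + n_done)
    x = data.features.to_numpy(float)
    y = data.behaviour.to_numpy(float)
    sv_obs, _ = _behav_svd(x, y)
    count = 0
    for _ in range(n_perm):
        sv_perm, _ = _behav_svd(x, rng.permutation(y))
        count += sv_perm >= sv_obs - 1e-12
    return np.array([(1.0 + count) / (1.0 + n_perm)])


def _procrustes_align(v_boot: np.ndarray, v_ref: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes rotation of bootstrap saliences onto the
    originals (reduces to a sign flip for one component)."""
    if v_ref.shape[1] == 1:
        sign = np.sign(float(v_boot[:, 0] @ v_ref[:, 0])) or 1.0
        return v_boot * sign
    u, _, vt = np.linalg.svd(v_boot.T @ v_ref, full_matrices=False)
    return v_boot @ (u @ vt)


def bootstrap_ratios(
    data: TaskPlscData | BehaviouralPlscData,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bootstrap ratios (salience / bootstrap SE) per feature and component.

    Subjects are the resampling unit — both sessions of a resampled subject
    enter together, preserving the pairing. Bootstrap saliences are aligned
    to the original by orthogonal Procrustes (sign flip for one component)
    before the standard error is taken; zero bootstrap variance yields the
    capped sentinel ``+-BSR_CAP`` (0 where the salience is itself 0).
    """
    rng = rng or np.random.default_rng()
    if isinstance(data, TaskPlscData):
        x = data.features.to_numpy(float)
        idx = data.features.index
        cond_labels = idx.get_level_values("condition").to_numpy()
        subj_labels = idx.get_level_values("subject_id").to_numpy()
        subjects = np.array(data.subjects)
        s, v, u, _ = _task_svd(x, cond_labels, data.conditions)
        v, u = _fix_task_signs(s, v, u, data.conditions)
        rows_of = {s_: np.flatnonzero(subj_labels == s_) for s_ in subjects}

        def one_boot(chosen) -> np.ndarray:
            rows = np.concatenate([rows_of[s_] for s_ in chosen])
            _, vb, ub, _ = _task_svd(x[rows], cond_labels[rows], data.conditions)
            return _procrustes_align(vb, v)

        original = v
    else:
        x = data.features.to_numpy(float)
        y = data.behaviour.to_numpy(float)
        subjects = np.arange(len(y))
        _, sal = _behav_svd(x, y)
        original = sal[:, None]

        def one_boot(chosen) -> np.ndarray:
            yb = y[chosen]
            if np.std(yb) == 0:
                raise _DegenerateResample
            _, sb = _behav_svd(x[chosen], yb)
            return _procrustes_align(sb[:, None], original)

    boots = []
    draws = 0
    while len(boots) < n_boot:
        draws += 1
        if draws > 20 * n_boot:  # pragma: no cover - pathological inputs only
            raise RuntimeError("too many degenerate bootstrap resamples")
        chosen = rng.choice(subjects, size=len(subjects), replace=True)
        if len(set(map(str, chosen))) < 2:
            continue  # degenerate resample: a single unique subject; redraw
        try:
            boots.append(one_boot(chosen))
        except _DegenerateResample:
            continue
    se = np.std(np.stack(boots), axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = original / se
    bsr = np.where(se == 0, np.sign(original) * BSR_CAP, bsr)
    return np.clip(bsr, -BSR_CAP, BSR_CAP)


class _DegenerateResample(Exception):
    pass


def task_plsc(
    features: pd.DataFrame,
    conditions: tuple = CONDITIONS,
    n_perm: int = 2000,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> PlscResult:
    """Mean-centred task PLSC of a (subject, condition) x feature table.

    Returns as many LVs as conditions; subject-level LV scores are the
    projections of each grand-mean-centred row onto the saliences, and
    condition scores their per-condition means. Salience signs are fixed so
    the drug condition weighs positively.
    """
    data = TaskPlscData(features, conditions)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = features.to_numpy(float)
    cond_labels = features.index.get_level_values("condition").to_numpy()
    s, v, u, grand = _task_svd(x, cond_labels, conditions)
    v, u = _fix_task_signs(s, v, u, conditions)
    scores = (x - grand) @ v
    lv_scores = pd.DataFrame(
        scores, index=features.index,
        columns=[f"LV{i + 1}" for i in range(v.shape[1])],
    )
    condition_scores = lv_scores.groupby(level="condition", sort=False).mean()
    perm_p = permutation_test(data, n_perm=n_perm, rng=rng) if n_perm else None
    bsr = bootstrap_ratios(data, n_boot=n_boot, rng=rng) if n_boot else None
    return PlscResult(
        singular_values=s, saliences=v, feature_ids=list(features.columns),
        lv_scores=lv_scores, condition_scores=condition_scores, perm_p=perm_p,
        bootstrap_ratios=bsr, mode="task", n_perm=n_perm, n_boot=n_boot,
        extras={"condition_weights": u, "conditions": list(conditions)},
    )


def select_behavioural_features(
    features: pd.DataFrame, mode: str = "drug"
) -> pd.DataFrame:
    """Per-subject feature table for the behavioural PLSC.

    ``mode='drug'`` takes the drug-condition rows; ``'difference'`` takes
    drug minus placebo — the subject's connectivity change.
    """
    drug = features.xs("drug", level="condition")
    if mode == "drug":
        return drug
    if mode == "difference":
        placebo = features.xs("placebo", level="condition")
        return drug - placebo.loc[drug.index]
    raise ValueError(f"unknown mode {mode!r}; expected 'drug' or 'difference'")


def behavioural_plsc(
    features: pd.DataFrame,
    behaviour: pd.Series,
    n_perm: int = 2000,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> PlscResult:
    """Behavioural PLSC: one LV maximally correlating brain and behaviour.

    ``features`` has one row per subject (see
    :func:`select_behavioural_features`). The salience sign is fixed so the
    latent brain score correlates positively with behaviour;
    ``behav_correlation`` reports that correlation.
    """
    behaviour = behaviour.loc[features.index]
    data = BehaviouralPlscData(features, behaviour)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = features.to_numpy(float)
    y = behaviour.to_numpy(float)
    sv, sal = _behav_svd(x, y)
    sd = x.std(axis=0, ddof=0)
    z = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    z[:, sd == 0] = 0.0
    scores = z @ sal
    r = float(np.corrcoef(scores, y)[0, 1]) if np.std(scores) > 0 else 0.0
    if r < 0:
        sal, scores, r = -sal, -scores, -r
    lv_scores = pd.DataFrame({"LV1": scores}, index=features.index)
    perm_p = permutation_test(data, n_perm=n_perm, rng=rng) if n_perm else None
    bsr = bootstrap_ratios(data, n_boot=n_boot, rng=rng) if n_boot else None
    return PlscResult(
        singular_values=np.array([sv]), saliences=sal[:, None],
        feature_ids=list(features.columns), lv_scores=lv_scores,
        perm_p=perm_p, bootstrap_ratios=bsr, behav_correlation=r,
        mode="behavioural", n_perm=n_perm, n_boot=n_boot,
    )
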