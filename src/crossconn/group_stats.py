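"""Mass-univariate group statistics for the paired (cross-over) design.

Covers: ordinary-least-squares residualization of connectivity features on
baseline physiology (heart rate, diastolic/systolic blood pressure, body
temperature); mass-univariate paired t-tests with Benjamini–Hochberg FDR
control over each feature family; and the directed-asymmetry analysis that
compares forward and backward couplings of every region pair within each
condition plus their drug-by-asymmetry interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

COVARIATE_COLUMNS = ["heart_rate", "dbp", "sbp", "temperature"]


@dataclass
class PairedTestResult:
    """Per-feature paired t-test results with BH-FDR over the family.

    ``excluded`` marks features with zero within-pair variance, which are
    dropped from the FDR family rather than assigned a pseudo p-value.
    """

    feature_ids: list[str]
    t_statistic: np.ndarray
    raw_p: np.ndarray
    fdr_q: np.ndarray
    significant: np.ndarray
    excluded: np.ndarray
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t_statistic, "p": self.raw_p, "q": self.fdr_q,
                "significant": self.significant, "excluded": self.excluded,
            },
            index=pd.Index(self.feature_ids, name="feature_id"),
        )


@dataclass
class AsymmetryResult:
    """Forward-vs-backward coupling tests per unordered region pair (i<j).

    ``t_drug``/``t_placebo`` test a_ij vs a_ji across subjects within a
    condition; ``t_interaction`` tests whether the asymmetry (a_ij - a_ji)
    differs between conditions. Swapping i and j flips every statistic's
    sign by construction.
    """

    pairs: list[tuple[str, str]]
    t_drug: np.ndarray
    p_drug: np.ndarray
    t_placebo: np.ndarray
    p_placebo: np.ndarray
    t_interaction: np.ndarray
    p_interaction: np.ndarray
    alpha: float = 0.05
    fdr: bool = False
    q_drug: np.ndarray | None = None
    q_placebo: np.ndarray | None = None
    q_interaction: np.ndarray | None = None
    counts: dict = field(default_factory=dict)


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns: {missing}")
    x = np.column_stack(
        [np.ones(len(covariates))] + [covariates[c].to_numpy(float) for c in COVARIATE_COLUMNS]
    )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify which covariates are linearly dependent on the others
        bad = []
        for j in range(1, x.shape[1]):
            others = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(COVARIATE_COLUMNS[j - 1])
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    return x


def residualize(features: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Residuals of each feature after OLS on [1, hr, dbp, sbp, temperature].

    Rows of ``features`` may be indexed by subject or (subject, condition);
    covariates are matched by subject, so both of a subject's sessions share
    that subject's baseline physiology. Residuals are mean-zero per feature.
    """
    subjects = (
        features.index.get_level_values("subject_id")
        if isinstance(features.index, pd.MultiIndex)
        else features.index
    )
    if not set(subjects) <= set(covariates.index):
        missing = sorted(set(subjects) - set(covariates.index))
        raise ValueError(f"covariates missing for subjects: {missing}")
    if covariates.shape[0] < 6:
        raise ValueError("need at least 6 subjects for residualization")
    cov = covariates.loc[subjects]
    x = _covariate_design(cov)
    y = features.to_numpy(float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return pd.DataFrame(resid, index=features.index, columns=features.columns)


class CovariateResidualizer:
    """Fit the covariate regression on one sample, apply it to another.

    Used inside cross-validation: coefficients are estimated on training
    sessions only and then applied to held-out sessions, so no information
    leaks from the test fold into preprocessing.
    """

    def __init__(self) -> None:
        self.beta_: np.ndarray | None = None

    def fit(self, features: np.ndarray, covariates: np.ndarray) -> "CovariateResidualizer":
        x = np.column_stack([np.ones(len(covariates)), covariates])
        self.beta_, *_ = np.linalg.lstsq(x, np.asarray(features, float), rcond=None)
        return self

    def transform(self, features: np.ndarray, covariates: np.ndarray) -> np.ndarray:
        if self.beta_ is None:
            raise RuntimeError("fit before transform")
        x = np.column_stack([np.ones(len(covariates)), covariates])
        return np.asarray(features, float) - x @ self.beta_


def bh_significant(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (reject flags, adjusted q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, q


def paired_tests_fdr(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    alpha: float = 0.05,
) -> PairedTestResult:
    """Paired t-test per feature (a minus b) with BH-FDR over the family.

    Both tables must carry the same subjects in the same order; a feature
    family is whatever set of columns is passed (FC edges, all EC
    couplings, or the self-connection family — analysed separately).
    """
    if features_a.shape != features_b.shape:
        raise ValueError("feature tables have different shapes")
    if list(features_a.columns) != list(features_b.columns):
        raise ValueError("feature tables have different columns")
    n = features_a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a paired t-test")
    diff = features_a.to_numpy(float) - features_b.to_numpy(float)
    excluded = diff.std(axis=0, ddof=1) == 0
    t = np.zeros(diff.shape[1])
    p = np.ones(diff.shape[1])
    if (~excluded).any():
        res = sps.ttest_rel(
            features_a.to_numpy(float)[:, ~excluded],
            features_b.to_numpy(float)[:, ~excluded],
        )
        t[~excluded] = res.statistic
        p[~excluded] = res.pvalue
    q = np.full(diff.shape[1], np.nan)
    significant = np.zeros(diff.shape[1], bool)
    if (~excluded).any():
        rej, qv = bh_significant(p[~excluded], alpha=alpha)
        q[~excluded] = qv
        significant[~excluded] = rej
    return PairedTestResult(
        feature_ids=list(features_a.columns), t_statistic=t, raw_p=p,
        fdr_q=q, significant=significant, excluded=excluded, alpha=alpha,
    )


def _stack_condition(connectomes_by_subject: dict[str, np.ndarray]) -> np.ndarray:
    return np.stack([connectomes_by_subject[s] for s in sorted(connectomes_by_subject)])


def asymmetry_tests(
    ec_drug: dict[str, np.ndarray],
    ec_placebo: dict[str, np.ndarray],
    region_labels: list[str],
    alpha: float = 0.05,
    fdr: bool = False,
) -> AsymmetryResult:
    """Directed-asymmetry tests over all C(R,2) unordered region pairs.

    For each pair i<j: paired t across subjects of a_ij vs a_ji within each
    condition, and the interaction test of the asymmetry difference between
    conditions. ``fdr=False`` (default) reports uncorrected p<alpha counts;
    ``fdr=True`` applies BH within each of the three families.
    """
    if set(ec_drug) != set(ec_placebo):
        raise ValueError("both conditions must cover the same subjects")
    a_d = _stack_condition(ec_drug)
    a_p = _stack_condition(ec_placebo)
    R = a_d.shape[1]
    iu, ju = np.triu_indices(R, k=1)
    pairs = [(region_labels[i], region_labels[j]) for i, j in zip(iu, ju)]
    fwd_d, bwd_d = a_d[:, iu, ju], a_d[:, ju, iu]
    fwd_p, bwd_p = a_p[:, iu, ju], a_p[:, ju, iu]

    def _paired(x, y):
        res = sps.ttest_rel(x, y, axis=0)
        t = np.asarray(res.statistic)
        p = np.asarray(res.pvalue)
        zero = (x - y).std(axis=0, ddof=1) == 0
        t[zero], p[zero] = 0.0, 1.0
        return t, p

    t_d, p_d = _paired(fwd_d, bwd_d)
    t_p, p_p = _paired(fwd_p, bwd_p)
    t_i, p_i = _paired(fwd_d - bwd_d, fwd_p - bwd_p)

    result = AsymmetryResult(
        pairs=pairs, t_drug=t_d, p_drug=p_d, t_placebo=t_p, p_placebo=p_p,
        t_interaction=t_i, p_interaction=p_i, alpha=alpha, fdr=fdr,
    )
    if fdr:
        rej_d, result.q_drug = bh_significant(p_d, alpha)
        rej_p, result.q_placebo = bh_significant(p_p, alpha)
        rej_i, result.q_interaction = bh_significant(p_i, alpha)
        sig_d, sig_p, sig_i = rej_d, rej_p, rej_i
    else:
        sig_d, sig_p, sig_i = p_d < alpha, p_p < alpha, p_i < alpha
    result.counts = {
        "n_pairs": len(pairs),
        "drug": int(sig_d.sum()),
        "placebo": int(sig_p.sum()),
        "interaction": int(sig_i.sum()),
    }
    return result
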