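"""Functional connectivity and the canonical feature-vector conventions.

Functional connectivity (FC) is the Pearson correlation between every pair
of region time series: for R regions this yields R(R-1)/2 unique
coefficients (8,646 for a 132-region parcellation). Effective-connectivity
matrices flatten to R(R-1) ordered off-diagonal couplings plus R
self-connections (17,424 coefficients in total at R=132). The orderings
defined here are the single canonical ones used by every downstream
statistic and classifier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import EffectiveConnectome, FcMatrix, FeatureVector, RoiTimeSeries

KINDS = ("fc", "ec_offdiag", "ec_self")


def pearson_fc(ts: RoiTimeSeries) -> FcMatrix:
    """Pearson product-moment correlation between all region pairs.

    Raises if any region has zero variance (its correlation is undefined),
    naming the offending region.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    sd = ts.data.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd <= 0)
    if dead.size:
        names = ", ".join(ts.region_labels[i] for i in dead)
        raise ValueError(f"zero-variance region(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FcMatrix(r=r, region_labels=list(ts.region_labels),
                    subject_id=ts.subject_id, condition=ts.condition)


def fisher_z(fc: FcMatrix) -> np.ndarray:
    """Fisher z-transform of the off-diagonal correlations (diagonal zeroed)."""
    r = fc.r.copy()
    np.fill_diagonal(r, 0.0)
    return np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))


def feature_ids(region_labels: list[str], kind: str) -> list[tuple[str, str, str]]:
    """Canonical feature identifiers for a vectorization kind.

    fc: unordered pairs (i<j), row-major. ec_offdiag: ordered (source,
    target) pairs for every matrix entry (i, j), i != j, row-major over the
    matrix — note entry (i, j) is the influence of j (source) on i (target).
    ec_self: one id per region.
    """
    R = len(region_labels)
    if kind == "fc":
        return [
            (region_labels[i], region_labels[j], "fc")
            for i in range(R) for j in range(i + 1, R)
        ]
    if kind == "ec_offdiag":
        return [
            (region_labels[j], region_labels[i], "ec_offdiag")
            for i in range(R) for j in range(R) if i != j
        ]
    if kind == "ec_self":
        return [(lbl, lbl, "ec_self") for lbl in region_labels]
    raise ValueError(f"unknown kind {kind!r}; expected one of {KINDS}")


def vectorize(
    matrix: np.ndarray | FcMatrix | EffectiveConnectome,
    kind: str,
    region_labels: list[str] | None = None,
    subject_id: str = "sub-00",
    condition: str = "placebo",
) -> FeatureVector:
    """Flatten a connectivity matrix into the canonical feature order.

    fc extracts the upper triangle (R(R-1)/2 values), ec_offdiag every
    ordered pair (R(R-1)), ec_self the diagonal (R).
    """
    if isinstance(matrix, FcMatrix):
        region_labels = matrix.region_labels
        subject_id, condition = matrix.subject_id, matrix.condition
        m = matrix.r
    elif isinstance(matrix, EffectiveConnectome):
        region_labels = matrix.region_labels
        subject_id, condition = matrix.subject_id, matrix.condition
        m = matrix.a
    else:
        m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    R = m.shape[0]
    if region_labels is None:
        region_labels = [f"r{i}" for i in range(R)]
    if len(region_labels) != R:
        raise ValueError("label count does not match matrix size")
    if kind == "fc":
        iu = np.triu_indices(R, k=1)
        values = m[iu]
    elif kind == "ec_offdiag":
        values = m[~np.eye(R, dtype=bool)]
    elif kind == "ec_self":
        values = np.diag(m).copy()
    else:
        raise ValueError(f"unknown kind {kind!r}; expected one of {KINDS}")
    return FeatureVector(values=values, feature_ids=feature_ids(region_labels, kind),
                         subject_id=subject_id, condition=condition)


def matrix_from_features(fv: FeatureVector, region_labels: list[str]) -> np.ndarray:
    """Inverse of :func:`vectorize` for ``fc`` vectors (unit diagonal restored)."""
    R = len(region_labels)
    if len(fv) != R * (R - 1) // 2:
        raise ValueError("feature count does not match an fc vectorization")
    m = np.eye(R)
    iu = np.triu_indices(R, k=1)
    m[iu] = fv.values
    m[(iu[1], iu[0])] = fv.values
    return m


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack per-session feature vectors into a (subject, condition) x feature
    DataFrame with canonical column names ``source->target:kind``."""
    if not vectors:
        raise ValueError("no feature vectors given")
    ids = vectors[0].feature_ids
    for fv in vectors:
        if fv.feature_ids != ids:
            raise ValueError("feature vectors have inconsistent feature_ids")
    cols = [f"{s}->{t}:{k}" for s, t, k in ids]
    index = pd.MultiIndex.from_tuples(
        [(fv.subject_id, fv.condition) for fv in vectors],
        names=["subject_id", "condition"],
    )
    return pd.DataFrame([fv.values for fv in vectors], index=index, columns=cols)


def fc_feature_table(sessions: list[RoiTimeSeries]) -> pd.DataFrame:
    """Pearson-FC feature table for a list of sessions."""
    return feature_table([vectorize(pearson_fc(ts), "fc") for ts in sessions])


def ec_feature_table(
    connectomes: list[EffectiveConnectome], kind: str = "ec_full"
) -> pd.DataFrame:
    """Effective-connectivity feature table.

    ``kind='ec_full'`` concatenates off-diagonal and self features (the
    R*R-coefficient family used for classification and whole-matrix PLSC);
    ``'ec_offdiag'`` and ``'ec_self'`` select a single family.
    """
    if kind == "ec_full":
        parts = []
        for ec in connectomes:
            off = vectorize(ec, "ec_offdiag")
            self_ = vectorize(ec, "ec_self")
            parts.append(
                FeatureVector(
                    values=np.concatenate([off.values, self_.values]),
                    feature_ids=off.feature_ids + self_.feature_ids,
                    subject_id=ec.subject_id, condition=ec.condition,
                )
            )
        return feature_table(parts)
    return feature_table([vectorize(ec, kind) for ec in connectomes])
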