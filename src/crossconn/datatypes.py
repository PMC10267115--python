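"""Shared containers for region-wise BOLD data and connectivity estimates.

The central object is :class:`RoiTimeSeries`: one resting-state session's
T x R matrix of region-averaged BOLD signals together with its sampling
metadata (repetition time, region labels, subject and condition). Everything
downstream — functional connectivity, regression-DCM effective connectivity,
group statistics — consumes and produces these containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

CONDITIONS = ("placebo", "drug")


@dataclass
class RoiTimeSeries:
    """One session's region-wise BOLD time series.

    Parameters
    ----------
    data:
        Array of shape (T, R): T timepoints by R regions, arbitrary units.
    tr:
        Repetition time (sampling interval) in seconds.
    region_labels:
        R region names; defines the column order used everywhere downstream.
    subject_id, condition:
        Session identity. ``condition`` is one of ``{"placebo", "drug"}``.
    """

    data: np.ndarray
    tr: float
    region_labels: list[str]
    subject_id: str = "sub-00"
    condition: str = "placebo"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (T x R), got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains missing or non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")
        if len(self.region_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {self.data.shape[1]} regions"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.n_timepoints <= self.n_regions:
            warnings.warn(
                f"T={self.n_timepoints} <= R={self.n_regions}; estimates will be "
                "poorly conditioned",
                stacklevel=2,
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class FcMatrix:
    """Symmetric Pearson functional-connectivity matrix with unit diagonal."""

    r: np.ndarray
    region_labels: list[str]
    subject_id: str = "sub-00"
    condition: str = "placebo"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        R = self.r.shape[0]
        if self.r.shape != (R, R):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass
class FeatureVector:
    """Flattened connectivity features in the package-wide canonical order.

    ``kind`` is one of ``fc`` (upper triangle, R(R-1)/2 entries), ``ec_offdiag``
    (all ordered pairs, R(R-1) entries) or ``ec_self`` (diagonal, R entries).
    ``feature_ids`` are (source_label, target_label, kind) triples.
    """

    values: np.ndarray
    feature_ids: list[tuple[str, str, str]]
    subject_id: str = "sub-00"
    condition: str = "placebo"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.feature_ids):
            raise ValueError("values and feature_ids must have matching length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RegionPosterior:
    """Variational posterior for one target region's incoming couplings.

    ``mean`` holds the posterior coupling strengths (Hz) of every source
    region into the target (self-connection included); ``tau_*_post`` the
    Gamma posterior over the regression's residual precision.
    """

    mean: np.ndarray
    covariance: np.ndarray
    tau_shape_post: float
    tau_rate_post: float
    free_energy: float
    n_iterations: int
    converged: bool
    free_energy_history: list[float] = field(default_factory=list)


@dataclass
class EffectiveConnectome:
    """R x R endogenous coupling matrix A (Hz) from regression DCM.

    Entry ``a[i, j]`` is the influence of region j on region i; the diagonal
    holds the (negative) self-connections interpreted as decay rates.
    """

    a: np.ndarray
    region_labels: list[str]
    per_region: list[RegionPosterior] = field(default_factory=list)
    subject_id: str = "sub-00"
    condition: str = "placebo"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        R = len(self.region_labels)
        if self.a.shape != (R, R):
            raise ValueError(f"A must be {R}x{R}, got {self.a.shape}")

    @property
    def n_regions(self) -> int:
        return self.a.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.a.size
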