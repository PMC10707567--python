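"""Functional-connectivity feature extraction from ROI time series.

An *atlas* (parcellation) divides the brain into ``n`` regions of interest
(ROIs).  For each subject the per-ROI BOLD time series (T time points x n
ROIs) is summarised by its n x n Pearson correlation matrix — the functional
connectivity (FC) matrix.  Because the matrix is symmetric with a unit
diagonal, only the strict lower triangle carries information; it is flattened
into a feature vector of length ``S = n(n-1)/2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AtlasSpec",
    "ROITimeSeries",
    "FCMatrix",
    "FeatureVector",
    "NAMED_ATLASES",
    "feature_count",
    "pearson_correlation",
    "connectivity_matrix",
    "vectorize_lower_triangle",
    "lower_triangle_indices",
    "build_view_features",
]


class DegenerateSignalWarning(UserWarning):
    """A zero-variance (constant) signal was encountered; correlation set to 0."""


def feature_count(n_rois: int) -> int:
    """Number of distinct ROI pairs, ``S = n(n-1)/2``, in exact integer arithmetic.

    Raises ``ValueError`` for atlases with fewer than two ROIs.
    """
    n = int(n_rois)
    if n < 2:
        raise ValueError(f"invalid atlas: n_rois must be >= 2, got {n_rois}")
    return n * (n - 1) // 2


@dataclass(frozen=True)
class AtlasSpec:
    """A named parcellation with ``n_rois`` regions and ``feature_dim = n(n-1)/2``."""

    name: str
    n_rois: int
    feature_dim: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_dim", feature_count(self.n_rois))


#: Parcellations used throughout the multi-atlas literature.  ``feature_dim``
#: is always derived from the ROI count; see docs/methods.md for the two
#: atlases whose commonly quoted feature counts disagree with n(n-1)/2.
NAMED_ATLASES: dict[str, AtlasSpec] = {
    "AAL": AtlasSpec("AAL", 116),
    "CC200": AtlasSpec("CC200", 200),
    "HO": AtlasSpec("HO", 111),
    "Dosenbach160": AtlasSpec("Dosenbach160", 160),
    "EZ": AtlasSpec("EZ", 116),
}


@dataclass
class ROITimeSeries:
    """Per-subject T x n matrix of ROI signals under a given atlas."""

    subject_id: str
    atlas: AtlasSpec
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"{self.subject_id}: time series must be 2-D")
        t, n = self.data.shape
        if n != self.atlas.n_rois:
            raise ValueError(
                f"{self.subject_id}: expected {self.atlas.n_rois} ROI columns "
                f"for atlas {self.atlas.name}, got {n}"
            )
        if t < 2:
            raise ValueError(f"{self.subject_id}: need at least 2 time points, got {t}")
        if not np.isfinite(self.data).all():
            raise ValueError(f"{self.subject_id}: time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass
class FCMatrix:
    """Symmetric n x n functional-connectivity (correlation) matrix."""

    atlas: AtlasSpec
    values: np.ndarray


@dataclass
class FeatureVector:
    """Strict-lower-triangle vectorisation of an FC matrix (length S)."""

    subject_id: str
    atlas: AtlasSpec
    values: np.ndarray


def pearson_correlation(u, v) -> float:
    """Pearson correlation of two equally long sequences.

    Zero-variance input yields 0 with a :class:`DegenerateSignalWarning`
    rather than NaN, so degenerate ROIs cannot poison downstream stages.
    """
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if u.size < 2:
        raise ValueError("need at least 2 observations")
    uc = u - u.mean()
    vc = v - v.mean()
    denom = np.sqrt((uc @ uc) * (vc @ vc))
    if denom == 0.0:
        warnings.warn(
            "zero-variance signal; correlation defined as 0",
            DegenerateSignalWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.clip((uc @ vc) / denom, -1.0, 1.0))


def connectivity_matrix(ts: ROITimeSeries) -> FCMatrix:
    """All pairwise ROI correlations of one subject.

    Entries involving a constant (zero-variance) ROI are set to 0 and a
    warning naming the offending ROI indices is emitted.
    """
    x = ts.data
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc * xc).sum(axis=0))
    degenerate = np.flatnonzero(norms == 0.0)
    if degenerate.size:
        warnings.warn(
            f"{ts.subject_id}: constant ROI column(s) {degenerate.tolist()}; "
            "affected correlations set to 0",
            DegenerateSignalWarning,
            stacklevel=2,
        )
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0.0, (xc.T @ xc) / np.where(denom > 0.0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    good = norms > 0.0
    r[np.diag_indices_from(r)] = np.where(good, 1.0, 0.0)
    r = (r + r.T) / 2.0  # enforce exact symmetry against rounding
    return FCMatrix(atlas=ts.atlas, values=r)


def lower_triangle_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major strict-lower-triangle index pairs: (1,0),(2,0),(2,1),(3,0),..."""
    return np.tril_indices(n, k=-1)


def vectorize_lower_triangle(m: FCMatrix | np.ndarray, atlas: AtlasSpec | None = None,
                             subject_id: str = "") -> FeatureVector:
    """Flatten the strict lower triangle of a symmetric matrix, row-major.

    The diagonal and upper triangle never appear; the output length equals
    ``feature_count(n)``.
    """
    if isinstance(m, FCMatrix):
        values, atlas = m.values, m.atlas
    else:
        values = np.asarray(m, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {values.shape}")
    n = values.shape[0]
    if atlas is None:
        atlas = AtlasSpec(f"adhoc{n}", n)
    i, j = lower_triangle_indices(n)
    return FeatureVector(subject_id=subject_id, atlas=atlas, values=values[i, j].copy())


def build_view_features(cohort: list[ROITimeSeries], atlas: AtlasSpec) -> pd.DataFrame:
    """FC feature table for one view: one row per subject, S columns.

    Row *i* is ``vectorize_lower_triangle(connectivity_matrix(cohort[i]))``.
    Columns are labelled ``f0..f{S-1}`` in row-major lower-triangle order;
    the index holds subject ids.
    """
    for ts in cohort:
        if ts.atlas.name != atlas.name or ts.atlas.n_rois != atlas.n_rois:
            raise ValueError(
                f"mixed atlases: subject {ts.subject_id} uses {ts.atlas.name} "
                f"({ts.atlas.n_rois} ROIs), expected {atlas.name} ({atlas.n_rois})"
            )
    columns = [f"f{k}" for k in range(atlas.feature_dim)]
    rows = np.empty((len(cohort), atlas.feature_dim), dtype=np.float64)
    ids = []
    for k, ts in enumerate(cohort):
        rows[k] = vectorize_lower_triangle(connectivity_matrix(ts)).values
        ids.append(ts.subject_id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"), columns=columns)
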