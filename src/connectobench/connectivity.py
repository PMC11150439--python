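"""Dense association matrices between node time series.

Two estimators of pairwise statistical dependence are supported, matching
the two edge definitions commonly used for functional connectomes:

* Pearson product-moment correlation.
* Mutual information I(X;Y) = H(X) + H(Y) - H(X,Y), estimated with an
  equal-width histogram plug-in estimator (natural log, so raw values are
  in nats), then rescaled by the off-diagonal matrix maximum so entries lie
  in [0, 1].

MI is symmetric and non-negative, and maps both strong positive and strong
negative correlations to high values.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .cohort import TimeSeriesSession

__all__ = [
    "ConnectivityMatrix",
    "pearson_matrix",
    "mutual_information_matrix",
    "default_mi_bins",
]


@dataclasses.dataclass
class ConnectivityMatrix:
    """Symmetric N x N association matrix with zero diagonal."""

    weights: np.ndarray
    measure: str
    n_timepoints: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be exactly zero")
        if self.measure not in ("pearson", "mutual_information"):
            raise ValueError(f"unknown measure {self.measure!r}")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _check_columns(data: np.ndarray) -> None:
    dead = np.flatnonzero(data.var(axis=0) == 0)
    if dead.size:
        raise ValueError(f"constant column(s) {dead.tolist()}: correlation undefined")


def pearson_matrix(session: TimeSeriesSession) -> ConnectivityMatrix:
    """Pearson correlation between every pair of node time courses over the
    full session length; diagonal zeroed."""
    data = session.data
    _check_columns(data)
    corr = np.corrcoef(data, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return ConnectivityMatrix(corr, "pearson", session.n_timepoints)


def default_mi_bins(n_timepoints: int) -> int:
    """Default histogram bin count: ceil(sqrt(T/5)), bounded to [8, 32]."""
    return int(np.clip(math.ceil(math.sqrt(n_timepoints / 5)), 8, 32))


def _entropy_from_counts(counts: np.ndarray, total: int) -> float:
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def mutual_information_matrix(
    session: TimeSeriesSession, n_bins: int | None = None, normalise: bool = True
) -> ConnectivityMatrix:
    """Histogram plug-in mutual information for every node pair.

    Each series is discretised into ``n_bins`` equal-width bins over its own
    range (so the estimate is invariant to affine rescaling of any series).
    Raw MI is in nats; the matrix is then divided by its maximum value,
    rescaling entries to [0, 1].  The maximum is taken over the full MI
    matrix including its diagonal of self-informations I(X;X) = H(X), so a
    pair's normalised weight reaches 1 only if its MI matches the largest
    binned marginal entropy; weakly dependent data can therefore fall
    entirely below an absolute threshold, leaving an empty network.
    """
    data = session.data
    t, n = data.shape
    if n_bins is None:
        n_bins = default_mi_bins(t)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if t < n_bins:
        raise ValueError("need at least n_bins timepoints")
    _check_columns(data)

    lo = data.min(axis=0)
    span = np.ptp(data, axis=0)
    digitised = np.floor((data - lo) / span * n_bins).astype(np.intp)
    np.clip(digitised, 0, n_bins - 1, out=digitised)

    marginal_h = np.empty(n)
    for i in range(n):
        marginal_h[i] = _entropy_from_counts(
            np.bincount(digitised[:, i], minlength=n_bins), t
        )

    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = np.bincount(
                digitised[:, i] * n_bins + digitised[:, j], minlength=n_bins * n_bins
            )
            h_joint = _entropy_from_counts(joint, t)
            # plug-in MI is mathematically >= 0; clip numerical residue
            mi[i, j] = mi[j, i] = max(0.0, marginal_h[i] + marginal_h[j] - h_joint)

    if normalise:
        peak = max(mi.max(), marginal_h.max())
        if peak > 0:
            mi /= peak
    return ConnectivityMatrix(mi, "mutual_information", t)
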