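"""Zero-referenced statistics for log-ratio expression profiles.

Compendium entries are log2 expression ratios, so 0 ("no change") is the
natural reference state of every profile.  All similarity and variability
statistics are therefore *uncentered*: no sample mean is subtracted.

The uncentered Pearson correlation of two profiles x and y over their
jointly observed contrasts c is

    r(x, y) = sum_c x_c y_c / sqrt(sum_c x_c^2 * sum_c y_c^2)

and the uncentered standard deviation of a profile is the root mean square
of its observed log ratios, ``sqrt(mean_c x_c^2)``.

Missing values are pairwise-deleted: a correlation uses only the contrasts
where both profiles are observed, and it is refused (rather than silently
returned) when the overlap is below ``StatParams.min_overlap`` or when a
restricted profile has numerically zero norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .errors import (
    DegenerateProfileError,
    EmptyProfileError,
    InsufficientOverlapError,
    ParameterError,
)

__all__ = [
    "StatParams",
    "DEFAULT_PARAMS",
    "uncentered_correlation",
    "uncentered_std",
    "correlations_to_reference",
    "pairwise_uncentered_distances",
]


@dataclass(frozen=True)
class StatParams:
    """Numerical guards shared by all profile statistics.

    Parameters
    ----------
    min_overlap:
        Minimum number of jointly observed contrasts for a correlation to
        be considered informative.  Must be at least 2; the package default
        is 3 because a correlation over fewer shared contrasts carries
        essentially no evidence.
    epsilon:
        Tolerance below which a profile norm is treated as zero.
    """

    min_overlap: int = 3
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.min_overlap < 2:
            raise ParameterError("min_overlap must be >= 2")
        if not self.epsilon > 0:
            raise ParameterError("epsilon must be positive")


DEFAULT_PARAMS = StatParams()


def _as_profile(x) -> np.ndarray:
    if isinstance(x, pd.Series):
        x = x.to_numpy()
    arr = np.asarray(x, dtype=float).ravel()
    return arr


def uncentered_correlation(x, y, params: StatParams = DEFAULT_PARAMS) -> float:
    """Uncentered Pearson correlation of two aligned log-ratio profiles.

    ``x`` and ``y`` must be indexed by the same contrast set (same length,
    positionally aligned).  NaN encodes a missing value; only jointly
    observed positions enter the sums.

    Raises
    ------
    InsufficientOverlapError
        If fewer than ``params.min_overlap`` contrasts are jointly observed.
    DegenerateProfileError
        If either restricted profile has zero norm within ``params.epsilon``.
    """
    xa, ya = _as_profile(x), _as_profile(y)
    if xa.shape != ya.shape:
        raise ParameterError(
            f"profiles must be aligned: lengths {xa.size} != {ya.size}"
        )
    joint = np.isfinite(xa) & np.isfinite(ya)
    n = int(joint.sum())
    if n < params.min_overlap:
        raise InsufficientOverlapError(
            f"only {n} jointly observed contrasts (min_overlap={params.min_overlap})"
        )
    xs, ys = xa[joint], ya[joint]
    nx = float(np.sqrt(np.dot(xs, xs)))
    ny = float(np.sqrt(np.dot(ys, ys)))
    if nx <= params.epsilon or ny <= params.epsilon:
        raise DegenerateProfileError("zero-norm profile on the shared contrasts")
    r = float(np.dot(xs, ys) / (nx * ny))
    return float(np.clip(r, -1.0, 1.0))


def uncentered_std(x) -> float:
    """Root mean square of the observed log ratios of a profile.

    Raises
    ------
    EmptyProfileError
        If the profile has no observed value.
    """
    xa = _as_profile(x)
    obs = np.isfinite(xa)
    if not obs.any():
        raise EmptyProfileError("profile has no observed values")
    xs = xa[obs]
    return float(np.sqrt(np.mean(xs * xs)))


def correlations_to_reference(
    profiles: pd.DataFrame,
    reference: pd.Series,
    params: StatParams = DEFAULT_PARAMS,
) -> pd.Series:
    """Uncentered correlation of every row of ``profiles`` with ``reference``.

    Vectorized batch form of :func:`uncentered_correlation` used for
    cleaning and extension scans.  Rows whose correlation is undefined
    (insufficient overlap or a degenerate restricted profile) get NaN
    instead of raising, so callers can report or exclude them.

    ``profiles`` columns are aligned to ``reference``'s index.
    """
    cols = reference.index
    X = profiles.reindex(columns=cols).to_numpy(dtype=float)
    r = reference.to_numpy(dtype=float)

    obs = np.isfinite(X) & np.isfinite(r)[None, :]
    X0 = np.where(obs, X, 0.0)
    R0 = np.where(obs, r[None, :], 0.0)

    num = (X0 * R0).sum(axis=1)
    nx = np.sqrt((X0 * X0).sum(axis=1))
    nr = np.sqrt((R0 * R0).sum(axis=1))
    n_joint = obs.sum(axis=1)

    ok = (n_joint >= params.min_overlap) & (nx > params.epsilon) & (nr > params.epsilon)
    out = np.full(X.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[ok] = np.clip(num[ok] / (nx[ok] * nr[ok]), -1.0, 1.0)
    return pd.Series(out, index=profiles.index, name="correlation")


def pairwise_uncentered_distances(
    profiles: pd.DataFrame, params: StatParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Condensed distance matrix ``1 - r`` between the rows of ``profiles``.

    Pairs whose correlation is undefined after pairwise deletion (too few
    shared observations, or a zero-norm restriction) are assigned the
    maximal distance 2.0, i.e. treated as maximally dissimilar; callers
    that need a stricter policy should pre-filter rows.

    Returns the condensed (upper-triangular) form expected by
    :func:`scipy.cluster.hierarchy.linkage`.
    """
    X = profiles.to_numpy(dtype=float)
    B = np.isfinite(X)
    X0 = np.where(B, X, 0.0)

    num = X0 @ X0.T
    # sum of x_i^2 over contrasts where row j is also observed
    S2 = (X0 * X0) @ B.T
    nobs = B.astype(np.int64) @ B.T.astype(np.int64)

    denom = np.sqrt(S2 * S2.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / denom
    ok = (nobs >= params.min_overlap) & (denom > params.epsilon**2)
    corr = np.where(ok, np.clip(corr, -1.0, 1.0), -1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    # enforce exact symmetry against floating round-off
    dist = (dist + dist.T) / 2.0
    return squareform(dist, checks=False)
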