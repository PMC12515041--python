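"""Robust centered log-ratio transform and the repeated-observations
(within-subject) correlation between features.

The rCLR of a sample is the log of each nonzero value against the geometric
mean of that sample's nonzero values; zeros are carried forward as missing
(NaN), never imputed.  Correlations between features are then computed with
within-subject centering (Bland & Altman's method for repeated observations),
appropriate because every mouse contributes more than one sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables_io import validate_feature_table

log = logging.getLogger(__name__)


def rclr(table: pd.DataFrame) -> pd.DataFrame:
    """Robust CLR: ``ln(value / gmean(nonzero values of the sample))``.

    Returns a samples x features frame with NaN where the input was zero.
    Raises on all-zero samples.
    """
    validate_feature_table(table)
    values = table.to_numpy(dtype=float)
    if (values.sum(axis=1) == 0).any():
        bad = table.index[values.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    logs = np.full(values.shape, np.nan)
    np.log(values, out=logs, where=values > 0)
    # per-sample mean over the nonzero entries = log geometric mean
    gmean_log = np.nanmean(logs, axis=1, keepdims=True)
    return pd.DataFrame(logs - gmean_log, index=table.index, columns=table.columns)


def rm_correlation(x, y, subject) -> float:
    """Correlation for repeated observations, centering within subjects.

    r = sum_ij (x_ij - xbar_i)(y_ij - ybar_i) /
        sqrt(sum_ij (x_ij - xbar_i)^2 * sum_ij (y_ij - ybar_i)^2)

    where i indexes subjects and j their observations.  Observations where
    either value is missing are dropped before centering (pairwise-complete).
    Returns NaN when a within-subject variance is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subject = np.asarray(subject)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y, subject = x[ok], y[ok], subject[ok]
    if x.size < 3 and len(set(subject.tolist())) < 2:
        return float("nan")
    sxy = sxx = syy = 0.0
    for s in pd.unique(subject):
        m = subject == s
        dx = x[m] - x[m].mean()
        dy = y[m] - y[m].mean()
        sxy += float(dx @ dy)
        sxx += float(dx @ dx)
        syy += float(dy @ dy)
    if sxx <= 0 or syy <= 0:
        return float("nan")
    return sxy / np.sqrt(sxx * syy)


def correlation_matrix(m: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """All-pairs repeated-observations correlation of an rCLR matrix.

    ``meta`` must carry a ``subject-id`` for every sample of ``m``.  Undefined
    entries (zero within-subject variance or too few complete pairs) are set
    to 0 — a neutral distance of 1 after conversion — and counted in the log.

    Implementation note: each entry equals :func:`rm_correlation` on the
    pairwise-complete observations of the two features, but all pairs are
    computed at once from subject-wise cross-product matrices.  For features
    j, k with joint validity mask V within subject s,

        sxy = sum_r x_r y_r - sum_s (sum_{V_s} x)(sum_{V_s} y) / |V_s|

    and likewise for sxx, syy — the centered sums expanded so that only
    masked matrix products over samples are needed.
    """
    absent = m.index.difference(meta.index)
    if len(absent):
        raise ValueError(f"samples without metadata: {absent.tolist()}")
    subjects = meta.loc[m.index, "subject-id"].to_numpy()
    X = m.to_numpy(dtype=float)
    p = X.shape[1]
    valid = ~np.isnan(X)
    Xz = np.where(valid, X, 0.0)
    Q = Xz * Xz
    V = valid.astype(float)

    sxy = Xz.T @ Xz          # products vanish unless both entries are valid
    sxx = Q.T @ V            # sum of x_j^2 over rows where k is also valid
    for s in pd.unique(subjects):
        rows = np.flatnonzero(subjects == s)
        Vs = V[rows]
        A = Xz[rows].T @ Vs              # A[j,k] = sum of x_j over joint mask
        M = Vs.T @ Vs                    # joint observation counts
        with np.errstate(invalid="ignore", divide="ignore"):
            inv = np.where(M > 0, 1.0 / np.maximum(M, 1), 0.0)
        sxy -= A * A.T * inv
        sxx -= A * A * inv
    syy = sxx.T

    tol = 1e-12
    defined = (sxx > tol) & (syy > tol)
    denom = np.sqrt(np.where(defined, sxx * syy, 1.0))
    r = np.zeros((p, p))
    np.divide(sxy, denom, out=r, where=defined)
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0                  # enforce exact symmetry
    np.fill_diagonal(r, 1.0)
    n_undefined = int((~defined[np.triu_indices(p, 1)]).sum())
    if n_undefined:
        log.info("correlation_matrix: %d undefined pair(s) set to 0", n_undefined)
    return pd.DataFrame(r, index=m.columns, columns=m.columns)


def corr_to_distance(c: pd.DataFrame) -> pd.DataFrame:
    """Convert a correlation matrix to the 1 - r distance matrix."""
    values = c.to_numpy(dtype=float)
    if not np.allclose(values, values.T):
        raise ValueError("correlation matrix must be symmetric")
    d = 1.0 - values
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=c.index, columns=c.columns)
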