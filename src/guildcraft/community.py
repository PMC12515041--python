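"""Community-level statistics: alpha diversity, Bray–Curtis dissimilarity,
principal coordinate analysis, pairwise PERMANOVA with BH correction, and
Procrustes/PROTEST concordance with the information-loss score.

The information-loss score compares how well two aggregation schemes (genus
vs guild) preserve the full feature-level ordination: it is the ratio of the
genus-level Procrustes residual m12^2 to the guild-level one, both measured
against the same reference ordination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .guilds import permanova
from .tables_io import validate_feature_table

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: pd.DataFrame, log_base: float = 2.0) -> pd.DataFrame:
    """Observed feature count and Shannon index per sample.

    Shannon H = -sum p_i log2 p_i over nonzero proportions (bits by default,
    matching the QIIME2 convention; pass ``log_base=np.e`` for nats).
    """
    validate_feature_table(table)
    values = table.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero-sum sample(s) present")
    p = values / totals[:, None]
    logs = np.zeros_like(p)
    np.log(p, out=logs, where=p > 0)
    terms = p * logs
    shannon = -terms.sum(axis=1) / np.log(log_base)
    observed = (values > 0).sum(axis=1)
    return pd.DataFrame({"observed": observed, "shannon": shannon}, index=table.index)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis dissimilarity matrix: d(u,v) = sum|u-v| / sum(u+v)."""
    validate_feature_table(table)
    values = table.to_numpy(dtype=float)
    if (values.sum(axis=1) == 0).any():
        raise ValueError("zero-sum sample(s) present")
    d = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` holds the axes for positive eigenvalues, scaled by
    sqrt(eigenvalue) and ordered by decreasing eigenvalue.  All eigenvalues —
    including negative ones, which arise for semi-metric dissimilarities like
    Bray–Curtis — are kept in ``eigenvalues``; ``proportion_explained`` is
    relative to the sum of positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: pd.DataFrame) -> OrdinationResult:
    """Metric eigen-embedding (principal coordinates) of a distance matrix."""
    values = d.to_numpy(dtype=float)
    n = values.shape[0]
    # Gower double-centering of -1/2 d^2
    a = -0.5 * values**2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigvals, eigvecs = np.linalg.eigh(centered)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(eigvals.max(), 0) * 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = eigvals / pos_sum if pos_sum > 0 else np.zeros(n)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=d.index, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def write_ordination(result: OrdinationResult, path) -> None:
    """Plain-text ordination layout (QIIME2-compatible blocks)."""
    n = len(result.coordinates)
    k = result.coordinates.shape[1]
    with open(path, "w") as fh:
        fh.write(f"Eigvals\t{len(result.eigenvalues)}\n")
        fh.write("\t".join(f"{v:.10g}" for v in result.eigenvalues) + "\n\n")
        fh.write(f"Proportion explained\t{len(result.proportion_explained)}\n")
        fh.write("\t".join(f"{v:.10g}" for v in result.proportion_explained) + "\n\n")
        fh.write(f"Site\t{n}\t{k}\n")
        for sid, row in result.coordinates.iterrows():
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# group testing
# ---------------------------------------------------------------------------

def permanova_pairwise(
    d: pd.DataFrame, groups, n_perm: int = 9_999, seed=None
) -> pd.DataFrame:
    """All pairwise PERMANOVAs with Benjamini–Hochberg adjusted q-values."""
    groups = pd.Series(np.asarray(groups), index=d.index)
    uniq = sorted(groups.unique())
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(uniq, 2):
        idx = groups.index[groups.isin([a, b])]
        sub = d.loc[idx, idx]
        f, p = permanova(sub, groups.loc[idx].to_numpy(), n_perm=n_perm,
                         seed=rng.integers(2**31))
        rows.append({"group_a": a, "group_b": b, "f": f, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Procrustes / PROTEST and information loss
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesComparison:
    """Procrustes residual m12^2 with its PROTEST permutation p-value."""

    m12_squared: float
    protest_p: float
    n_perm: int
    n_axes: int


def _shared_axes(a: OrdinationResult, b: OrdinationResult, n_axes: int | None) -> int:
    k = min(a.coordinates.shape[1], b.coordinates.shape[1])
    if n_axes is not None:
        k = min(k, n_axes)
    if k < 1:
        raise ValueError("no shared positive axes")
    return k


def _m12sq(x: np.ndarray, y: np.ndarray) -> float:
    _, _, disparity = _scipy_procrustes(x, y)
    return float(disparity)


def procrustes(
    a: OrdinationResult,
    b: OrdinationResult,
    n_perm: int = 999,
    seed=None,
    n_axes: int | None = None,
) -> ProcrustesComparison:
    """Least-squares superimposition of two ordinations plus PROTEST.

    Both configurations are centered, scaled to unit sum of squares and
    optimally rotated; m12^2 is the residual sum of squares (0 iff the
    configurations agree up to translation/rotation/scaling).  PROTEST
    permutes the sample rows of ``b``: p = (1 + #{permuted m12^2 <=
    observed}) / (1 + n_perm).  Axes are truncated to the shared
    positive-eigenvalue count (optionally capped at ``n_axes``).
    """
    if list(a.coordinates.index) != list(b.coordinates.index):
        if set(a.coordinates.index) != set(b.coordinates.index):
            raise ValueError("ordinations must cover the same samples")
        b = OrdinationResult(
            coordinates=b.coordinates.loc[a.coordinates.index],
            eigenvalues=b.eigenvalues,
            proportion_explained=b.proportion_explained,
        )
    k = _shared_axes(a, b, n_axes)
    x = a.coordinates.to_numpy()[:, :k]
    y = b.coordinates.to_numpy()[:, :k]
    m12 = _m12sq(x, y)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    count = 0
    for _ in range(n_perm):
        if _m12sq(x, y[rng.permutation(n)]) <= m12 + 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return ProcrustesComparison(m12_squared=m12, protest_p=p, n_perm=n_perm, n_axes=k)


def information_loss(m2_genus: float, m2_cag: float, atol: float = 1e-12) -> float:
    """Ratio of genus-level to guild-level Procrustes residual.

    Values above 1 mean the genus aggregation lost more community structure
    than the guild aggregation.  Returns NaN (undefined) when the guild-level
    residual is zero (within ``atol``, since a perfect superimposition leaves
    a rounding-level residual).
    """
    if m2_genus < 0 or m2_cag < 0:
        raise ValueError("Procrustes residuals cannot be negative")
    if m2_cag <= atol:
        log.info("information_loss: undefined (guild-level m12^2 = 0)")
        return float("nan")
    return m2_genus / m2_cag
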