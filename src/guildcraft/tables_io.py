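"""Feature-table data model, TSV I/O, rarefaction, prevalence filtering and
the four-level data-reduction ledger.

A *feature table* is a :class:`pandas.DataFrame` with samples as rows
(index named ``sample-id``) and features (ASVs, genera or CAGs) as columns.
Values are non-negative counts or relative abundances.  Sample metadata is a
DataFrame indexed by ``sample-id`` with columns ``subject-id``, ``cage``,
``diet``, ``regime``, ``timepoint`` and ``zt_hours``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SAMPLE_ID = "sample-id"

#: Metadata columns required alongside the sample identifier index.
METADATA_COLUMNS = ("subject-id", "cage", "diet", "regime", "timepoint", "zt_hours")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the feature-table invariants and return the table unchanged.

    Raises ``ValueError`` on duplicate sample or feature identifiers, negative
    entries or non-numeric values.
    """
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if table.columns.has_duplicates:
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dups}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("feature table must be numeric")
    if np.isnan(values.astype(float)).any():
        raise ValueError("feature table contains missing values")
    if (values < 0).any():
        raise ValueError("feature table contains negative values")
    return table


def validate_metadata(meta: pd.DataFrame, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check metadata invariants; optionally that it covers ``table``'s samples."""
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if (meta["zt_hours"].astype(float) < 0).any():
        raise ValueError("zt_hours must be non-negative")
    if table is not None:
        absent = table.index.difference(meta.index)
        if len(absent):
            raise ValueError(f"samples without metadata: {absent.tolist()}")
    return meta


# ---------------------------------------------------------------------------
# I/O  (tab-separated, UTF-8, samples as rows, first header cell "sample-id")
# ---------------------------------------------------------------------------

def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.index.name = SAMPLE_ID
    table.columns = table.columns.astype(str)
    return validate_feature_table(table)


def write_feature_table(table: pd.DataFrame, path) -> None:
    validate_feature_table(table)
    out = table.copy()
    out.index.name = SAMPLE_ID
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    meta.index.name = SAMPLE_ID
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: pd.DataFrame, depth: int = 18_000, seed=None) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Draws follow the multivariate hypergeometric distribution (equivalent to
    drawing ``depth`` individual reads without replacement).  Samples whose
    total is below ``depth`` are dropped with a warning.  Counts must be
    integers.

    Parameters
    ----------
    table : counts feature table.
    depth : target library size per sample (default 18 000).
    seed : int or :class:`numpy.random.Generator` for reproducible draws.
    """
    validate_feature_table(table)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    values = table.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError("rarefaction requires integer counts")
    counts = np.round(values).astype(np.int64)
    rng = np.random.default_rng(seed)

    totals = counts.sum(axis=1)
    keep = totals >= depth
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("rarefy: dropping %d sample(s) below depth %d", n_dropped, depth)
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    for row, i in enumerate(np.flatnonzero(keep)):
        if totals[i] == depth:
            out[row] = counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(counts[i], depth)
    return pd.DataFrame(out, index=table.index[keep], columns=table.columns)


# ---------------------------------------------------------------------------
# prevalence filtering and sparsity
# ---------------------------------------------------------------------------

def prevalence_filter(
    table: pd.DataFrame, min_prev: float = 0.25, strict: bool = True
) -> pd.DataFrame:
    """Keep features present in more than ``min_prev`` of the samples.

    Presence means a nonzero value.  The cutoff is strict (``>``) by default,
    so with ``min_prev=0.25`` a feature seen in exactly 25% of samples is
    removed; pass ``strict=False`` for ``>=``.  Column order is preserved.
    """
    validate_feature_table(table)
    if not 0 <= min_prev < 1:
        raise ValueError("min_prev must be in [0, 1)")
    prev = (table.to_numpy() > 0).mean(axis=0)
    keep = prev > min_prev if strict else prev >= min_prev
    # min_prev == 0 with strict cutoff still drops all-zero features
    if keep.sum() == 0:
        log.warning("prevalence_filter: no features pass min_prev=%s", min_prev)
    return table.loc[:, table.columns[keep]]


def sparsity(table: pd.DataFrame) -> float:
    """Percentage of zero cells in the table."""
    if table.size == 0:
        raise ValueError("sparsity of an empty table is undefined")
    return 100.0 * float((table.to_numpy() == 0).sum()) / table.size


# ---------------------------------------------------------------------------
# data-reduction ledger
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed-table rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LedgerRow:
    """One row of the data-reduction comparison ledger.

    ``level`` runs 1 (feature selection) to 4 (health-relevant variables);
    ``method`` is ``"guild"`` or ``"genus"``; percentages are of the original
    rarefied read total.
    """

    level: int
    method: str
    n_variables: int
    reads_retained: int
    total_reads: int
    pct_reads: float
    sparsity_pct: float


def reduction_ledger(
    stages: list[tuple[int, str, pd.DataFrame]],
    total_reads: int | None = None,
    ndigits: int = 2,
) -> list[LedgerRow]:
    """Build the data-reduction ledger from per-level stage tables.

    Each stage is ``(level, method, table)`` where the table holds the reads
    retained at that stage (aggregated variables conserve member-ASV reads,
    so a stage's grand sum maps back to ASV reads).  ``total_reads`` defaults
    to the largest stage sum and must be shared by all stages.
    """
    if not stages:
        raise ValueError("no stages supplied")
    sums = [float(t.to_numpy().sum()) for _, _, t in stages]
    if total_reads is None:
        total_reads = int(round(max(sums)))
    rows = []
    for (level, method, table), s in zip(stages, sums):
        if s > total_reads * (1 + 1e-9):
            raise ValueError(
                f"stage level={level} method={method} retains {s} reads, "
                f"more than the denominator {total_reads}"
            )
        rows.append(
            LedgerRow(
                level=int(level),
                method=method,
                n_variables=table.shape[1],
                reads_retained=int(round(s)),
                total_reads=int(total_reads),
                pct_reads=round_half_up(100.0 * s / total_reads, ndigits),
                sparsity_pct=round_half_up(sparsity(table), ndigits),
            )
        )
    return rows


def ledger_frame(rows: list[LedgerRow]) -> pd.DataFrame:
    """Ledger rows as a DataFrame mirroring the printed comparison table."""
    return pd.DataFrame(
        {
            "level": [r.level for r in rows],
            "method": [r.method for r in rows],
            "n_variables": [r.n_variables for r in rows],
            "reads_retained": [r.reads_retained for r in rows],
            "pct_reads": [r.pct_reads for r in rows],
            "sparsity_pct": [r.sparsity_pct for r in rows],
        }
    )
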