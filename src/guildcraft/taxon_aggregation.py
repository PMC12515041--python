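"""Genus-level comparator: parse QIIME2-style taxonomy strings, split features
into genus-classifiable and unclassifiable sets, aggregate to genera and
track the reads each choice discards.

Genus identity is the full lineage down to the genus rank (not the bare
genus name), so homonymous genera in different families stay separate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

#: Rank prefixes in SILVA/QIIME2 lineage order; genus is depth 6 (1-based).
RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
GENUS_DEPTH = 6

#: Genus tokens treated as unclassifiable (case-insensitive prefixes).
DEFAULT_PLACEHOLDERS = ("uncultured", "unclassified")


@dataclass
class TaxonomyMap:
    """Per-feature taxonomy lineages with genus-level classifiability flags."""

    lineages: dict[str, list[str]]
    placeholders: tuple[str, ...] = DEFAULT_PLACEHOLDERS
    _genus: dict[str, str | None] = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self):
        for fid, ranks in self.lineages.items():
            self._genus[fid] = self._genus_lineage(ranks)

    def _genus_lineage(self, ranks: list[str]) -> str | None:
        if len(ranks) < GENUS_DEPTH:
            return None
        genus = ranks[GENUS_DEPTH - 1].strip()
        name = genus[3:] if genus.lower().startswith("g__") else genus
        name = name.strip()
        if not name:
            return None
        if any(name.lower().startswith(tok) for tok in self.placeholders):
            return None
        return ";".join(r.strip() for r in ranks[:GENUS_DEPTH])

    def classifiable_at_genus(self, feature_id: str) -> bool:
        if feature_id not in self._genus:
            raise KeyError(f"no taxonomy for feature {feature_id!r}")
        return self._genus[feature_id] is not None

    def genus_of(self, feature_id: str) -> str | None:
        """Full lineage string down to genus, or None if unclassifiable."""
        if feature_id not in self._genus:
            raise KeyError(f"no taxonomy for feature {feature_id!r}")
        return self._genus[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


def read_taxonomy(path, placeholders: tuple[str, ...] = DEFAULT_PLACEHOLDERS) -> TaxonomyMap:
    """Read a QIIME2 taxonomy export: columns "Feature ID" and "Taxon"
    (semicolon-delimited lineage); an optional "Confidence" column is ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    fid_col = cols.get("feature id") or df.columns[0]
    tax_col = cols.get("taxon") or df.columns[1]
    lineages = {
        str(row[fid_col]): [t.strip() for t in str(row[tax_col]).split(";")]
        for _, row in df.iterrows()
    }
    return TaxonomyMap(lineages=lineages, placeholders=placeholders)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    pd.DataFrame(
        {
            "Feature ID": list(tax.lineages),
            "Taxon": ["; ".join(r) for r in tax.lineages.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def aggregate_genus(
    table: pd.DataFrame, tax: TaxonomyMap
) -> tuple[pd.DataFrame, list[str]]:
    """Sum classifiable features into genus columns; return the genus table
    and the list of excluded (genus-unclassifiable) features.

    Conservation: reads(genus table) + reads(excluded features) equals the
    input read total exactly.
    """
    missing = [f for f in table.columns if f not in tax]
    if missing:
        raise ValueError(f"taxonomy does not cover features: {missing[:5]}...")
    genus_members: dict[str, list[str]] = {}
    excluded: list[str] = []
    for f in table.columns:
        g = tax.genus_of(str(f))
        if g is None:
            excluded.append(str(f))
        else:
            genus_members.setdefault(g, []).append(f)
    genus_table = pd.DataFrame(
        {g: table[members].sum(axis=1) for g, members in genus_members.items()},
        index=table.index,
    )
    if excluded:
        excl_reads = float(table[excluded].to_numpy().sum())
        total = float(table.to_numpy().sum())
        log.info(
            "aggregate_genus: excluded %d unclassifiable feature(s), %.0f reads (%.1f%%)",
            len(excluded), excl_reads, 100 * excl_reads / total if total else 0.0,
        )
    return genus_table, excluded


def genus_prevalence_filter(
    genus_table: pd.DataFrame, min_prev: float = 0.25, strict: bool = True
) -> pd.DataFrame:
    """Prevalence cutoff on genus columns; same strict-``>`` contract as the
    ASV-level filter."""
    from .tables_io import prevalence_filter

    return prevalence_filter(genus_table, min_prev=min_prev, strict=strict)


def track_asvs(
    guild_side: set[str],
    genus_side: set[str],
    table: pd.DataFrame,
    tax: TaxonomyMap | None = None,
) -> dict:
    """Compare the health-relevant ASV sets selected by the two methods.

    Returns shared and per-side exclusive ASVs with their read counts and
    percentage of the table's total reads; when a taxonomy is supplied the
    guild-exclusive set is further split by genus classifiability.
    """
    guild_side = {str(f) for f in guild_side}
    genus_side = {str(f) for f in genus_side}
    total = float(table.to_numpy().sum())

    def summarize(features: set[str]) -> dict:
        present = [f for f in features if f in table.columns]
        reads = float(table[present].to_numpy().sum()) if present else 0.0
        return {
            "n": len(features),
            "reads": int(round(reads)),
            "pct_reads": 100.0 * reads / total if total else 0.0,
        }

    shared = guild_side & genus_side
    report = {
        "shared": {"features": sorted(shared), **summarize(shared)},
        "guild_only": {"features": sorted(guild_side - genus_side),
                       **summarize(guild_side - genus_side)},
        "genus_only": {"features": sorted(genus_side - guild_side),
                       **summarize(genus_side - guild_side)},
    }
    if tax is not None:
        unclass = {f for f in guild_side - genus_side
                   if f in tax and not tax.classifiable_at_genus(f)}
        report["guild_only_unclassifiable"] = {"features": sorted(unclass), **summarize(unclass)}
    return report
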