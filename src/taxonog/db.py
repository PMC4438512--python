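"""Build the rank-wise taxon-specific (unique) NOG database.

For every rank, the NOGs of all member genomes of a taxon are pooled into
the taxon-total set; a NOG is taxon-specific (unique) when it is absent from
the total set of every *other* taxon at the same rank — not merely from the
taxon's siblings.  With fully classified reference lineages this global rule
automatically nests: a NOG unique to a class can only occur inside one
phylum, so it is unique to that phylum too.

Reference genomes may be only partially classified.  They contribute at the
ranks where their lineage is known and are skipped at deeper ranks.  To keep
the parent-containment invariant (child-unique within parent-unique) exact
in that case as well, unique sets are intersected top-down with the parent
taxon's unique set; on fully classified references this is a no-op.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Mapping

import pandas as pd

from .annotation import MIN_GENES_DEFAULT, filter_genomes
from .core import RANKS, Rank, ReferenceTaxonomy, TaxonKey, UniqueNogDB

__all__ = [
    "total_nogs_per_taxon",
    "unique_nogs_per_taxon",
    "build_db",
    "db_summary",
]


def total_nogs_per_taxon(
    ref: ReferenceTaxonomy, rank: Rank
) -> Dict[TaxonKey, FrozenSet[str]]:
    """Union of member genomes' NOG sets per taxon at ``rank``.

    Genomes whose lineage is unknown at ``rank`` are skipped at that rank.
    """
    totals: Dict[TaxonKey, set] = {}
    for key, members in ref.members(rank).items():
        pooled = totals.setdefault(key, set())
        for profile in members:
            pooled |= profile.nogs
    return {key: frozenset(nogs) for key, nogs in totals.items()}


def unique_nogs_per_taxon(
    totals: Mapping[TaxonKey, Iterable[str]],
) -> Dict[TaxonKey, FrozenSet[str]]:
    """Per taxon, the NOGs present in no other taxon of the same rank.

    unique[t] = totals[t] minus the union of totals[u] over all u != t.
    """
    if not totals:
        raise ValueError("need at least one taxon")
    # a NOG is unique iff it occurs in exactly one taxon; subtracting the
    # union of all *other* totals per taxon is equivalent and avoids
    # re-unioning for every taxon
    owner: Dict[str, TaxonKey | None] = {}
    for key, nogs in totals.items():
        for nog in nogs:
            owner[nog] = key if nog not in owner else None
    unique: Dict[TaxonKey, FrozenSet[str]] = {}
    for key, nogs in totals.items():
        unique[key] = frozenset(n for n in nogs if owner[n] == key)
    return unique


def build_db(
    ref: ReferenceTaxonomy, min_genes: int = MIN_GENES_DEFAULT
) -> UniqueNogDB:
    """Build the full six-rank unique-NOG database from a reference taxonomy.

    Applies the genome-size filter first, then computes total and unique sets
    for every rank.  Deterministic: genome order never affects the result.
    """
    kept, dropped = filter_genomes(ref.profiles, min_genes=min_genes)
    if not kept:
        raise ValueError(
            f"no reference genomes left after the >= {min_genes} genes filter "
            f"({len(dropped)} dropped)"
        )
    filtered = ReferenceTaxonomy(profiles=kept, lineage_of=ref.lineage_of)
    total: Dict[Rank, Dict[TaxonKey, FrozenSet[str]]] = {}
    unique: Dict[Rank, Dict[TaxonKey, FrozenSet[str]]] = {}
    for rank in RANKS:
        totals_r = total_nogs_per_taxon(filtered, rank)
        if not totals_r:
            total[rank] = {}
            unique[rank] = {}
            continue
        uniques_r = unique_nogs_per_taxon(totals_r)
        if rank > Rank.PHYLUM:
            parent_unique = unique[Rank(rank - 1)]
            uniques_r = {
                key: nogs & parent_unique.get(key[:-1], frozenset())
                for key, nogs in uniques_r.items()
            }
        total[rank] = totals_r
        unique[rank] = uniques_r
    meta = {
        "source_genomes": len(kept),
        "dropped_genomes": len(dropped),
        "min_genes": min_genes,
    }
    return UniqueNogDB(unique=unique, total=total, meta=meta)


def db_summary(db: UniqueNogDB) -> pd.DataFrame:
    """Per-taxon abundance table: total, unique and unique fraction per rank."""
    rows = []
    for rank in RANKS:
        for key in sorted(db.total.get(rank, {})):
            n_total = len(db.total[rank][key])
            n_unique = len(db.unique.get(rank, {}).get(key, frozenset()))
            rows.append(
                {
                    "rank": rank.label,
                    "taxon_key": "|".join(key),
                    "taxon": key[-1],
                    "n_total": n_total,
                    "n_unique": n_unique,
                    "unique_fraction": n_unique / n_total if n_total else 0.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["rank", "taxon_key", "taxon", "n_total", "n_unique", "unique_fraction"],
    )
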