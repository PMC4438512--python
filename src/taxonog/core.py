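"""Core domain types for gene-content based bacterial taxonomy.

The unit of gene content throughout the package is the NOG (non-supervised
orthologous group) identifier: a genome is reduced to the *set* of NOGs its
protein-coding genes map to.  Reference genomes carry a six-rank lineage
(phylum .. species); a taxon is identified by its full lineage prefix, never
by its bare name, so that homonymous names under different parents remain
distinct taxa.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

__all__ = [
    "Rank",
    "RANKS",
    "UNCLASSIFIED",
    "TaxonKey",
    "Lineage",
    "GenomeProfile",
    "ReferenceTaxonomy",
    "UniqueNogDB",
    "ClassifierConfig",
    "RankDecision",
    "ClassificationResult",
    "MissingRankError",
    "LineageGapError",
    "taxon_key",
]

#: Sentinel label for a rank at which no taxon reached the evidence threshold.
UNCLASSIFIED = "UNCLASSIFIED"

#: A taxon key: the tuple of lineage labels from phylum down to the taxon's rank.
TaxonKey = Tuple[str, ...]


class Rank(enum.IntEnum):
    """The six bacterial taxonomic ranks, ordered from broadest to narrowest."""

    PHYLUM = 0
    CLASS = 1
    ORDER = 2
    FAMILY = 3
    GENUS = 4
    SPECIES = 5

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Rank":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown rank label: {label!r}") from None

    @property
    def parent(self) -> Optional["Rank"]:
        return Rank(self - 1) if self > Rank.PHYLUM else None

    @property
    def child(self) -> Optional["Rank"]:
        return Rank(self + 1) if self < Rank.SPECIES else None


RANKS: Tuple[Rank, ...] = tuple(Rank)

#: Greengenes-style single-letter rank prefixes, phylum .. species.
_GG_PREFIXES = ("p__", "c__", "o__", "f__", "g__", "s__")

_WS = re.compile(r"\s+")


def _norm(label: str) -> str:
    """Whitespace-normalize a taxon label (labels compare case-sensitively)."""
    return _WS.sub(" ", label.strip())


class MissingRankError(KeyError):
    """A lineage was queried at a rank where it is unknown."""


class LineageGapError(ValueError):
    """A lineage has a known rank below an unknown one (gaps are not allowed)."""


@dataclass(frozen=True)
class Lineage:
    """Ordered taxon labels phylum -> species; ``None`` marks an unknown rank.

    Invariant: once a rank is unknown every deeper rank is unknown too, so a
    lineage is always a contiguous prefix of known labels starting at phylum.
    """

    labels: Tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        labels = tuple(
            _norm(l) if isinstance(l, str) and _norm(l) else None for l in self.labels
        )
        if len(labels) != len(RANKS):
            raise ValueError(f"expected {len(RANKS)} labels, got {len(labels)}")
        seen_unknown = False
        for rank, label in zip(RANKS, labels):
            if label is None:
                seen_unknown = True
            elif seen_unknown:
                raise LineageGapError(
                    f"rank {rank.label} is known below an unknown rank: {labels}"
                )
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_labels(cls, *labels: Optional[str]) -> "Lineage":
        """Build from up to six positional labels (missing trailing ranks ok)."""
        padded = list(labels) + [None] * (len(RANKS) - len(labels))
        return cls(tuple(padded))

    @classmethod
    def from_greengenes(cls, lineage_string: str) -> "Lineage":
        """Parse a Greengenes-style string ``p__X; c__Y; ...`` into a lineage.

        Ranks above phylum (``k__``) are ignored; an empty label after its
        prefix (``g__``) marks the rank unknown.
        """
        by_prefix: Dict[str, str] = {}
        for token in lineage_string.split(";"):
            token = token.strip()
            if len(token) >= 3 and token[1:3] == "__":
                by_prefix[token[:3]] = token[3:]
        return cls(tuple(_norm(by_prefix.get(p, "")) or None for p in _GG_PREFIXES))

    def known_at(self, rank: Rank) -> bool:
        return self.labels[rank] is not None

    @property
    def deepest_known(self) -> Optional[Rank]:
        deepest = None
        for rank in RANKS:
            if self.labels[rank] is not None:
                deepest = rank
        return deepest

    def label(self, rank: Rank) -> Optional[str]:
        return self.labels[rank]

    def key(self, rank: Rank) -> TaxonKey:
        """The full lineage prefix through ``rank`` (the taxon's identity)."""
        if self.labels[rank] is None:
            raise MissingRankError(f"lineage unknown at rank {rank.label}: {self}")
        return tuple(self.labels[: rank + 1])  # type: ignore[return-value]

    def __str__(self) -> str:
        return ";".join(l if l is not None else "" for l in self.labels)


def taxon_key(lineage: Lineage, rank: Rank) -> TaxonKey:
    """The identity of ``lineage``'s taxon at ``rank``: its full label prefix.

    Keying taxa by the phylum-through-rank label tuple disambiguates
    same-named taxa that sit under different parents.
    """
    return lineage.key(rank)


@dataclass(frozen=True)
class GenomeProfile:
    """A genome reduced to its deduplicated NOG set.

    ``gene_count`` is the pre-deduplication gene total; ``assigned_fraction``
    is the share of genes that received any NOG.  Each NOG appears at most
    once per genome regardless of how many genes mapped to it.
    """

    genome_id: str
    nogs: FrozenSet[str]
    gene_count: int
    assigned_fraction: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nogs", frozenset(self.nogs))
        if self.gene_count < 0:
            raise ValueError("gene_count must be >= 0")
        if len(self.nogs) > self.gene_count:
            raise ValueError(
                f"{self.genome_id}: {len(self.nogs)} NOGs exceed gene_count "
                f"{self.gene_count}"
            )
        if not 0.0 <= self.assigned_fraction <= 1.0:
            raise ValueError("assigned_fraction must be in [0, 1]")


@dataclass
class ReferenceTaxonomy:
    """Reference genome profiles plus their lineages.

    Every profile must have a lineage and every lineage a known phylum.
    """

    profiles: List[GenomeProfile]
    lineage_of: Dict[str, Lineage]

    def __post_init__(self) -> None:
        for profile in self.profiles:
            lineage = self.lineage_of.get(profile.genome_id)
            if lineage is None:
                raise ValueError(f"no lineage for genome {profile.genome_id}")
            if not lineage.known_at(Rank.PHYLUM):
                raise ValueError(f"genome {profile.genome_id} has no phylum")

    def __len__(self) -> int:
        return len(self.profiles)

    def members(self, rank: Rank) -> Dict[TaxonKey, List[GenomeProfile]]:
        """Profiles grouped by taxon at ``rank``; unknown-at-rank genomes skipped."""
        groups: Dict[TaxonKey, List[GenomeProfile]] = {}
        for profile in self.profiles:
            lineage = self.lineage_of[profile.genome_id]
            if lineage.known_at(rank):
                groups.setdefault(lineage.key(rank), []).append(profile)
        return groups


@dataclass
class UniqueNogDB:
    """Per-rank, per-taxon sets of taxon-specific (unique) and total NOGs.

    A NOG is unique to a taxon at a rank when it occurs in that taxon and in
    no other taxon at the same rank.  Invariants: within a rank the unique
    sets of distinct taxa are pairwise disjoint; unique[t] is a subset of
    total[t]; and below phylum unique[t] is a subset of unique[parent(t)].
    """

    unique: Dict[Rank, Dict[TaxonKey, FrozenSet[str]]]
    total: Dict[Rank, Dict[TaxonKey, FrozenSet[str]]]
    meta: Dict[str, object] = field(default_factory=dict)

    def taxa(self, rank: Rank) -> List[TaxonKey]:
        return sorted(self.unique.get(rank, {}))

    def children(self, rank: Rank, parent: TaxonKey) -> List[TaxonKey]:
        """Taxa at ``rank`` whose lineage prefix extends ``parent``."""
        return [k for k in self.taxa(rank) if k[: len(parent)] == parent]

    def unique_nogs(self, rank: Rank, key: TaxonKey) -> FrozenSet[str]:
        return self.unique.get(rank, {}).get(key, frozenset())

    def total_nogs(self, rank: Rank, key: TaxonKey) -> FrozenSet[str]:
        return self.total.get(rank, {}).get(key, frozenset())

    def validate(self) -> None:
        """Assert the structural invariants; raise ``AssertionError`` on breach."""
        for rank in RANKS:
            uniques = self.unique.get(rank, {})
            seen: Dict[str, TaxonKey] = {}
            for key, nogs in uniques.items():
                assert nogs <= self.total.get(rank, {}).get(key, frozenset()), (
                    f"unique not within total for {key} at {rank.label}"
                )
                for nog in nogs:
                    other = seen.get(nog)
                    assert other is None, (
                        f"NOG {nog} unique to both {other} and {key} at {rank.label}"
                    )
                    seen[nog] = key
                if rank > Rank.PHYLUM:
                    parent_unique = self.unique.get(Rank(rank - 1), {}).get(
                        key[:-1], frozenset()
                    )
                    assert nogs <= parent_unique, (
                        f"unique NOGs of {key} not within parent "
                        f"{key[:-1]} at {Rank(rank - 1).label}"
                    )

    # -- serialization: one TSV per rank (rank, taxon_key, nog_id rows, sorted)
    # plus a JSON meta header.  No timestamps: identical inputs must produce
    # byte-identical artifacts.

    _KEY_SEP = "|"

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for rank in RANKS:
            for kind, table in (("unique", self.unique), ("total", self.total)):
                rows = sorted(
                    (self._KEY_SEP.join(key), nog)
                    for key, nogs in table.get(rank, {}).items()
                    for nog in nogs
                )
                path = directory / f"{rank.label}.{kind}.tsv"
                with path.open("w") as handle:
                    handle.write("rank\ttaxon_key\tnog_id\n")
                    for key_str, nog in rows:
                        handle.write(f"{rank.label}\t{key_str}\t{nog}\n")
        # taxa with empty sets would vanish from the pair-per-row TSVs,
        # so the taxon list is kept in the metadata
        meta = dict(self.meta)
        meta["taxa"] = {
            rank.label: [self._KEY_SEP.join(k) for k in sorted(self.total.get(rank, {}))]
            for rank in RANKS
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "UniqueNogDB":
        directory = Path(directory)
        meta_path = directory / "meta.json"
        if not meta_path.exists():
            raise FileNotFoundError(
                f"no unique-NOG database found in {directory} (missing meta.json)"
            )
        meta = json.loads(meta_path.read_text())
        taxa = meta.pop("taxa", {})
        unique: Dict[Rank, Dict[TaxonKey, FrozenSet[str]]] = {}
        total: Dict[Rank, Dict[TaxonKey, FrozenSet[str]]] = {}
        for rank in RANKS:
            for kind, table in (("unique", unique), ("total", total)):
                per_taxon: Dict[TaxonKey, set] = {
                    tuple(k.split(cls._KEY_SEP)): set()
                    for k in taxa.get(rank.label, [])
                }
                path = directory / f"{rank.label}.{kind}.tsv"
                if path.exists():
                    with path.open() as handle:
                        next(handle)  # header
                        for line in handle:
                            _, key_str, nog = line.rstrip("\n").split("\t")
                            per_taxon.setdefault(
                                tuple(key_str.split(cls._KEY_SEP)), set()
                            ).add(nog)
                table[rank] = {k: frozenset(v) for k, v in per_taxon.items()}
        return cls(unique=unique, total=total, meta=meta)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunables of the hierarchical maximum-match classifier.

    tie_threshold
        The look-ahead rule fires when the runner-up taxon's match count is at
        least this fraction of the best taxon's (default 0.30).
    lookahead_depth
        How many ranks a look-ahead chain may descend while the candidates
        stay tied (chains starting at phylum never extend below order).
    min_matches
        Minimum taxon-specific matches required to assign a rank at all;
        below it the rank (and all deeper ranks) are UNCLASSIFIED.
    tie_rank_limit
        Deepest rank at which the tie rule is applied; ``Rank.GENUS`` applies
        it uniformly, ``Rank.CLASS`` restricts it to phylum and class.
    """

    tie_threshold: float = 0.30
    lookahead_depth: int = 1
    min_matches: int = 1
    tie_rank_limit: Rank = Rank.GENUS

    def __post_init__(self) -> None:
        if not 0.0 < self.tie_threshold < 1.0:
            raise ValueError("tie_threshold must be in (0, 1)")
        if self.lookahead_depth < 1:
            raise ValueError("lookahead_depth must be >= 1")
        if self.min_matches < 1:
            raise ValueError("min_matches must be >= 1")


@dataclass
class RankDecision:
    """The outcome of scoring one rank for one query genome."""

    rank: Rank
    candidates: List[Tuple[TaxonKey, int]]
    chosen: Optional[TaxonKey]  # None == UNCLASSIFIED
    match_count: int = 0
    runner_up: Optional[TaxonKey] = None
    runner_up_count: int = 0
    tie_triggered: bool = False
    resolved_by: Optional[Rank] = None
    lookahead_trace: Optional["RankDecision"] = None

    @property
    def assigned_label(self) -> str:
        return self.chosen[-1] if self.chosen else UNCLASSIFIED


@dataclass
class ClassificationResult:
    """Per-rank assignments for one query genome.

    Assignments form a consistent lineage (each chosen taxon is a child of
    the previous rank's choice) and once a rank is UNCLASSIFIED all deeper
    ranks are UNCLASSIFIED.
    """

    genome_id: str
    decisions: Dict[Rank, RankDecision]

    @property
    def deepest_assigned(self) -> Optional[Rank]:
        deepest = None
        for rank in RANKS:
            if self.decisions[rank].chosen is not None:
                deepest = rank
        return deepest

    def assigned(self, rank: Rank) -> Optional[TaxonKey]:
        return self.decisions[rank].chosen

    @property
    def lineage_labels(self) -> Tuple[str, ...]:
        """Six assigned labels, using the UNCLASSIFIED sentinel where unassigned."""
        return tuple(self.decisions[rank].assigned_label for rank in RANKS)

    def to_rows(self) -> List[Dict[str, object]]:
        rows = []
        for rank in RANKS:
            decision = self.decisions[rank]
            rows.append(
                {
                    "genome_id": self.genome_id,
                    "rank": rank.label,
                    "assigned": decision.assigned_label,
                    "match_count": decision.match_count,
                    "runner_up": (
                        decision.runner_up[-1] if decision.runner_up else ""
                    ),
                    "runner_up_count": decision.runner_up_count,
                    "tie_triggered": decision.tie_triggered,
                }
            )
        return rows
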