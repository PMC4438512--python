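"""Tabular readers and writers for lineages, profiles and reports.

All interchange is plain TSV (one JSON sidecar for database metadata).
Writers emit rows in sorted order so identical inputs always produce
byte-identical artifacts.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from .annotation import NogCatalog, ParseError
from .core import RANKS, GenomeProfile, Lineage, LineageGapError, Rank, ReferenceTaxonomy

__all__ = [
    "read_lineage_table",
    "write_lineage_table",
    "write_gene2nog",
    "write_catalog",
    "read_reference",
]

logger = logging.getLogger(__name__)

_LINEAGE_COLUMNS = ["genome_id"] + [rank.label for rank in RANKS]


def read_lineage_table(
    path: str | Path,
) -> Tuple[Dict[str, Lineage], List[Tuple[int, str]]]:
    """Read a lineage TSV (genome_id, phylum..species; empty cell = unknown).

    A single ``lineage`` column holding Greengenes-style strings
    (``p__X; c__Y; ...``) is accepted as an alternative layout.  Rows that
    violate the no-gap rule (a known rank below an unknown one) are rejected;
    the rejected (line, reason) pairs are returned alongside the table and
    their count is logged.
    """
    path = Path(path)
    lineages: Dict[str, Lineage] = {}
    rejected: List[Tuple[int, str]] = []
    with path.open() as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ParseError(path, 1, "empty lineage table")
        header = [c.strip() for c in header]
        if header == _LINEAGE_COLUMNS:
            greengenes = False
        elif header == ["genome_id", "lineage"]:
            greengenes = True
        else:
            raise ParseError(
                path,
                1,
                f"expected columns {_LINEAGE_COLUMNS} or [genome_id, lineage], got {header}",
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                rejected.append((lineno, f"expected {len(header)} columns, got {len(row)}"))
                continue
            genome_id = row[0].strip()
            try:
                if greengenes:
                    lineage = Lineage.from_greengenes(row[1])
                else:
                    lineage = Lineage(tuple(row[1:]))
            except LineageGapError as exc:
                rejected.append((lineno, str(exc)))
                continue
            lineages[genome_id] = lineage
    if rejected:
        logger.warning(
            "%s: rejected %d lineage rows violating the no-gap rule", path, len(rejected)
        )
    return lineages, rejected


def write_lineage_table(lineages: Dict[str, Lineage], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        handle.write("\t".join(_LINEAGE_COLUMNS) + "\n")
        for genome_id in sorted(lineages):
            labels = [l or "" for l in lineages[genome_id].labels]
            handle.write("\t".join([genome_id] + labels) + "\n")


def write_gene2nog(profiles: Iterable[GenomeProfile], path: str | Path) -> None:
    """Write profiles as a gene-to-NOG TSV.

    Gene ids are synthesized (one gene per NOG, plus empty-NOG filler rows up
    to the genome's gene total), which round-trips the NOG sets and gene
    counts exactly.
    """
    with Path(path).open("w") as handle:
        handle.write("genome_id\tgene_id\tnog_id\n")
        for profile in sorted(profiles, key=lambda p: p.genome_id):
            gene = 0
            for nog in sorted(profile.nogs):
                handle.write(f"{profile.genome_id}\tgene{gene:05d}\t{nog}\n")
                gene += 1
            for _ in range(profile.gene_count - len(profile.nogs)):
                handle.write(f"{profile.genome_id}\tgene{gene:05d}\t\n")
                gene += 1


def write_catalog(catalog: NogCatalog, path: str | Path) -> None:
    with Path(path).open("w") as handle:
        handle.write("member_id\tnog_id\tcategories\n")
        for member in sorted(catalog.member_to_nog):
            nog = catalog.member_to_nog[member]
            cats = catalog.nog_to_categories.get(nog, "")
            handle.write(f"{member}\t{nog}\t{cats}\n")


def read_reference(
    profiles_path: str | Path, lineage_path: str | Path
) -> ReferenceTaxonomy:
    """Load a reference taxonomy from a gene-to-NOG TSV plus a lineage TSV.

    Profiles without a lineage row are dropped with a logged count (the
    reverse — lineages without profiles — is harmless and ignored).
    """
    from .annotation import load_profiles

    profiles = load_profiles(profiles_path, fmt="gene2nog")
    lineages, _ = read_lineage_table(lineage_path)
    matched = [p for p in profiles if p.genome_id in lineages]
    if len(matched) < len(profiles):
        logger.warning(
            "%d profiles had no lineage row and were dropped", len(profiles) - len(matched)
        )
    return ReferenceTaxonomy(
        profiles=matched,
        lineage_of={p.genome_id: lineages[p.genome_id] for p in matched},
    )
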