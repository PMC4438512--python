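"""Turn per-gene evidence into genome NOG profiles.

Two input routes are supported: a direct gene-to-NOG table, or a precomputed
tabular best-hit alignment (NCBI BLAST ``-outfmt 6``) against an orthologous
-group members catalog.  Running the aligner itself is out of scope — the
package consumes its tabular output.

Per gene, only the best hit transfers a NOG (maximal bit score; ties broken
by lower e-value, then lexicographically smallest subject id).  Each NOG
enters a genome's profile at most once.  Genomes with fewer genes than the
smallest known bacterial gene complement (475, *Mycoplasma genitalium*) are
excluded from reference databases.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

from .core import GenomeProfile

__all__ = [
    "AlignmentHit",
    "NogCatalog",
    "ParseError",
    "MIN_GENES_DEFAULT",
    "assign_nogs",
    "filter_genomes",
    "load_profiles",
    "read_blast_tab",
    "count_fasta_sequences",
]

logger = logging.getLogger(__name__)

#: Smallest gene complement known for a bacterium (Mycoplasma genitalium).
MIN_GENES_DEFAULT = 475


class ParseError(ValueError):
    """A tabular input failed to parse; carries the offending line number."""

    def __init__(self, path, line_number: int, message: str):
        super().__init__(f"{path}:{line_number}: {message}")
        self.path = path
        self.line_number = line_number


class AlignmentHit(NamedTuple):
    """One query-gene vs catalog-member alignment hit."""

    gene_id: str
    subject_id: str
    bit_score: float
    e_value: float


@dataclass
class NogCatalog:
    """Maps catalog member proteins to their NOG and NOGs to COG categories.

    ``nog_to_categories`` values are strings of single-letter functional
    category codes; a NOG absent from the mapping stays uncategorized (the
    unknown-function placeholder ``S`` is never auto-assigned).
    """

    member_to_nog: Dict[str, str]
    nog_to_categories: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NogCatalog":
        """Read a catalog TSV with columns member_id, nog_id, categories.

        The categories column is optional per row; a header line is required.
        """
        member_to_nog: Dict[str, str] = {}
        nog_to_categories: Dict[str, str] = {}
        path = Path(path)
        with path.open() as handle:
            reader = csv.reader(handle, delimiter="\t")
            header = next(reader, None)
            if header is None or header[0] != "member_id":
                raise ParseError(path, 1, "expected header starting with member_id")
            for lineno, row in enumerate(reader, start=2):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) < 2:
                    raise ParseError(path, lineno, f"expected >=2 columns, got {len(row)}")
                member, nog = row[0].strip(), row[1].strip()
                member_to_nog[member] = nog
                if len(row) >= 3 and row[2].strip():
                    nog_to_categories[nog] = row[2].strip()
        return cls(member_to_nog, nog_to_categories)


def _best_hit(hits: List[AlignmentHit]) -> AlignmentHit:
    # deterministic regardless of input order: score desc, e-value asc, subject asc
    return min(hits, key=lambda h: (-h.bit_score, h.e_value, h.subject_id))


def assign_nogs(
    hits: Iterable[AlignmentHit],
    catalog: NogCatalog,
    genome_id: str,
    gene_count: int,
    max_evalue: Optional[float] = 1e-5,
) -> GenomeProfile:
    """Build a genome profile from alignment hits via best-hit NOG transfer.

    Hits above ``max_evalue`` are discarded before best-hit selection (set to
    ``None`` to keep all hits).  Genes whose best subject is absent from the
    catalog count as unassigned.  The result is a pure function of the hit
    multiset: input order never matters.
    """
    by_gene: Dict[str, List[AlignmentHit]] = {}
    for hit in hits:
        if max_evalue is not None and hit.e_value > max_evalue:
            continue
        by_gene.setdefault(hit.gene_id, []).append(hit)
    if gene_count < len(by_gene):
        raise ValueError(
            f"{genome_id}: gene_count {gene_count} < {len(by_gene)} distinct genes in hits"
        )
    nogs = set()
    assigned = 0
    unmapped = 0
    for gene_id in sorted(by_gene):
        best = _best_hit(by_gene[gene_id])
        nog = catalog.member_to_nog.get(best.subject_id)
        if nog is None:
            unmapped += 1
            continue
        nogs.add(nog)
        assigned += 1
    if unmapped:
        logger.warning(
            "%s: %d genes had best hits missing from the catalog", genome_id, unmapped
        )
    fraction = assigned / gene_count if gene_count else 0.0
    return GenomeProfile(
        genome_id=genome_id,
        nogs=frozenset(nogs),
        gene_count=gene_count,
        assigned_fraction=fraction,
    )


def filter_genomes(
    profiles: Iterable[GenomeProfile], min_genes: int = MIN_GENES_DEFAULT
) -> Tuple[List[GenomeProfile], List[Tuple[GenomeProfile, str]]]:
    """Split profiles into (kept, dropped-with-reason) by total gene count.

    A genome is kept iff ``gene_count >= min_genes`` (boundary inclusive).
    """
    kept: List[GenomeProfile] = []
    dropped: List[Tuple[GenomeProfile, str]] = []
    for profile in profiles:
        if profile.gene_count >= min_genes:
            kept.append(profile)
        else:
            dropped.append(
                (profile, f"gene_count {profile.gene_count} < {min_genes}")
            )
    return kept, dropped


def read_blast_tab(path: str | Path) -> List[AlignmentHit]:
    """Parse NCBI BLAST tabular output (``-outfmt 6``, 12 columns, no header)."""
    hits: List[AlignmentHit] = []
    path = Path(path)
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(path, lineno, f"expected 12 columns, got {len(fields)}")
            try:
                hits.append(
                    AlignmentHit(
                        gene_id=fields[0],
                        subject_id=fields[1],
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return hits


def _load_gene2nog(path: Path) -> List[GenomeProfile]:
    """Read a gene-to-NOG TSV (genome_id, gene_id, nog_id; header required).

    An empty nog_id marks a gene that received no NOG; it still counts toward
    the genome's gene total.  Duplicate (genome, gene) rows naming different
    NOGs are an error; consistent duplicates collapse.
    """
    genes: Dict[str, Dict[str, Optional[str]]] = {}
    with path.open() as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:3]] != [
            "genome_id",
            "gene_id",
            "nog_id",
        ]:
            raise ParseError(path, 1, "expected header genome_id\tgene_id\tnog_id")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ParseError(path, lineno, f"expected 3 columns, got {len(row)}")
            genome_id, gene_id, nog_id = (c.strip() for c in row)
            if not genome_id or not gene_id:
                raise ParseError(path, lineno, "empty genome_id or gene_id")
            nog: Optional[str] = nog_id or None
            per_genome = genes.setdefault(genome_id, {})
            if gene_id in per_genome and per_genome[gene_id] != nog:
                raise ParseError(
                    path,
                    lineno,
                    f"gene {gene_id} of {genome_id} maps to both "
                    f"{per_genome[gene_id]!r} and {nog!r}",
                )
            per_genome[gene_id] = nog
    profiles = []
    for genome_id in sorted(genes):
        per_genome = genes[genome_id]
        nogs = frozenset(n for n in per_genome.values() if n is not None)
        assigned = sum(1 for n in per_genome.values() if n is not None)
        profiles.append(
            GenomeProfile(
                genome_id=genome_id,
                nogs=nogs,
                gene_count=len(per_genome),
                assigned_fraction=assigned / len(per_genome) if per_genome else 0.0,
            )
        )
    return profiles


def load_profiles(
    path: str | Path,
    fmt: str = "gene2nog",
    catalog: Optional[NogCatalog] = None,
    genome_id: Optional[str] = None,
    gene_count: Optional[int] = None,
    max_evalue: Optional[float] = 1e-5,
) -> List[GenomeProfile]:
    """Load genome profiles from a tabular file.

    ``fmt="gene2nog"`` reads a multi-genome gene-to-NOG TSV.  ``fmt="blast-tab"``
    reads one genome's BLAST tabular hits and requires a ``catalog``; the
    genome id defaults to the file stem and the gene total to the number of
    distinct query ids (pass ``gene_count`` when unaligned genes exist).
    Output is deterministic regardless of row order.
    """
    path = Path(path)
    if fmt == "gene2nog":
        return _load_gene2nog(path)
    if fmt == "blast-tab":
        if catalog is None:
            raise ValueError("blast-tab format requires a catalog")
        hits = read_blast_tab(path)
        n_genes = gene_count if gene_count is not None else len({h.gene_id for h in hits})
        return [
            assign_nogs(
                hits,
                catalog,
                genome_id=genome_id or path.stem,
                gene_count=n_genes,
                max_evalue=max_evalue,
            )
        ]
    raise ValueError(f"unknown profile format: {fmt!r}")


def count_fasta_sequences(path: str | Path) -> int:
    """Number of sequences in a protein FASTA (used only to count genes)."""
    from Bio import SeqIO

    return sum(1 for _ in SeqIO.parse(str(path), "fasta"))
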