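"""Synthetic reference taxonomies with planted taxon-specific gene pools.

The generator emulates the pan-genome structure the classification method
relies on: every node of a six-rank taxonomy tree owns a disjoint pool of
node-specific NOGs, all genomes share draws from a universal core pool, and
a genome is the union of samples from each of its six ancestor-node pools,
a core sample, and (optionally) cross-lineage noise NOGs drawn uniformly
from other nodes' pools — the adversarial contamination for a unique-set
method.  The planted pools are returned as ground truth so database
construction and classification can be checked against the generator.

What this does *not* emulate: real genome sizes, sequence-level evolution,
horizontal transfer structure, or the uneven taxon sampling of public
genome collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import NogCatalog
from .core import (
    RANKS,
    GenomeProfile,
    Lineage,
    Rank,
    ReferenceTaxonomy,
    TaxonKey,
)

__all__ = ["SimConfig", "SimulatedWorld", "AmbiguousQuery", "simulate", "make_query", "make_ambiguous_pair"]

#: Local label prefixes per rank (same local names recur under different
#: parents, deliberately exercising lineage-prefix taxon identity).
_RANK_LETTER = ("p", "c", "o", "f", "g", "s")


@dataclass(frozen=True)
class SimConfig:
    """Shape and sampling parameters of a synthetic taxonomy.

    children_per_rank
        Fan-out at each rank, phylum first: (4, 3, 2, 2, 2, 2) gives 4 phyla
        and 192 species.
    genomes_per_species
        Reference genomes sampled per species leaf.
    pool_size_per_node
        Node-specific NOGs owned by every taxonomy node (all pools disjoint).
    core_pool_size
        Universal core NOGs shared across the whole tree.
    genes_per_genome
        Nominal gene total per genome (the NOG set is usually smaller; the
        default clears the 475-gene reference filter).
    sample_frac_specific
        Fraction of each ancestor-node pool sampled into a genome.
    core_sample_frac
        Fraction of the core pool sampled into a genome.
    noise_rate
        Cross-lineage noise: noise NOGs are added at this fraction of the
        genome's signal NOG count, drawn uniformly from other lineages' pools.
    s_enrichment
        Weight multiplier for the unknown-function category S when assigning
        categories to node-pool NOGs (plants a qualitative enrichment signal
        in taxon-specific sets).
    """

    children_per_rank: Tuple[int, ...] = (4, 3, 2, 2, 2, 2)
    genomes_per_species: int = 3
    pool_size_per_node: int = 20
    core_pool_size: int = 200
    genes_per_genome: int = 600
    sample_frac_specific: float = 1.0
    core_sample_frac: float = 0.9
    noise_rate: float = 0.0
    s_enrichment: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.children_per_rank) != len(RANKS):
            raise ValueError("children_per_rank needs one entry per rank")
        if any(c < 1 for c in self.children_per_rank):
            raise ValueError("children_per_rank entries must be >= 1")
        for name in ("genomes_per_species", "pool_size_per_node", "core_pool_size", "genes_per_genome"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.sample_frac_specific <= 1.0:
            raise ValueError("sample_frac_specific must be in (0, 1]")
        if not 0.0 <= self.core_sample_frac <= 1.0:
            raise ValueError("core_sample_frac must be in [0, 1]")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must be in [0, 1)")


@dataclass
class SimulatedWorld:
    """Ground truth of a simulated taxonomy: the planted pools and catalog."""

    cfg: SimConfig
    pools: Dict[TaxonKey, FrozenSet[str]]
    core_pool: FrozenSet[str]
    catalog: NogCatalog
    species_lineages: List[Lineage]

    def lineage_pool_nogs(self, lineage: Lineage) -> FrozenSet[str]:
        """Union of the node pools along a lineage's known ranks."""
        nogs: set = set()
        for rank in RANKS:
            if lineage.known_at(rank):
                nogs |= self.pools[lineage.key(rank)]
        return frozenset(nogs)


@dataclass
class AmbiguousQuery:
    """A query engineered to trigger (or probe) the phylum-rank tie branch."""

    profile: GenomeProfile
    truth: Lineage
    best_phylum: TaxonKey
    runner_phylum: TaxonKey
    best_count: int
    runner_count: int


def _species_keys(cfg: SimConfig) -> List[TaxonKey]:
    keys: List[TaxonKey] = [()]
    for rank, fanout in zip(RANKS, cfg.children_per_rank):
        letter = _RANK_LETTER[rank]
        keys = [key + (f"{letter}{i + 1}",) for key in keys for i in range(fanout)]
    return keys


def _assign_categories(
    rng: np.random.Generator, nogs: Sequence[str], s_weight: float
) -> Dict[str, str]:
    from .funcat import COG_CATEGORIES

    letters = list(COG_CATEGORIES)
    weights = np.array([s_weight if c == "S" else 1.0 for c in letters], dtype=float)
    weights /= weights.sum()
    categories = {}
    for nog in nogs:
        k = int(rng.integers(1, 3))  # 1 or 2 letters per NOG
        chosen = rng.choice(letters, size=k, replace=False, p=weights)
        categories[nog] = "".join(sorted(chosen))
    return categories


def _sample(rng: np.random.Generator, items: Sequence[str], k: int) -> List[str]:
    if k >= len(items):
        return list(items)
    idx = rng.choice(len(items), size=k, replace=False)
    return [items[i] for i in sorted(idx)]


def _sample_genome(
    rng: np.random.Generator,
    world: SimulatedWorld,
    lineage: Lineage,
    genome_id: str,
    sample_frac: float,
    drop_frac: float,
    noise_rate: float,
) -> GenomeProfile:
    cfg = world.cfg
    specific: set = set()
    for rank in RANKS:
        if not lineage.known_at(rank):
            break
        pool = sorted(world.pools[lineage.key(rank)])
        k = int(round(sample_frac * len(pool)))
        if k > len(pool):
            raise ValueError("requested sample exceeds pool size")
        specific.update(_sample(rng, pool, k))
    if drop_frac > 0.0 and specific:
        keep = int(round((1.0 - drop_frac) * len(specific)))
        specific = set(_sample(rng, sorted(specific), keep))
    core = _sample(
        rng, sorted(world.core_pool), int(round(cfg.core_sample_frac * len(world.core_pool)))
    )
    signal = specific | set(core)
    nogs = set(signal)
    if noise_rate > 0.0:
        own = world.lineage_pool_nogs(lineage)
        foreign = sorted(
            set().union(*world.pools.values()) - own
        )
        n_noise = int(round(noise_rate * len(signal)))
        nogs |= set(_sample(rng, foreign, n_noise))
    gene_count = max(cfg.genes_per_genome, len(nogs))
    return GenomeProfile(
        genome_id=genome_id,
        nogs=frozenset(nogs),
        gene_count=gene_count,
        assigned_fraction=len(nogs) / gene_count if gene_count else 0.0,
    )


def simulate(cfg: SimConfig) -> Tuple[ReferenceTaxonomy, SimulatedWorld]:
    """Generate a reference taxonomy plus its generating ground truth.

    Deterministic given ``cfg.seed``: the same config always yields the same
    genomes, pools and category catalog.
    """
    rng = np.random.default_rng(cfg.seed)
    species = _species_keys(cfg)

    # disjoint node pools: every prefix of every species key is a node
    nodes: List[TaxonKey] = sorted(
        {key[: depth + 1] for key in species for depth in range(len(RANKS))}
    )
    pools: Dict[TaxonKey, FrozenSet[str]] = {
        node: frozenset(
            f"NOG_{'.'.join(node)}_{i:04d}" for i in range(cfg.pool_size_per_node)
        )
        for node in nodes
    }
    core_pool = frozenset(f"NOG_core_{i:05d}" for i in range(cfg.core_pool_size))

    all_nogs = sorted(set().union(*pools.values()))
    categories = _assign_categories(rng, all_nogs, cfg.s_enrichment)
    categories.update(_assign_categories(rng, sorted(core_pool), 1.0))
    catalog = NogCatalog(
        member_to_nog={f"prot_{nog}": nog for nog in list(all_nogs) + sorted(core_pool)},
        nog_to_categories=categories,
    )

    lineages = [Lineage(key) for key in species]
    world = SimulatedWorld(
        cfg=cfg,
        pools=pools,
        core_pool=core_pool,
        catalog=catalog,
        species_lineages=lineages,
    )

    profiles: List[GenomeProfile] = []
    lineage_of: Dict[str, Lineage] = {}
    for lineage in lineages:
        stem = ".".join(lineage.key(Rank.SPECIES))
        for g in range(cfg.genomes_per_species):
            genome_id = f"{stem}_g{g}"
            profiles.append(
                _sample_genome(
                    rng,
                    world,
                    lineage,
                    genome_id,
                    sample_frac=cfg.sample_frac_specific,
                    drop_frac=0.0,
                    noise_rate=cfg.noise_rate,
                )
            )
            lineage_of[genome_id] = lineage
    ref = ReferenceTaxonomy(profiles=profiles, lineage_of=lineage_of)
    return ref, world


def make_query(
    world: SimulatedWorld,
    lineage: Lineage,
    drop_frac: float = 0.0,
    seed: int = 0,
    noise_rate: Optional[float] = None,
) -> GenomeProfile:
    """A novel genome from ``lineage`` with a fraction of specific NOGs dropped.

    ``drop_frac`` removes that share of the sampled node-specific NOGs (the
    degradation knob for hold-out experiments); noise defaults to the world's
    configured rate.  Deterministic given (world seed, seed).
    """
    for rank in RANKS:
        if lineage.known_at(rank) and lineage.key(rank) not in world.pools:
            raise ValueError(f"lineage not in the simulated tree: {lineage}")
    if not 0.0 <= drop_frac <= 1.0:
        raise ValueError("drop_frac must be in [0, 1]")
    rng = np.random.default_rng([world.cfg.seed, 1_000_003, seed])
    rate = world.cfg.noise_rate if noise_rate is None else noise_rate
    return _sample_genome(
        rng,
        world,
        lineage,
        genome_id=f"query_{'.'.join(k for k in lineage.labels if k)}_{seed}",
        sample_frac=world.cfg.sample_frac_specific,
        drop_frac=drop_frac,
        noise_rate=rate,
    )


def make_ambiguous_pair(
    world: SimulatedWorld,
    second_best_ratio: float = 0.4,
    best_count: int = 10,
    class_evidence: int = 4,
    seed: int = 0,
) -> AmbiguousQuery:
    """Engineer a query whose top-two phylum counts sit at a chosen ratio.

    The query carries ``best_count`` NOGs specific to the first phylum
    (``class_evidence`` of them from its first class's pool, the rest from
    the phylum's own pool) and ``round(ratio * best_count)`` NOGs from a
    second phylum's own pool with no class-level evidence — so a triggered
    look-ahead resolves to the first phylum via its class counts.
    """
    phyla = sorted({key[:1] for key in world.pools})
    if len(phyla) < 2:
        raise ValueError("need at least two phyla")
    best_phylum, runner_phylum = phyla[0], phyla[1]
    first_class = sorted(k for k in world.pools if len(k) == 2 and k[:1] == best_phylum)[0]
    runner_count = int(round(second_best_ratio * best_count))
    rng = np.random.default_rng([world.cfg.seed, 2_000_003, seed])
    phylum_evidence = best_count - class_evidence
    for need, pool in (
        (phylum_evidence, best_phylum),
        (class_evidence, first_class),
        (runner_count, runner_phylum),
    ):
        if need > len(world.pools[pool]):
            raise ValueError(f"pool {pool} smaller than requested evidence {need}")
    nogs = set(_sample(rng, sorted(world.pools[best_phylum]), phylum_evidence))
    nogs |= set(_sample(rng, sorted(world.pools[first_class]), class_evidence))
    nogs |= set(_sample(rng, sorted(world.pools[runner_phylum]), runner_count))
    profile = GenomeProfile(
        genome_id=f"ambiguous_{second_best_ratio}_{seed}",
        nogs=frozenset(nogs),
        gene_count=max(world.cfg.genes_per_genome, len(nogs)),
        assigned_fraction=1.0,
    )
    truth = Lineage.from_labels(*first_class)
    return AmbiguousQuery(
        profile=profile,
        truth=truth,
        best_phylum=best_phylum,
        runner_phylum=runner_phylum,
        best_count=best_count,
        runner_count=runner_count,
    )
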