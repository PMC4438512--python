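"""Independent brute-force oracles the implementation is checked against."""

from math import comb

from taxonog.annotation import filter_genomes
from taxonog.core import RANKS


def occurrence_scan_unique(ref, rank, min_genes=0):
    """Unique sets by per-NOG occurrence scan: for each NOG list every taxon
    at the rank containing it; the NOG is unique iff that list has one entry."""
    kept, _ = filter_genomes(ref.profiles, min_genes=min_genes)
    containing = {}
    for p in kept:
        lineage = ref.lineage_of[p.genome_id]
        if not lineage.known_at(rank):
            continue
        key = lineage.key(rank)
        for nog in p.nogs:
            containing.setdefault(nog, set()).add(key)
    unique = {}
    for p in kept:
        lineage = ref.lineage_of[p.genome_id]
        if lineage.known_at(rank):
            unique.setdefault(lineage.key(rank), set())
    for nog, keys in containing.items():
        if len(keys) == 1:
            unique[next(iter(keys))].add(nog)
    return {k: frozenset(v) for k, v in unique.items()}


def hypergeom_two_sided(k, n, K, N):
    """Exact two-sided hypergeometric p by enumeration: sum the probabilities
    of all draw outcomes no more probable than the observed one."""
    denom = comb(N, n)
    pmf = {
        i: comb(K, i) * comb(N - K, n - i) / denom
        for i in range(max(0, n - (N - K)), min(n, K) + 1)
    }
    observed = pmf[k]
    return sum(p for p in pmf.values() if p <= observed * (1 + 1e-12))
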