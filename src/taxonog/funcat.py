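"""Functional-category composition of taxon-specific NOG sets.

Orthologous groups carry one or more single-letter COG functional category
codes (U = intracellular trafficking and secretion, S = function unknown,
...).  This module profiles a NOG set over the 23 categories, compares the
category proportions of a taxon's unique set against its total set as an
overabundance ratio, and tests enrichment with an exact hypergeometric
(Fisher) formulation treating the unique set as a draw from the total set.

A NOG annotated with k category letters contributes 1/k to each of them
(fractional attribution), which keeps proportions normalized; a full-count
mode (each letter counts 1) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional

import pandas as pd
from scipy.stats import fisher_exact

from .annotation import NogCatalog
from .core import UniqueNogDB, Rank

__all__ = [
    "COG_CATEGORIES",
    "CategoryProfile",
    "category_profile",
    "overabundance",
    "flag_abundant",
    "enrichment_test",
    "phylum_category_table",
]

#: The 23 single-letter functional categories used for bacterial NOGs
#: (the classical COG scheme minus the chiefly eukaryotic A and B classes).
COG_CATEGORIES = "JKLDYVTMNZWUOCGEFHIPQRS"


@dataclass
class CategoryProfile:
    """Category composition of one NOG set.

    ``fractional`` holds 1/k-weighted counts (they sum to ``set_size``);
    ``counts`` holds plain NOG counts per letter (a NOG with several letters
    counts once in each).  ``set_size`` is the number of categorized NOGs;
    uncategorized NOGs are tallied separately and excluded from proportions.
    """

    fractional: Dict[str, float] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)
    set_size: int = 0
    n_uncategorized: int = 0

    def proportions(self, mode: str = "fractional") -> Dict[str, float]:
        """Per-category proportions; empty when the set has no categorized NOG."""
        if self.set_size == 0:
            return {}
        if mode == "fractional":
            return {c: v / self.set_size for c, v in self.fractional.items()}
        if mode == "count-each":
            denom = sum(self.counts.values())
            return {c: v / denom for c, v in self.counts.items()}
        raise ValueError(f"unknown attribution mode: {mode!r}")


def category_profile(nogs: Iterable[str], catalog: NogCatalog) -> CategoryProfile:
    """Profile a NOG set over the functional categories in ``catalog``."""
    profile = CategoryProfile()
    for nog in nogs:
        letters = catalog.nog_to_categories.get(nog, "")
        if not letters:
            profile.n_uncategorized += 1
            continue
        profile.set_size += 1
        weight = 1.0 / len(letters)
        for letter in letters:
            profile.fractional[letter] = profile.fractional.get(letter, 0.0) + weight
            profile.counts[letter] = profile.counts.get(letter, 0) + 1
    return profile


def overabundance(
    unique_profile: CategoryProfile,
    total_profile: CategoryProfile,
    mode: str = "fractional",
) -> Dict[str, Optional[float]]:
    """Ratio of a category's proportion in the unique set to the total set.

    A ratio above 1 means the category is overrepresented among the
    taxon-specific NOGs.  Categories with zero total proportion are reported
    as ``None`` (undefined) rather than infinite.
    """
    props_total = total_profile.proportions(mode)
    props_unique = unique_profile.proportions(mode)
    ratios: Dict[str, Optional[float]] = {}
    for category in sorted(set(props_total) | set(props_unique)):
        p_total = props_total.get(category, 0.0)
        if p_total == 0.0:
            ratios[category] = None
        else:
            ratios[category] = props_unique.get(category, 0.0) / p_total
    return ratios


def flag_abundant(
    ratios_per_taxon: Mapping[str, Mapping[str, Optional[float]]],
    threshold: float = 1.2,
) -> Dict[str, int]:
    """Per category, the number of taxa whose ratio is strictly above threshold."""
    if not ratios_per_taxon:
        raise ValueError("need ratios for at least one taxon")
    counts: Dict[str, int] = {}
    for ratios in ratios_per_taxon.values():
        for category, ratio in ratios.items():
            counts.setdefault(category, 0)
            if ratio is not None and ratio > threshold:
                counts[category] += 1
    return counts


def enrichment_test(
    unique_profile: CategoryProfile,
    total_profile: CategoryProfile,
    category: str,
) -> float:
    """Two-sided exact test for a category's enrichment in the unique set.

    The unique set (n categorized NOGs, k in the category) is modelled as a
    draw without replacement from the total set (N NOGs, K in the category),
    i.e. a hypergeometric null, assessed with Fisher's exact test on the
    2x2 table.  Degenerate tables return p = 1.0.
    """
    k = unique_profile.counts.get(category, 0)
    n = unique_profile.set_size
    K = total_profile.counts.get(category, 0)
    N = total_profile.set_size
    if k > K or n > N:
        raise ValueError("unique set must be contained in the total set")
    if N == 0 or n == 0 or K == 0 or K == N:
        return 1.0
    table = [[k, n - k], [K - k, (N - n) - (K - k)]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def phylum_category_table(
    db: UniqueNogDB,
    catalog: NogCatalog,
    rank: Rank = Rank.PHYLUM,
    mode: str = "fractional",
    abundance_threshold: float = 1.2,
) -> pd.DataFrame:
    """Per-taxon functional comparison of unique vs total NOG sets at a rank.

    One row per (taxon, category): proportions in the total and unique sets,
    the overabundance ratio, the exact-test p-value and whether the ratio
    exceeds the abundance threshold.
    """
    rows = []
    for key in db.taxa(rank):
        total_profile = category_profile(db.total_nogs(rank, key), catalog)
        unique_profile = category_profile(db.unique_nogs(rank, key), catalog)
        ratios = overabundance(unique_profile, total_profile, mode)
        props_total = total_profile.proportions(mode)
        props_unique = unique_profile.proportions(mode)
        for category in sorted(ratios):
            ratio = ratios[category]
            rows.append(
                {
                    "rank": rank.label,
                    "taxon_key": "|".join(key),
                    "taxon": key[-1],
                    "category": category,
                    "prop_total": props_total.get(category, 0.0),
                    "prop_unique": props_unique.get(category, 0.0),
                    "ratio": float("nan") if ratio is None else ratio,
                    "p_value": enrichment_test(unique_profile, total_profile, category),
                    "abundant": ratio is not None and ratio > abundance_threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "taxon_key",
            "taxon",
            "category",
            "prop_total",
            "prop_unique",
            "ratio",
            "p_value",
            "abundant",
        ],
    )
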