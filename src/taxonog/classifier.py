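"""Hierarchical taxonomic classification over the unique-NOG database.

A query genome descends the rank hierarchy phylum -> species.  At each rank
the candidate taxa (children of the taxon chosen at the previous rank; all
phyla at the top) are scored by how many of their taxon-specific NOGs the
query contains, and the maximum-match taxon wins.

When the runner-up's match count reaches >= 30% of the best count the
decision is ambiguous and a look-ahead fires: the children of *both*
candidates are scored at the next rank, the child with the maximum matches
wins, and its parent becomes the choice at the current rank.  Look-ahead
chains may recurse while candidates stay tied (capped, and never below the
order rank for chains starting at phylum).  If look-ahead finds no evidence
the higher raw count stands.  A rank with fewer than ``min_matches``
specific-NOG matches is UNCLASSIFIED, as is everything below it.

The species assignment names the closest known species by gene content; it
is advisory rather than a confident species identification.
"""

from __future__ import annotations

import logging
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .annotation import MIN_GENES_DEFAULT
from .core import (
    RANKS,
    UNCLASSIFIED,
    ClassificationResult,
    ClassifierConfig,
    GenomeProfile,
    Lineage,
    Rank,
    RankDecision,
    ReferenceTaxonomy,
    TaxonKey,
    UniqueNogDB,
)
from .db import build_db

__all__ = [
    "match_counts",
    "resolve_rank",
    "classify",
    "evaluate",
    "UniqueNogTaxonomyClassifier",
]

logger = logging.getLogger(__name__)


def match_counts(
    query_nogs: FrozenSet[str] | set,
    db: UniqueNogDB,
    rank: Rank,
    restrict_to: Optional[TaxonKey] = None,
) -> List[Tuple[TaxonKey, int]]:
    """Score every candidate taxon at ``rank`` against the query's NOG set.

    The score of a taxon is the size of the intersection between the query
    NOGs and the taxon's unique-NOG set.  With ``restrict_to`` only children
    of that taxon are scored.  Sorted by count descending, then taxon key
    ascending, so the order is deterministic.
    """
    keys = (
        db.children(rank, restrict_to) if restrict_to is not None else db.taxa(rank)
    )
    counts = [(key, len(query_nogs & db.unique_nogs(rank, key))) for key in keys]
    counts.sort(key=lambda item: (-item[1], item[0]))
    return counts


def _lookahead_winner(
    query_nogs: FrozenSet[str],
    db: UniqueNogDB,
    rank: Rank,
    parents: Sequence[TaxonKey],
    cfg: ClassifierConfig,
    deepest_rank: Rank,
) -> Tuple[Optional[TaxonKey], Optional[Rank], Optional[RankDecision]]:
    """Score the children of the tied ``parents`` at ``rank`` to break the tie.

    Returns (winning child key, rank that resolved, trace decision); the
    winner is ``None`` when no child shows any specific-NOG evidence.
    Recurses while the top two children are themselves tied, down to
    ``deepest_rank`` at most.
    """
    counts: List[Tuple[TaxonKey, int]] = []
    for parent in parents:
        counts.extend(match_counts(query_nogs, db, rank, restrict_to=parent))
    counts.sort(key=lambda item: (-item[1], item[0]))
    trace = RankDecision(rank=rank, candidates=counts, chosen=None)
    if not counts or counts[0][1] == 0:
        return None, None, trace
    (top_key, top_count) = counts[0]
    (second_key, second_count) = counts[1] if len(counts) > 1 else (None, 0)
    trace.match_count = top_count
    trace.runner_up = second_key
    trace.runner_up_count = second_count
    still_tied = (
        second_key is not None
        and second_count / top_count >= cfg.tie_threshold
        and second_key[: len(top_key) - 1] != top_key[:-1]  # different parents
    )
    if still_tied and rank < deepest_rank:
        winner, resolved_by, sub_trace = _lookahead_winner(
            query_nogs,
            db,
            Rank(rank + 1),
            [top_key, second_key],
            cfg,
            deepest_rank,
        )
        trace.lookahead_trace = sub_trace
        if winner is not None:
            # map the deeper winner back to whichever of our candidates it extends
            chosen = top_key if winner[: len(top_key)] == top_key else second_key
            trace.chosen = chosen
            trace.tie_triggered = True
            trace.resolved_by = resolved_by
            return chosen, resolved_by, trace
    if second_count == top_count and second_key is not None:
        logger.warning(
            "exact %d-vs-%d tie at %s between %s and %s; choosing lexicographically",
            top_count,
            second_count,
            rank.label,
            top_key,
            second_key,
        )
    trace.chosen = top_key
    return top_key, rank, trace


def resolve_rank(
    query_nogs: FrozenSet[str] | set,
    db: UniqueNogDB,
    rank: Rank,
    parent: Optional[TaxonKey],
    cfg: Optional[ClassifierConfig] = None,
) -> RankDecision:
    """Decide the taxon at one rank, applying the look-ahead tie rule."""
    cfg = cfg or ClassifierConfig()
    query_nogs = frozenset(query_nogs)
    counts = match_counts(query_nogs, db, rank, restrict_to=parent)
    decision = RankDecision(rank=rank, candidates=counts, chosen=None)
    if not counts or counts[0][1] < cfg.min_matches:
        return decision
    (best_key, best_count) = counts[0]
    (second_key, second_count) = counts[1] if len(counts) > 1 else (None, 0)
    decision.runner_up = second_key
    decision.runner_up_count = second_count
    tie = (
        second_key is not None
        and second_count / best_count >= cfg.tie_threshold
        and rank <= cfg.tie_rank_limit
        and rank < Rank.SPECIES
    )
    if tie:
        decision.tie_triggered = True
        # a chain starting at phylum or class resolves within class/order;
        # elsewhere it descends at most lookahead_depth ranks
        if rank <= Rank.CLASS:
            deepest = Rank(max(rank + 1, min(rank + cfg.lookahead_depth, Rank.ORDER)))
        else:
            deepest = Rank(min(rank + cfg.lookahead_depth, Rank.SPECIES))
        winner, resolved_by, trace = _lookahead_winner(
            query_nogs, db, Rank(rank + 1), [best_key, second_key], cfg, deepest
        )
        decision.lookahead_trace = trace
        if winner is not None:
            chosen = best_key if winner[: len(best_key)] == best_key else second_key
            decision.chosen = chosen
            decision.resolved_by = resolved_by
            decision.match_count = dict(counts)[chosen]
            return decision
        # look-ahead exhausted without evidence: the raw maximum stands
    if second_key is not None and second_count == best_count:
        logger.warning(
            "exact tie at %s between %s and %s (count %d); "
            "choosing lexicographically smaller key",
            rank.label,
            best_key,
            second_key,
            best_count,
        )
    decision.chosen = best_key
    decision.match_count = best_count
    return decision


def classify(
    query: GenomeProfile,
    db: UniqueNogDB,
    cfg: Optional[ClassifierConfig] = None,
) -> ClassificationResult:
    """Assign a full lineage to a query genome by descending the rank tree."""
    cfg = cfg or ClassifierConfig()
    if not query.nogs:
        logger.warning("query %s has an empty NOG set", query.genome_id)
    decisions: Dict[Rank, RankDecision] = {}
    parent: Optional[TaxonKey] = None
    unclassified = False
    for rank in RANKS:
        if unclassified or (not query.nogs):
            decisions[rank] = RankDecision(rank=rank, candidates=[], chosen=None)
            continue
        decision = resolve_rank(query.nogs, db, rank, parent, cfg)
        decisions[rank] = decision
        if decision.chosen is None:
            unclassified = True
        else:
            parent = decision.chosen
    return ClassificationResult(genome_id=query.genome_id, decisions=decisions)


def evaluate(
    queries: Sequence[GenomeProfile],
    truths: Sequence[Lineage],
    db: UniqueNogDB,
    cfg: Optional[ClassifierConfig] = None,
) -> pd.DataFrame:
    """Per-rank accuracy of classification against known truth lineages.

    A query counts toward a rank only where its truth lineage is known there;
    UNCLASSIFIED outcomes are tallied separately, not as errors-by-name.
    """
    if len(queries) != len(truths):
        raise ValueError("queries and truths differ in length")
    results = [classify(q, db, cfg) for q in queries]
    rows = []
    for rank in RANKS:
        n_known = n_correct = n_unclassified = 0
        for result, truth in zip(results, truths):
            if not truth.known_at(rank):
                continue
            n_known += 1
            assigned = result.assigned(rank)
            if assigned is None:
                n_unclassified += 1
            elif assigned == truth.key(rank):
                n_correct += 1
        rows.append(
            {
                "rank": rank.label,
                "n": n_known,
                "n_correct": n_correct,
                "n_unclassified": n_unclassified,
                "accuracy": n_correct / n_known if n_known else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["rank", "n", "n_correct", "n_unclassified", "accuracy"])


class UniqueNogTaxonomyClassifier(BaseEstimator):
    """Taxonomic classifier over rank-wise taxon-specific orthologous groups.

    ``fit`` pools the reference genomes' NOG sets per taxon at each of the six
    ranks and extracts the taxon-specific sets (present in exactly one taxon
    at that rank); ``predict`` assigns lineages by hierarchical maximum-match
    descent with the look-ahead disambiguation rule.

    Parameters
    ----------
    min_genes : int, default=475
        Reference genomes with fewer genes are excluded from the database
        (the smallest known bacterial gene complement).
    tie_threshold : float, default=0.30
        Runner-up/best match-count ratio at which the look-ahead fires.
    lookahead_depth : int, default=1
        Ranks a look-ahead chain may descend while candidates stay tied.
    min_matches : int, default=1
        Specific-NOG matches required to assign a rank at all.
    tie_rank_limit : {"class", "genus"} or Rank, default="genus"
        Deepest rank at which the tie rule applies.  ``"genus"`` applies it
        uniformly; ``"class"`` restricts it to the phylum and class decisions.

    Attributes
    ----------
    db_ : UniqueNogDB
        The built per-rank unique/total NOG database.
    n_genomes_ : int
        Reference genomes retained after the gene-count filter.

    Examples
    --------
    >>> clf = UniqueNogTaxonomyClassifier(min_genes=1)
    >>> clf.fit(profiles, lineages).predict(queries)  # doctest: +SKIP
    """

    def __init__(
        self,
        min_genes: int = MIN_GENES_DEFAULT,
        tie_threshold: float = 0.30,
        lookahead_depth: int = 1,
        min_matches: int = 1,
        tie_rank_limit: str | Rank = "genus",
    ):
        self.min_genes = min_genes
        self.tie_threshold = tie_threshold
        self.lookahead_depth = lookahead_depth
        self.min_matches = min_matches
        self.tie_rank_limit = tie_rank_limit

    def _config(self) -> ClassifierConfig:
        limit = (
            self.tie_rank_limit
            if isinstance(self.tie_rank_limit, Rank)
            else Rank.from_label(str(self.tie_rank_limit))
        )
        return ClassifierConfig(
            tie_threshold=self.tie_threshold,
            lookahead_depth=self.lookahead_depth,
            min_matches=self.min_matches,
            tie_rank_limit=limit,
        )

    def fit(
        self, X: Sequence[GenomeProfile] | ReferenceTaxonomy, y: Optional[Sequence[Lineage]] = None
    ) -> "UniqueNogTaxonomyClassifier":
        """Build the unique-NOG database from reference profiles and lineages.

        ``X`` may be a ReferenceTaxonomy (then ``y`` is ignored) or a sequence
        of GenomeProfile with ``y`` the matching sequence of Lineage.
        """
        self._config()  # validate parameters early
        if isinstance(X, ReferenceTaxonomy):
            ref = X
        else:
            profiles = list(X)
            if y is None or len(list(y)) != len(profiles):
                raise ValueError("y must provide one Lineage per profile")
            ref = ReferenceTaxonomy(
                profiles=profiles,
                lineage_of={p.genome_id: lin for p, lin in zip(profiles, y)},
            )
        self.db_ = build_db(ref, min_genes=self.min_genes)
        self.n_genomes_ = int(self.db_.meta["source_genomes"])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "db_"):
            raise RuntimeError("this classifier is not fitted yet; call fit first")

    def classify(self, query: GenomeProfile) -> ClassificationResult:
        """Full per-rank result (match counts, ties, look-ahead traces)."""
        self._check_fitted()
        return classify(query, self.db_, self._config())

    def predict(self, X: Sequence[GenomeProfile]) -> np.ndarray:
        """Assigned lineages as an (n_queries, 6) array of labels.

        Unassigned ranks carry the UNCLASSIFIED sentinel.
        """
        self._check_fitted()
        return np.array([self.classify(q).lineage_labels for q in X], dtype=object)

    def predict_result(self, X: Sequence[GenomeProfile]) -> List[ClassificationResult]:
        self._check_fitted()
        return [self.classify(q) for q in X]

    def score(self, X: Sequence[GenomeProfile], y: Sequence[Lineage]) -> float:
        """Mean per-rank accuracy over the ranks known in each truth lineage."""
        self._check_fitted()
        table = evaluate(list(X), list(y), self.db_, self._config())
        known = table[table["n"] > 0]
        if known.empty:
            return float("nan")
        return float(known["n_correct"].sum() / known["n"].sum())

    def evaluate(self, X: Sequence[GenomeProfile], y: Sequence[Lineage]) -> pd.DataFrame:
        self._check_fitted()
        return evaluate(list(X), list(y), self.db_, self._config())
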