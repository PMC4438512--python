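"""Hierarchical descent, the look-ahead tie rule, and the sklearn estimator."""

import numpy as np
import pytest
from sklearn.base import clone

from taxonog import (
    ClassifierConfig,
    GenomeProfile,
    Lineage,
    ReferenceTaxonomy,
    UNCLASSIFIED,
    UniqueNogTaxonomyClassifier,
    build_db,
    classify,
    evaluate,
    match_counts,
    resolve_rank,
)
from taxonog.core import RANKS, Rank
from tests.conftest import profile


@pytest.fixture
def two_phylum_db():
    """Two phyla with class structure, all sets hand-checkable.

    Phylum A owns a1..a5 (a4, a5 via its classes c1/c2); phylum B owns b1..b5.
    """
    ref = ReferenceTaxonomy(
        [
            profile("GA1", {"a1", "a2", "a4"}),
            profile("GA2", {"a1", "a3", "a5"}),
            profile("GB1", {"b1", "b2", "b3"}),
            profile("GB2", {"b1", "b4", "b5"}),
        ],
        {
            "GA1": Lineage.from_labels("A", "c1"),
            "GA2": Lineage.from_labels("A", "c2"),
            "GB1": Lineage.from_labels("B", "c1"),
            "GB2": Lineage.from_labels("B", "c2"),
        },
    )
    return build_db(ref, min_genes=1)


class TestMatchCounts:
    def test_hand_intersections_sorted_descending(self, two_phylum_db):
        counts = match_counts({"a1", "a2", "b1"}, two_phylum_db, Rank.PHYLUM)
        assert counts == [(("A",), 2), (("B",), 1)]

    def test_disjoint_query_scores_zero_everywhere(self, two_phylum_db):
        counts = match_counts({"zz"}, two_phylum_db, Rank.PHYLUM)
        assert all(c == 0 for _, c in counts)

    def test_query_equal_to_unique_set_scores_its_size(self, two_phylum_db):
        unique_a = two_phylum_db.unique_nogs(Rank.PHYLUM, ("A",))
        counts = match_counts(unique_a, two_phylum_db, Rank.PHYLUM)
        assert counts[0] == (("A",), len(unique_a))

    def test_restrict_to_scores_only_children(self, two_phylum_db):
        counts = match_counts({"a4", "b1"}, two_phylum_db, Rank.CLASS, restrict_to=("A",))
        assert [k for k, _ in counts] == [("A", "c1"), ("A", "c2")]


class TestResolveRank:
    def test_clear_winner_below_threshold_skips_lookahead(self, two_phylum_db):
        # counts (A: 5 of a1..a5, B: 1) -> ratio 0.2 < 0.30
        d = resolve_rank({"a1", "a2", "a3", "a4", "a5", "b1"}, two_phylum_db, Rank.PHYLUM, None)
        assert d.chosen == ("A",) and not d.tie_triggered
        assert (d.match_count, d.runner_up_count) == (5, 1)

    def test_ratio_at_threshold_triggers_lookahead_resolved_by_class(self, two_phylum_db):
        # counts (A:2 via a1,a4), (B:1 via b1): 1/2 >= 0.30; class-level
        # evidence a4 sits in A/c1 so the look-ahead resolves to A via c1
        d = resolve_rank({"a1", "a4", "b1"}, two_phylum_db, Rank.PHYLUM, None)
        assert d.tie_triggered
        assert d.chosen == ("A",)
        assert d.resolved_by is Rank.CLASS
        assert d.lookahead_trace.chosen == ("A", "c1")

    def test_lookahead_can_overturn_the_raw_maximum(self, two_phylum_db):
        # B leads 3:2 at phylum but its class evidence is split 1/1 while
        # A concentrates 2 matches in one class, so the look-ahead picks A
        d = resolve_rank({"a2", "a4", "b1", "b2", "b4"}, two_phylum_db, Rank.PHYLUM, None)
        assert d.tie_triggered and d.chosen == ("A",)
        assert d.lookahead_trace.chosen == ("A", "c1")

    def test_all_zero_counts_is_unclassified(self, two_phylum_db):
        d = resolve_rank({"zz"}, two_phylum_db, Rank.PHYLUM, None)
        assert d.chosen is None

    def test_exhausted_lookahead_falls_back_to_raw_maximum(self, two_phylum_db):
        # a1 and b1 are phylum-level only: no class evidence on either side,
        # so the exhausted look-ahead falls back to the raw maximum (an exact
        # 1-1 tie, broken toward the lexicographically smaller key)
        d = resolve_rank({"a1", "b1"}, two_phylum_db, Rank.PHYLUM, None)
        assert d.tie_triggered
        assert d.chosen == ("A",)
        assert d.resolved_by is None

    def test_tie_rule_can_be_restricted_to_upper_ranks(self, two_phylum_db):
        cfg = ClassifierConfig(tie_rank_limit=Rank.CLASS)
        d = resolve_rank({"a1", "a4", "b1"}, two_phylum_db, Rank.PHYLUM, None, cfg)
        assert d.tie_triggered  # phylum is within the limit
        d_genus = resolve_rank({"a1", "a4", "b1"}, two_phylum_db, Rank.PHYLUM, None,
                               ClassifierConfig(tie_threshold=0.9))
        assert not d_genus.tie_triggered  # higher threshold, no tie


class TestClassify:
    def test_training_genomes_recover_their_lineage(self, tiny_world, tiny_db):
        ref, _ = tiny_world
        for p in ref.profiles[::5]:
            result = classify(p, tiny_db)
            truth = ref.lineage_of[p.genome_id]
            for rank in RANKS:
                assert result.assigned(rank) == truth.key(rank)

    def test_phylum_only_evidence_stops_below_phylum(self, two_phylum_db):
        result = classify(profile("q", {"a1"}), two_phylum_db)
        assert result.assigned(Rank.PHYLUM) == ("A",)
        assert result.assigned(Rank.CLASS) is None
        assert result.deepest_assigned is Rank.PHYLUM
        # once UNCLASSIFIED, everything deeper stays UNCLASSIFIED
        assert result.lineage_labels[1:] == (UNCLASSIFIED,) * 5

    def test_empty_query_unclassified_at_all_ranks(self, two_phylum_db):
        result = classify(GenomeProfile("q", frozenset(), 0), two_phylum_db)
        assert result.deepest_assigned is None
        assert result.lineage_labels == (UNCLASSIFIED,) * 6

    def test_assignments_form_consistent_lineage(self, tiny_world, tiny_db):
        ref, world = tiny_world
        from taxonog import make_query

        for seed, lineage in enumerate(world.species_lineages[::7]):
            result = classify(
                make_query(world, lineage, drop_frac=0.3, seed=seed, noise_rate=0.1),
                tiny_db,
            )
            previous = None
            for rank in RANKS:
                key = result.assigned(rank)
                if previous is None and rank > Rank.PHYLUM:
                    assert key is None
                if key is not None and rank > Rank.PHYLUM:
                    assert key[:-1] == previous
                previous = key

    def test_adding_true_taxon_nogs_never_flips_a_clear_decision(self, two_phylum_db):
        base = {"a1", "a2", "a3"}
        d0 = resolve_rank(base, two_phylum_db, Rank.PHYLUM, None)
        assert d0.chosen == ("A",) and not d0.tie_triggered
        for nog in two_phylum_db.unique_nogs(Rank.PHYLUM, ("A",)):
            d1 = resolve_rank(base | {nog}, two_phylum_db, Rank.PHYLUM, None)
            assert d1.chosen == ("A",)
            assert d1.match_count >= d0.match_count


class TestEvaluate:
    def test_all_correct_gives_unit_accuracy(self, tiny_world, tiny_db):
        ref, _ = tiny_world
        queries = ref.profiles[:10]
        truths = [ref.lineage_of[p.genome_id] for p in queries]
        table = evaluate(queries, truths, tiny_db)
        assert (table["accuracy"] == 1.0).all()

    def test_unclassified_tallied_separately(self, two_phylum_db):
        table = evaluate(
            [profile("q", {"a1"})], [Lineage.from_labels("A", "c1")], two_phylum_db
        )
        by_rank = table.set_index("rank")
        assert by_rank.loc["phylum", "accuracy"] == 1.0
        assert by_rank.loc["class", "n_unclassified"] == 1
        assert by_rank.loc["class", "n_correct"] == 0


class TestEstimator:
    def test_fit_predict_recovers_lineages(self, tiny_world):
        ref, _ = tiny_world
        clf = UniqueNogTaxonomyClassifier(min_genes=1)
        lineages = [ref.lineage_of[p.genome_id] for p in ref.profiles]
        predictions = clf.fit(ref.profiles, lineages).predict(ref.profiles[:8])
        assert predictions.shape == (8, 6)
        for row, p in zip(predictions, ref.profiles[:8]):
            assert tuple(row) == ref.lineage_of[p.genome_id].labels

    def test_score_is_mean_per_rank_accuracy(self, tiny_world):
        ref, _ = tiny_world
        clf = UniqueNogTaxonomyClassifier(min_genes=1).fit(ref)
        truths = [ref.lineage_of[p.genome_id] for p in ref.profiles[:10]]
        assert clf.score(ref.profiles[:10], truths) == 1.0

    def test_get_set_params_and_clone(self):
        clf = UniqueNogTaxonomyClassifier(tie_threshold=0.4, min_matches=2)
        params = clf.get_params()
        assert params["tie_threshold"] == 0.4
        cloned = clone(clf)
        assert cloned.get_params() == params
        cloned.set_params(tie_threshold=0.2)
        assert cloned.tie_threshold == 0.2

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            UniqueNogTaxonomyClassifier().predict([])

    def test_invalid_threshold_rejected_at_fit(self, tiny_world):
        ref, _ = tiny_world
        with pytest.raises(ValueError, match="tie_threshold"):
            UniqueNogTaxonomyClassifier(tie_threshold=1.5, min_genes=1).fit(ref)

    def test_determinism_identical_inputs_identical_results(self, tiny_world):
        ref, _ = tiny_world
        lineages = [ref.lineage_of[p.genome_id] for p in ref.profiles]
        a = UniqueNogTaxonomyClassifier(min_genes=1).fit(ref.profiles, lineages)
        b = UniqueNogTaxonomyClassifier(min_genes=1).fit(
            list(reversed(ref.profiles)), list(reversed(lineages))
        )
        qa = a.predict(ref.profiles[:12])
        qb = b.predict(ref.profiles[:12])
        assert (qa == qb).all()
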