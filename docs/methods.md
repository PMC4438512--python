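# Methods

## Model

A bacterial genome is represented as the set of orthologous groups (NOGs)
its protein-coding genes map to; each NOG counts once per genome no matter
how many genes hit it. The working assumption is that every taxon, at every
rank, maintains genes found nowhere else at that rank — the taxon-specific
fraction of its pan-genome — and that this fingerprint, not the shared
core, is the informative signal for classification. Accuracy is therefore
bounded by the quality of the reference lineages: the method reproduces the
reference taxonomy, it does not adjudicate it.

**Database.** For each rank r and taxon t, the taxon-total set T_r(t) is
the union of member genomes' NOG sets, and the unique set U_r(t) removes
every NOG present in any *other* taxon at rank r (global subtraction, not
sibling-only, at every rank including species). With fully classified
references this nests automatically: a class-unique NOG occurs in only one
class, hence only one phylum. Reference genomes may be partially
classified; they contribute at the ranks their lineage covers and are
skipped deeper. Because a genome skipped at rank r can hide a conflict that
the global subtraction at r never sees, unique sets are additionally
intersected top-down with the parent taxon's unique set. On fully
classified references this intersection is a no-op; otherwise it restores
the hierarchy invariants (within-rank disjointness, unique ⊆ total,
child-unique ⊆ parent-unique) that the classifier and its reports rely on.

**Classification.** Descent from phylum to species; at each rank only the
children of the previous choice are scored by |query ∩ U_r(t)|, so
assignments always form a consistent lineage. Ties are governed by two
rules:

- *Look-ahead (≥30%)*: if the runner-up's count is ≥ `tie_threshold`
  (default 0.30) of the best count, the children of both candidates are
  scored at the next rank and the best child's parent wins. The chain may
  recurse while candidates stay tied, up to `lookahead_depth` (default 1)
  ranks; chains starting at phylum or class never descend past order, where
  the method's decision anchors. An exhausted look-ahead (no child
  evidence) falls back to the raw maximum. The rule applies uniformly down
  to `tie_rank_limit` (default genus; set to class for the narrower
  behaviour of applying it only at the top two decisions). At species there
  are no children, so the raw maximum decides.
- *Exact ties* after all of the above break toward the lexicographically
  smaller taxon key, with a logged warning — a deterministic convention,
  not a biological claim.

A rank whose best count falls below `min_matches` (default 1) is
UNCLASSIFIED, and so is everything deeper; the species-rank answer should
be read as "closest known species by gene content".

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_genes` | 475 genes | reference inclusion floor; the smallest known bacterial gene complement, boundary inclusive |
| `tie_threshold` | 0.30 (count ratio) | runner-up/best ratio that triggers look-ahead; read as a ratio of match counts |
| `lookahead_depth` | 1 rank | tie-chain recursion depth |
| `min_matches` | 1 NOG | evidence floor per rank |
| `max_evalue` | 1e-5 | optional hit filter before best-hit selection (the alignment route states no cutoff of its own, so this is an explicit, configurable knob; set `None` to disable) |

Best-hit selection among a gene's alignment hits is by maximal bit score,
then lower e-value, then lexicographically smallest subject id — the last
two being deterministic conventions for ties.

## Functional categories

NOGs carry COG category letters; we use the 23-letter bacterial set (the
classical scheme minus the chiefly eukaryotic RNA-processing A and
chromatin B classes). A NOG with k letters contributes 1/k to each
(fractional attribution keeps proportions summing to 1); `--count-each`
gives every letter a full count instead, as a sensitivity mode, since
either convention is defensible. Uncategorized NOGs are tallied but
excluded from proportions — the unknown-function placeholder S is never
imputed. Overabundance of a category is prop(unique)/prop(total);
categories absent from the total set are reported undefined rather than
infinite. Enrichment is tested by modelling the unique set as a draw
without replacement from the total set (hypergeometric null, two-sided
Fisher exact test on the 2×2 table); degenerate tables return p = 1.

## Synthetic data

The generator emulates the pan-genome structure the method assumes: every
node of a six-rank tree owns a disjoint pool of node-specific NOGs
(default 20), all genomes sample a universal core (default 200 NOGs at 90%
coverage), and each genome is the union of samples from its six
ancestor-node pools (default fraction 1.0) plus optional cross-lineage
noise drawn uniformly from other nodes' pools — the adversarial case for a
unique-set method, since every noise gene is somebody's specific marker.
The default tree is 4×3×2×2×2×2 (192 species) with 3 genomes per species
(576 genomes), sized so a full build-classify cycle runs in seconds on one
CPU while exercising every rank; hold-out experiments use 5% noise and 20%
specific-NOG dropout on novel query genomes, a deliberately harsher regime
than re-classifying training genomes. Local taxon names repeat under
different parents (every phylum has a "c1") to keep lineage-prefix taxon
identity honest. Category letters are assigned with the unknown-function
class S weighted 1.5× in node pools, planting a qualitative enrichment
signal in taxon-specific sets.

What the generator does **not** emulate: real genome sizes and gene-count
dispersion, sequence evolution, horizontal transfer (noise is uniform, not
phylogenetically structured), shared *non-core* gene blocks between sister
taxa, and the extremely uneven taxon sampling of public collections. Green
tests on this generator therefore demonstrate correctness of the set
algebra and decision procedure under the model's own assumptions, not
field accuracy on real genome databases.

A note on functional overabundance: the ratio prop(unique)/prop(total)
only departs from 1 when the total set is dominated by shared (core)
genes. The default simulation keeps the core small for speed, which
dilutes the planted S signal; the functional-analysis checks therefore use
a core-heavy configuration (core 4000, node pools 20) that mirrors the
realistic regime where most of a taxon's gene repertoire is shared.

## Numerical and design choices

- All interchange is sorted plain TSV plus one JSON metadata sidecar;
  artifacts carry no timestamps, so identical inputs, options and seed give
  byte-identical outputs (this is asserted in the tests).
- The occurrence-scan formulation (a NOG is unique iff exactly one taxon at
  the rank contains it) is kept as an independent brute-force oracle in the
  test suite and acceptance script, never as the production path.
- Simulation randomness flows through a single numpy Generator seeded from
  the config; query generation derives per-query streams from (world seed,
  query seed) so reference and query sampling never interleave.
- `UniqueNogTaxonomyClassifier` follows scikit-learn conventions (fit /
  predict / score, `get_params`/`set_params`, trailing-underscore fitted
  attributes) so it composes with sklearn model selection; `predict`
  returns an (n, 6) object array of rank labels with an UNCLASSIFIED
  sentinel, and `score` is the mean per-rank accuracy over the ranks known
  in each truth lineage.

## Limitations

- Classification reliability degrades below genus by design: species-level
  output is the nearest known species, and novel species (no conspecific
  reference) cannot be assigned correctly at species rank.
- A query from a taxon absent from the reference is either forced into its
  nearest sampled relative or left UNCLASSIFIED; there is no explicit
  novelty detection or confidence model.
- Reads and metagenomes are out of scope; the unit of input is a complete
  genome's protein complement.
- The alignment step itself (producing the best-hit table) is external;
  the package only consumes its tabular output.
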