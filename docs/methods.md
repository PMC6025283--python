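# Methods

## The model

The pipeline treats a retrieved publication set as a sample from a
research area and asks two questions of each MeSH descriptor: *is it
noteworthy now* (the term funnel) and *what is it about* (the title
correlation). The final artifact is a sparse network whose branches are
research sub-topics; no community detection is applied — the branch
structure is a property of Pathfinder-pruned minimax graphs.

### Lifetime and Time Periods

Annual publication counts define the area's lifetime. Windows of
`window_years` (default 3) calendar years are formed backwards from
`y_last`; a window is eligible when its annual average strictly exceeds
`min_avg` (default 10 publications/year — the level at which sustained
research activity can be said to exist). Two conventions are deliberate:

- **Strict inequality.** An average of exactly 10.0 is ineligible.
- **Contiguity.** Scanning stops at the first ineligible window; an
  eligible window older than an ineligible one is discarded. The lifetime
  is a single contiguous span by definition, and the periods are
  relabelled `T_1` (oldest) to `T_N` (ending at `y_last`).

`y_last` defaults to the newest year present in the corpus; for live
retrievals the caller should pass the newest *complete* calendar year,
since a partial year deflates the final period's average. Records newer
than `y_last` are excluded from all downstream stages. A rolling-year
(non-calendar) anchoring is reserved in the configuration but not
implemented: its anchor convention is genuinely underdetermined and
guessing one would silently change every downstream count.

The publication year of a record is resolved from PubMed XML in the order:
article `PubDate/Year`, leading four-digit year of `MedlineDate`,
`DateCompleted/Year`; records resolving to none are dropped and accounted
for in the parse report. MEDLINE has no single canonical year field; this
chain prefers the publication's own date over the curation date.

### The term funnel

`C(M_i)T_n` is **document frequency**: the number of publications in `T_n`
whose heading list contains descriptor `M_i`. A descriptor repeated under
several qualifiers counts once, and qualifiers are ignored for term
identity ("Neoplasms/drug therapy" and "Neoplasms/immunology" are both
"Neoplasms") — displayed networks show bare Main Headings, and
qualifier-level counting would double-count publications. Whether
occurrence counting at heading-line granularity would change results is an
open empirical question; document frequency is the defensible default and
is stated here prominently because it is a modelling choice, not a fact of
the data.

Routine removal requires `N ≥ 2` and is refused for `N = 1`, where every
observed term is trivially present in all periods. The emerging rule uses
only the last two periods (`C(T_N) − C(T_{N−1}) > 0` and
`C(T_N) ≥ min_final_count`, default 3 ≈ once a year over a three-year
period); earlier periods influence the result only through routine
removal. Both filters are per-row predicates, so their application order
does not affect the final set.

### Title correlation

Keyword extraction is intentionally simple and fully reproducible:
lowercase, punctuation stripped, tokens from a versioned stopword list
dropped (the list ships in the package and is covered by a checksum test).
Stopwords act as phrase boundaries: every maximal run of consecutive
content tokens is emitted as a noun phrase (when ≥ 2 tokens) and each
content token as a unigram. This chunking-by-stopwords rule replaces
part-of-speech tagging; on title-style text, where nearly all content
tokens are nouns and adjectives, the two agree closely, and the rule has
no model dependency. No stemming or lemmatization is applied by default —
over-merging phrase variants would silently change the vocabulary size K.

`C(TK_k|M_i)` counts **publications** (binary per title), not token
repetitions; titles rarely repeat a term, and publication counting keeps
the matrix interpretable as co-indexing. The keyword vocabulary (K
columns) is taken from the whole retrieved corpus, while matrix rows count
final-period publications only.

Cosine similarity of profile rows gives `Sim ∈ [0, 1]`; a zero profile
(term without final-period publications, kept with a warning) has
similarity 0 to everything — no shared vocabulary, no edge. The
co-occurrence baseline stores raw integer pair counts with each term's
document frequency on the diagonal.

### Pathfinder pruning

Similarities map to dissimilarities as `d = 1 − Sim` where `Sim > 0`, and
*no edge* (`+∞`) where `Sim = 0`. Zero similarity means no evidence of
relatedness, which is different from maximal dissimilarity; mapping it to
`d = 1` would let spurious unit-weight edges enter tie unions. Baseline
co-occurrence counts are first max-normalized (by the largest off-diagonal
count) into `[0, 1]` so the same transform applies.

Minimax distances (path cost = maximum edge weight, all path lengths
admissible) are computed by Floyd–Warshall with (max, min) composition —
O(n³), well under a second at the few-hundred-node scale of emerging-term
networks; no sub-cubic fast path is implemented. An edge survives iff its
direct weight is within `1e−9` (absolute) of the minimax distance: ties
are **kept**, which is exactly what makes the retained set the union of
all minimum spanning trees rather than one arbitrary MST. The test suite
verifies this equality against two independent oracles (exhaustive simple
path enumeration, and enumeration of all spanning trees) on all complete
graphs up to six nodes. Disconnected inputs yield a pathfinder forest.
General `(q, r)` parameters are recorded on the graph for provenance but
not varied.

### Network decoration and layout

Display classes come from MeSH tree letters with C-priority: any C tree →
disease, else any D tree → chemicals-and-drugs, else other; descriptors
absent from the map are "other". The tree mapping is user-supplied (NLM
ASCII descriptor export or a two-column TSV) — the package bundles no MeSH
release, only a synthetic toy map in the tests. Layout is
Fruchterman–Reingold with a fixed documented seed (20160101); exact
geometry is non-unique and only per-seed determinism is promised.
Disconnected components are laid out independently and tiled along x.

## The synthetic-data generator

The generator emulates precisely the two structures the method exploits,
with known ground truth:

- **Trajectories.** Each planted term has an exact per-period document
  count; roles are validated up front (routine: positive everywhere;
  emerging: rising into the final period, final count ≥ 3, at least one
  zero period; transient: neither; query: planted across the whole
  corpus). Recounting the generated corpus reproduces the spec exactly.
- **Vocabulary clusters.** Each period's publications are partitioned
  into per-cluster pools plus a generic pool; a term's documents are drawn
  only from its cluster's pool, and titles are built from the cluster's
  private keyword pool (anchor keyword in every title, stopword padding
  between keywords so the extractor is exercised nontrivially). At
  `noise_rate = 0` cross-cluster profiles share no vocabulary, so
  intra-cluster cosine strictly exceeds inter-cluster cosine by
  construction; `noise_rate > 0` adds off-cluster keywords per title.

The default spec is a miniature of a single-topic retrieval: five
three-year periods ending 2016 with rising volume (34 → 144 publications
per period; the first period's annual average, 11.3, sits just above the
eligibility threshold), three routine terms, two clusters of four emerging
terms, three transient terms — small enough that the whole suite runs in
seconds, large enough that every filter has work to do. The hub fixture
adds a query term indexing *every* final-period publication, reproducing
the strong-hub pathology: under co-occurrence correlation it connects to
every node of the pruned network, under title correlation its bland
mixed-vocabulary profile earns it a few edges at most.

What the generator does **not** emulate: realistic title language (titles
are keyword bags with stopword padding), heading co-assignment structure
beyond the planted clusters, MeSH vocabulary growth over time, or
retrieval noise. Passing tests therefore demonstrate that the
implementation realizes the method's definitions and recovers planted
structure under the method's own assumptions — not that the method's
assumptions hold for real MEDLINE corpora.

## Numerical conventions

- Eligibility and the emerging rule use exact integer/rational arithmetic;
  averages are displayed at one decimal but never rounded before
  comparison.
- Cosine values are clipped to `[0, 1]` and symmetrized
  (`(S + Sᵀ)/2`) to remove float asymmetry at the 1e−16 level; the
  diagonal is set to exactly 1 for nonzero profiles, 0 for zero profiles.
- Pathfinder weight comparisons use absolute tolerance 1e−9.
- All randomness (generator, layout) flows from explicit seeds; equal
  seeds give byte-identical fixture files and GraphML exports.

## Known limitations

- The Entrez client is a thin paged wrapper and is exercised offline
  against mocks only; politeness beyond paging and retries (API keys, rate
  headers) is left to the caller.
- O(n³) minimax is the only Pathfinder algorithm; networks beyond a few
  thousand nodes would need the MST-based scalable variants.
- Keyword extraction is English-oriented and chunking-based; highly
  non-nominal titles (questions, full clauses) will yield some spurious
  "phrases".
- With `N = 1` (a single eligible period) the funnel is undefined and the
  pipeline aborts rather than guessing a degenerate rule.
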