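# Methods

## Problem setting

A consumer health vocabulary maps professional medical concepts to the
informal terms laypeople use. `layglove` treats vocabulary enrichment as a
synonym-retrieval task: for each concept with a known lay *seed term*, the
system must retrieve the concept's other lay terms (held out from it) from
a corpus of lay health discussion, using only distributional evidence plus
an optional lexical resource. The underlying assumption is the
distributional hypothesis — words appearing in similar contexts have
similar meaning — operationalised through co-occurrence embeddings.

## Preprocessing

The normalisation order is fixed: lowercase → delete apostrophes and split
on non-alphanumeric characters → drop tokens containing any digit → drop
stopwords and domain stopwords → Snowball-stem → drop stems shorter than
`min_token_len` (default 3). Stemming precedes the length filter so the
filter sees the form that actually enters the vocabulary. Digit-bearing
tokens are dropped whole rather than digit-stripped (`b12` carries no
usable lexical content once stripped). The domain stopword default is
{test, doctor, symptom, physician} — ubiquitous, low-information words in
health forums — and is user-replaceable. The Snowball English stemmer is
implemented in-package (`layglove._stem`) from the published algorithm
definition; note stemming is not strictly idempotent on every possible
string (`agre → agr`), though re-preprocessing realistic preprocessed text
is stable, which is the property the pipeline relies on and tests.

## Ground truth and seed assignment

Concept mappings arrive as `CUI \t concept-name \t term` rows. Filters:
concepts must have unigram preferred names; terms must be unigrams; terms
are stemmed and de-duplicated; a term equal to the stemmed preferred name
is removed (it is the professional word itself); a term must occur in the
**unexpanded** preprocessed corpus strictly more than `min_freq` (default
100) times; concepts need at least `min_terms` (default 2) survivors.
Frequency filtering uses the unexpanded corpus because filtering precedes
expansion in the pipeline's data flow; expansion counts would inflate
exactly the terms being tested. Seed selection draws one term per concept
from a single RNG stream, iterating concepts in sorted-CUI order so the
draw is independent of input order.

## Lexical resource and Resnik similarity

`LexicalResource` is a behavioural contract: senses of a surface, lemmas
of a sense, hyponym/hypernym sense links, a sense taxonomy and an
information-content (IC) table. Resnik similarity of two senses is the IC
of their most informative common ancestor (a sense subsumes itself, so
self-similarity is the sense's own IC). Polysemy is never disambiguated:
relations are the union over all senses of the query term, and a
candidate's score is the maximum Resnik value over all (seed sense,
candidate sense) pairs; duplicate surfaces collapse keeping the maximum.
Multi-word lemmas stay single tokens joined by underscores. Lemma surfaces
are stemmed on load (per underscore component) so inserted tokens unify
with the stemmed corpus vocabulary; an identity stemmer is available for
pre-stemmed or artificial resources. The packaged `toy_lexicon.json` is a
labelled synthetic miniature, not a WordNet extract; its IC values were
chosen so the `headache` entry yields distinct, ordered Resnik scores
across all three relation kinds.

## Corpus expansion

For seed *s* with scored synset *X*: sort by descending score (ties
lexicographic), truncate to `cap` (default 10, applied after cross-sense
deduplication), split into *X₁*/*X₂*, and rewrite every original
occurrence of *s* as `… X₁ s X₂ …`. Two split modes exist because the two
natural readings of "split evenly by similarity" differ: `roundrobin`
(default) alternates items left/right, balancing each side's total
similarity; `halves` keeps the ranked prefix contiguous on the left. Only
original corpus positions are scanned, so insertions are never themselves
expanded, and deleting all inserted tokens recovers the original corpus
exactly. A term seeding several concepts gets one merged plan (relation
lists unioned before ranking) so no occurrence is expanded twice. Under
flat counting with window ≥ |X₁|+|X₂|+1, the seed's co-occurrence row
gains exactly occurrences(s) per inserted token — the additive row model
`V̌ₛ = Vₛ + V_X` restricted to inserted coordinates — with inequality only
when insertions collide with pre-existing tokens or overlapping windows.

## Embedding model

Co-occurrence: symmetric, windows never cross documents, weighting either
flat or 1/distance (default). The trainer minimises
`Σ f(X_ij)(wᵢ·w̃ⱼ + bᵢ + b̃ⱼ − log X_ij)²` with `f(x) = (x/x_max)^α`
(x_max = 100, α = 0.75), learning rate 0.05, AdaGrad per-parameter
adaptation (accumulators initialised to 1), vectors initialised uniformly
in (−0.5/dim, +0.5/dim). Each symmetric entry is visited in both
orientations per epoch. Determinism: one seeded generator drives
initialisation and every epoch's shuffle, and the compiled inner loop
fixes the floating-point evaluation order, so identical seeds give
bitwise-identical vectors. Export vectors are `w + w̃` (configurable to
`w` alone). An empty matrix returns initialised vectors with zero loss
and a warning rather than failing, so degenerate corpora surface at
evaluation rather than mid-pipeline.

## Ranking and evaluation

Candidate lists are exhaustive cosine scans of the vocabulary (desk-scale
vocabularies need no ANN indexing), ties broken lexicographically.
Cosine may be negative for learned vectors; negative-scored candidates
are retained and ranked — clipping to [0, 1] would discard ordering
information. Seeds of other concepts are *not* excluded: they may be
legitimate held-out synonyms. An out-of-vocabulary seed produces "no list
generated", which reduces the macro-precision denominator rather than
raising.

Micro metrics count retrieved synonym terms (precision over
`lists generated × n`, recall over all held-out synonyms of the full
dataset); macro metrics count hit concepts (precision over generated
lists — forced by the framework's own worked arithmetic, 15/20 against a
25-concept dataset — recall over the dataset). F = 2PR/(P+R), defined 0
at P = R = 0. Each (concept, synonym) pair counts once regardless of
duplicate candidates. MRR averages 1/(first-hit rank) over generated
lists with 0 for misses (switchable to hits-only averaging). The
candidate-size sweep ranks once at max(n) and evaluates prefixes, so
micro recall and NumCon are non-decreasing in n by construction. Relative
improvement between algorithms is `(F_b − F_a)/F_a` on macro F (averaged
first when two datasets are supplied), reported as a rounded integer
percentage, undefined at F_a = 0. The optional `paired_hit_test` (exact
McNemar on per-concept hit indicators) is tooling this package adds for
significance checks; it is not part of the evaluation framework proper.

## Synthetic benchmark

Each concept owns a context-token multinomial; its synonyms substitute
for one another in identical slots — the minimal generative process under
which distributional synonymy is identifiable. Defaults: 20 concepts × 3
synonyms, 8 context tokens per concept, 150 background tokens, 800
documents of 40 tokens, synonym/context slot rates 0.3/0.45, planted
frequency guarantee > 101 (so the > 100 ground-truth filter passes), all
driven by one seeded RNG (byte-identical regeneration). Tokens are
invented stem-stable pseudo-words outside the stopword lists, so
preprocessing passes them through unchanged. The generated toy lexicon
exposes only `lexicon_coverage` (default 0.6) of each synonym group, plus
a two-level taxonomy giving every concept a hyponym and hypernym — so
lexicon-derived and corpus-derived true positives stay distinguishable.

What passing on this benchmark shows: the mechanism works end to end —
planted synonyms are ranked above background, expansion does not hurt and
typically helps recall. What it does not show: performance on real lay
health text, which has misspellings, multi-word lay terms, heavy-tailed
vocabularies and topic drift that the generator deliberately omits.

## Problem sizes and defaults

Pipeline defaults mirror the best-performing large-corpus setting
(window 30, 400-dimensional vectors, expansion cap 10, candidate lists
n = 10, frequency filter > 100). The benchmark runs in examples, tests
and the acceptance script use window 10, 50-dimensional vectors and 25
epochs: on an 800-document corpus with ~400 vocabulary entries the
planted structure saturates well below the production setting, and these
sizes keep a full double pipeline run in seconds. Epoch count is not part
of the reference setting and is a free parameter here (25 as default).

## Known limitations

- No WordNet adapter is bundled; the contract plus toy resource stand in.
  Results with a real lexicon depend on its version and IC corpus.
- Only unigram seed terms are expanded and ranked; multi-word lay terms
  are out of scope (lexicon multi-word lemmas enter as single
  underscore-joined tokens).
- Training determinism is guaranteed per platform; floating-point results
  may differ across architectures.
- The synthetic benchmark's ceiling is quickly reached at default sizes
  (both pipeline variants can recover every planted group), so it
  separates algorithms mainly through MRR and micro metrics.
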