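# layglove

Automatic enrichment of consumer health vocabularies from lay text.

Professional medical ontologies (UMLS concepts such as *C0021400
influenza*) map poorly onto the words patients actually use (*flu*,
*grippe*). Hand-curated consumer health vocabularies that bridge this gap
grow slowly because every new lay term needs human review. `layglove`
implements a fully automatic alternative for researchers in health NLP and
ontology maintenance: given a corpus of lay health discussion and concepts
that already have at least one known lay *seed term*, it proposes new
synonym candidates for each concept — optionally boosting a small corpus
with synonym/hyponym/hypernym synsets from a lexical resource such as
WordNet before training.

## Method

1. **Preprocess** the corpus: lowercase, strip punctuation, drop tokens
   containing digits, remove (domain) stopwords, Snowball-stem, drop stems
   shorter than 3 characters.
2. **Ground truth**: keep unigram lay terms occurring > 100 times in the
   corpus, and concepts with ≥ 2 surviving terms; draw one seed term per
   concept at random, holding the rest out for evaluation.
3. **Expansion** (optional): for each seed term *s*, fetch its relational
   synset *X* from the lexicon, rank *X* by Resnik similarity to *s*
   (information content of the most informative common ancestor), cap at
   the 10 most similar, split into *X₁*, *X₂*, and rewrite every
   occurrence `… w  X₁ s X₂  w′ …`. At the co-occurrence level this
   adds the insertion counts to the seed's row: `V̌ₛ = Vₛ + V_X` on the
   inserted coordinates.
4. **Embeddings**: build the symmetric windowed co-occurrence matrix *X*
   and minimise the log-bilinear objective

   `J = Σ_{ij} f(X_ij) (wᵢ·w̃ⱼ + bᵢ + b̃ⱼ − log X_ij)²`,
   `f(x) = (x/x_max)^α` for `x < x_max`, else 1,

   with AdaGrad updates over shuffled nonzero entries (seeded, bitwise
   reproducible). Export vectors are `w + w̃`.
5. **Ranking**: candidates for a seed are the top-*n* vocabulary tokens by
   cosine similarity `cos(v₁,v₂) = v₁·v₂ / (‖v₁‖‖v₂‖)`.
6. **Evaluation**: micro precision/recall count retrieved held-out
   synonyms (`TP / (lists·n)`, `TP / Σ|held-out|`); macro
   precision/recall count hit concepts (`hits / lists generated`,
   `hits / dataset size`); plus F = 2PR/(P+R), NumCon (hit-concept
   count), and mean reciprocal rank of the first true synonym.

A seeded synthetic-benchmark generator plants synonym groups that share
context distributions (with a matching toy lexicon), so the whole pipeline
is testable without any licensed resource or crawled corpus.

## Worked example

```python
from layglove import RelationKind, fetch_related, load_bundled_lexicon
from layglove.expansion import ExpansionPlan, expand_corpus, rank_and_split
from layglove.textprep import TokenizedCorpus

resource = load_bundled_lexicon(stemmer_id="identity")
synonyms = fetch_related("headache", RelationKind.SYNONYM, resource)
left, right = rank_and_split(synonyms, cap=10, mode="halves")
plan = ExpansionPlan("headache", RelationKind.SYNONYM, tuple(left), tuple(right))
expanded = expand_corpus(TokenizedCorpus([["i", "had", "a", "headache"]]),
                         {"headache": plan})
print(" ".join(expanded.documents[0]))
```

prints

```
i had a worry cephalalgia headache concern vexation
```

the seed's synset — `worry` (Resnik 4.0), `cephalalgia` (3.5), `concern`
(3.0), `vexation` (2.5) — split around the seed occurrence in ranked
order. Running `python examples/04_evaluation_metrics.py` scores a
transparent 25-concept scenario and prints

```
micro P/R: 0.30 / 0.40  (30/100 and 30/75)
macro P/R: 0.75 / 0.60  (15/20 and 15/25)
```

i.e. 30 of 100 proposed candidates were true held-out synonyms covering
30 of the 75 hidden terms, and 15 of the 20 generated lists (out of 25
concepts) contained at least one. The other `examples/` scripts cover
preprocessing, embedding training/ranking, and the full synthetic
benchmark; the `layglove` CLI exposes every stage
(`preprocess`, `build-seeds`, `lexicon-probe`, `expand`, `cooccur`,
`train`, `rank`, `eval`, `sweep`, `synth`, `run`).

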