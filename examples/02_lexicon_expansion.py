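"""Expand seed-term contexts with relational synsets from a lexicon.

Queries the bundled toy lexical resource for the synonyms of "headache",
ranks them by Resnik similarity, splits them into left/right insertion
subsets, and rewrites a sentence so the seed occurrence is surrounded by
its synset.  The contiguous-halves split shown here places the two most
similar items to the left of the seed.
"""

from layglove import RelationKind, fetch_related, load_bundled_lexicon
from layglove.expansion import ExpansionPlan, expand_corpus, rank_and_split
from layglove.textprep import TokenizedCorpus

# identity stemmer keeps the lexicon's raw surfaces for display purposes;
# the pipeline default stems them to match a stemmed corpus
resource = load_bundled_lexicon(stemmer_id="identity")

synonyms = fetch_related("headache", RelationKind.SYNONYM, resource)
print("scored synonyms of 'headache':")
for t in sorted(synonyms, key=lambda t: -t.score):
    print(f"  {t.surface:12s} resnik={t.score:.2f}")

left, right = rank_and_split(synonyms, cap=10, mode="halves")
print(f"\nsplit: left={left}  right={right}")

plan = ExpansionPlan("headache", RelationKind.SYNONYM, tuple(left), tuple(right))
corpus = TokenizedCorpus([["i", "had", "a", "headache"]])
expanded = expand_corpus(corpus, {"headache": plan})
print("expanded text:", " ".join(expanded.documents[0]))

# The seed keeps its original neighbours while gaining its synset as
# immediate context, which is what strengthens its co-occurrence row.
for kind in (RelationKind.HYPONYM, RelationKind.HYPERNYM):
    terms = sorted(t.surface for t in fetch_related("headache", kind, resource))
    print(f"{kind.value}s: {terms}")
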