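"""Normalise raw health-forum text into the token stream the pipeline uses.

Shows the fixed preprocessing order (lowercase, strip punctuation, drop
digit-bearing tokens, remove stopwords, Snowball-stem, drop short stems)
and how morphological variants of a lay term collapse onto one stem.
"""

from layglove import RawDocument, preprocess_corpus, term_frequencies

docs = [
    RawDocument("post1", "I've had terrible headaches and fatigue for 3 days!"),
    RawDocument("post2", "The doctor said my fatigued state causes fatiguing pain."),
    RawDocument("post3", "Fatigue, dizziness... more fatigues than ever."),
]

corpus = preprocess_corpus(docs)
for raw, toks in zip(docs, corpus.documents):
    print(f"{raw.text!r}\n  -> {toks}")

print("\nvocabulary frequencies:")
for token, count in sorted(term_frequencies(corpus).items()):
    print(f"  {token:10s} {count}")

# All of fatigue/fatigued/fatiguing/fatigues stem to "fatigu", so its count
# aggregates every variant; "doctor" vanished as a domain stopword and the
# token "3" as a number.
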