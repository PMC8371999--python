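"""Train co-occurrence embeddings on a tiny corpus and rank neighbours.

Builds the symmetric windowed co-occurrence matrix, fits the log-bilinear
model, and lists the vocabulary closest to a seed token by cosine
similarity.  The corpus plants "ach" and "pain" in interchangeable
contexts, so they should surface as each other's top candidates.
"""

import random

from layglove import TrainingConfig, build_cooccurrence, top_candidates, train_embeddings

rng = random.Random(0)
contexts = ["head", "sharp", "dull", "chronic", "night"]
noise = ["water", "sleep", "work", "coffee", "walk"]
docs = []
for _ in range(300):
    term = rng.choice(["ach", "pain"])  # synonyms: same context slots
    docs.append([rng.choice(contexts), term, rng.choice(contexts), rng.choice(noise)])

matrix = build_cooccurrence(docs, window=3, weighting="inverse-distance")
print(f"matrix: {len(matrix.vocab_index)} tokens, {len(matrix.entries)} nonzero pairs")

model = train_embeddings(matrix, TrainingConfig(dim=16, epochs=60, rng_seed=1))
print(f"final mean epoch loss: {model.epoch_losses[-1]:.4f}")

candidates = top_candidates(model, "ach", n=4)
print("\nnearest neighbours of 'ach':")
for token, score in candidates.candidates:
    print(f"  {token:8s} cosine={score:.3f}")

# The shared context words themselves score high too (they co-occur with
# "ach" directly); excluding them isolates the distributional synonym:
filtered = top_candidates(model, "ach", n=3, exclusions=set(contexts))
print("\nwith context tokens excluded:")
for token, score in filtered.candidates:
    print(f"  {token:8s} cosine={score:.3f}")

# "pain" now tops the list: both tokens were drawn from identical context
# distributions, which the embedding geometry recovers.
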