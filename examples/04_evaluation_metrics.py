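"""The micro/macro/F/MRR evaluation framework on a transparent scenario.

Constructs 25 concepts with four synonyms each (one seed, three held
out), 20 generated candidate lists of five candidates, 15 of which hold
exactly two true synonyms, then prints every metric with the counting
that produced it.
"""

from layglove.evaluate import (compare_algorithms, evaluate,
                               mean_reciprocal_rank, score_lists)
from layglove.groundtruth import SeedAssignment
from layglove.ranking import CandidateList

assignments, lists = [], {}
for k in range(25):
    cui = f"C{k:03d}"
    syns = [f"c{k}syn{i}" for i in range(4)]
    assignments.append(SeedAssignment(cui, syns[0], frozenset(syns[1:])))
    if k >= 20:
        lists[cui] = None  # seed out of vocabulary: no list generated
        continue
    if k < 15:
        tokens = [syns[1], "junk1", "junk2", syns[2], "junk3"]
    else:
        tokens = ["junk1", "junk2", "junk3", "junk4", "junk5"]
    scored = tuple((t, 1.0 - 0.01 * i) for i, t in enumerate(tokens))
    lists[cui] = CandidateList(syns[0], scored, 5)

report = evaluate(lists, assignments, n=5, dataset_size=25)
print(f"lists generated:      {report.lists_generated} (of 25 concepts)")
print(f"true positives:       {report.true_positive_count} "
      f"(out of {report.lists_generated * 5} candidates)")
print(f"held-out synonyms:    {report.total_truths}")
print(f"micro P/R: {report.micro.precision:.2f} / {report.micro.recall:.2f}"
      f"  (30/100 and 30/75)")
print(f"macro P/R: {report.macro.precision:.2f} / {report.macro.recall:.2f}"
      f"  (15/20 and 15/25)")
print(f"NumCon: {report.num_con}   MRR: {report.mrr:.3f}")

records = score_lists(lists, assignments)
print(f"MRR over hit lists only: {mean_reciprocal_rank(records, over='hits'):.3f}")

# Relative improvement between two algorithms, from macro F averaged over
# two evaluation datasets:
rel = compare_algorithms([48.44, 49.23], [57.87, 64.29])
print(f"\nrelative macro-F improvement: +{rel}%")
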