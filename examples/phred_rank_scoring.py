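"""Train the deleteriousness classifier on synthetic annotations and turn
its posteriors into PHRED-scaled rank scores.

The two training classes are proxies: derived variants (label 0) stand in
for benign changes, simulated de novo variants (label 1) for potentially
deleterious ones.  Scores are relative ranks: 20 means top 1% of the score
universe, 10 means top 10%.
"""

import numpy as np

from chcadd import cadd_model, features, synthetic

world = synthetic.make_world(seed=7)
fm = features.encode(world.annotation_table, features.demo_schema(),
                     labels=world.annotation_labels)
fm = features.combine(fm, [("consequence", "tss_distance"),
                           ("consequence", "conservation")])
fm = features.scale(fm)

weights = cadd_model.train(fm, seed=0)
print("penalty grid (test-set metrics):")
print(weights.metrics.to_string(index=False))
print(f"selected penalty: {weights.penalty}")

# score every row against a universe of all possible alternative alleles
# of the toy genome (3 per base)
N = 3 * world.config.genome_length
table = cadd_model.score_variants(weights, fm, N=N)
top = table.table.nlargest(3, "phred")
print(f"\nscore universe N = {N:,}; top 3 of {len(table.table)} variants:")
print(top[["posterior", "rank", "phred"]].to_string(index=False))
print("\nA phred of -10*log10(rank/N): higher = ranked more deleterious "
      "relative to every possible variant.")
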