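"""Pairwise proteome comparison and taxonomic rank assignment.

Builds four synthetic proteome pairs sharing 5%, 15%, 30% and 65% of
their proteins, computes RBH-based AAI, orthologous fraction (OF) and the
bit-score-normalized similarity SG, and maps each pair to a rank verdict
(same genus >= 60% OF; same family 20-50% OF with SG > 0.05; distinct
families < 10% OF; the 10-20% band stays ambiguous).
"""

import numpy as np

from proviscope import mcpsearch as ms
from proviscope import protcompare as pc
from proviscope.synthgenome import random_protein

scheme = ms.ScoringScheme()
rng = np.random.default_rng(77)
n = 20
genome_a = {f"a{i}": "M" + random_protein(rng, 70) for i in range(n)}

print(f"{'shared':>6} {'OF':>5} {'AAI':>6} {'SG':>6}  rank")
for n_shared in (1, 3, 6, 13):
    genome_b = {f"b{i}": "M" + random_protein(rng, 70) for i in range(n - n_shared)}
    for i in range(n_shared):
        genome_b[f"s{i}"] = genome_a[f"a{i}"]
    rbh = pc.reciprocal_best_hits(genome_a, genome_b, scheme)
    m = pc.pair_metrics(genome_a, genome_b, rbh, "A", "B", scheme=scheme)
    rank = pc.assign_rank(m).rank
    print(f"{n_shared:>6} {m.of:>5.2f} {m.aai:>6.1f} {m.sg:>6.3f}  {rank}")

print()
print("OF tracks the planted ortholog fraction exactly; SG rises with shared")
print("content, and the rank verdicts reproduce the genus/family thresholds,")
print("including the deliberately unresolved ambiguous band.")
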