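"""Detect a nested CRISPR-Cas system and match a spacer to a target.

Forges a locus with two CRISPR arrays (74 and 61 spacers, identical 30-bp
repeats) inside one same-orientation cas gene cluster, runs the array
detector, checks the nested layout, and demonstrates spacer-protospacer
matching against a synthetic viral genome carrying one near-exact
protospacer.
"""

import numpy as np

from proviscope import featureannot as fa
from proviscope import synthgenome as sg

rng = np.random.default_rng(1)
specs = [
    sg.CrisprArraySpec(n_spacers=74, repeat_length=30, with_cas_cluster=True),
    sg.CrisprArraySpec(n_spacers=61, repeat_length=30, with_cas_cluster=True),
]
locus, truth = sg.forge_crispr_locus(specs, rng)

arrays = fa.detect_crispr_arrays(locus)
print(f"locus length    : {len(locus):,} bp")
for i, arr in enumerate(arrays, 1):
    print(f"array {i}         : {arr.n_spacers} spacers, "
          f"repeat {arr.repeat_length} bp, span {arr.start:,}..{arr.end:,}")
print(f"total spacers   : {sum(a.n_spacers for a in arrays)}")

cas = [(s, e, st) for s, e, st, _name in truth.cas_genes]
nested, layout = fa.detect_nested_system(arrays, cas)
print(f"nested layout   : {nested} (orientation {layout['orientation']})")

# Plant one spacer (with two substitutions) inside a synthetic virus genome.
spacer = arrays[0].spacers[6]
mutated = list(spacer)
mutated[4] = "A" if mutated[4] != "A" else "C"
mutated[20] = "G" if mutated[20] != "G" else "T"
virus = sg.random_dna(rng, 4_000) + "".join(mutated) + sg.random_dna(rng, 4_000)
match = fa.match_spacer(spacer, {"synthetic_virus": virus}, spacer_id="array1_spacer7")
print(f"spacer match    : target={match.target_id} coverage={match.coverage:.0%} "
      f"identity={match.identity:.1%} strand={match.strand}")
print()
print("Both arrays are recovered with their exact spacer counts and the shared")
print("30-bp repeat; the spacer hit shows how past-invader records in an array")
print("link a CRISPR locus to the viral genome it targets.")
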