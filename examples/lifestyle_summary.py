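"""Summarize lifestyle predictions for the bundled provirus table.

Loads the shipped compilation of 39 archaeal provirus records (PhaTYP-style
Virulent/Temperate labels with lysis-gene flags) and applies the
lytic-potential rule: a provirus can lyse its host if it is labelled
Virulent OR carries holin/endolysin genes.
"""

from proviscope import report

records = report.load_lifestyle_table()
counts = report.summarize(records)

print(f"records                    : {counts.n_total}")
print(f"virulent                   : {counts.n_virulent}")
print(f"temperate                  : {counts.n_temperate}")
print(f"virulent with lysis genes  : {counts.n_virulent_with_lysis}")
print(f"temperate with lysis genes : {counts.n_temperate_with_lysis}")
print(f"lytic potential (total)    : {counts.n_lytic_potential}")
print()
print("Temperate proviruses carrying holin/endolysin genes still count as")
print("lysis-capable, so the lytic-potential total is the virulent count plus")
print("the temperate-with-lysis count.")
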