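"""Synthetic vection ratings and the within-subject statistical analysis.

Draws a 7-subject 2 (viewing) x 3 (coupling) rating table from the default
effect pattern, runs the two-way repeated-measures ANOVA, the per-coupling
passive-vs-active t-tests, and the pooled oscillating-vs-radial contrast.
"""

import numpy as np

import vectionsim as vs
from vectionsim.observers import COUPLINGS, VIEWINGS

table = vs.playback_design(vs.generate_ratings(vs.EffectConfig(),
                                               n_subjects=7, seed=2))
cells = table.cell_matrix("strength")

print("cell mean vection strength (0-100):")
print(f"{'':<10}" + "".join(f"{c:>15}" for c in COUPLINGS))
for j, v in enumerate(VIEWINGS):
    print(f"{v:<10}" + "".join(f"{cells[:, j, c].mean():>15.1f}"
                               for c in range(3)))
print()
print(vs.rm_anova_twoway(cells).to_text())
print()
print("passive vs active, per coupling condition:")
for c, coupling in enumerate(COUPLINGS):
    r = vs.paired_t(cells[:, 1, c], cells[:, 0, c])
    print(f"  {coupling:<15} t({r.df}) = {r.t:5.2f}, p = {r.p:.4f}, "
          f"mean diff = {r.mean_difference:+.1f}")
print()
print("pooled (contralateral+ipsilateral)/2 vs pure radial:")
for v in VIEWINGS:
    r = vs.pooled_oscillation_contrast(table, v)
    print(f"  {v:<8} t({r.df}) = {r.t:5.2f}, p = {r.p:.4f}, "
          f"mean diff = {r.mean_difference:+.1f}")
print()
print("Reading: passive viewing boosts vection mainly in the ipsilateral")
print("condition (the interaction); pooled oscillating flow beats pure")
print("radial flow only under passive viewing.")
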