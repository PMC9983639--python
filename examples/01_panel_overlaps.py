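"""Compare the bundled disease gene panels.

Loads the six motor-neuron-disease panels shipped with the package and
prints their pairwise overlaps. The ALS panels illustrate the split between
familial (pathogenicity, OMIM-style) and sporadic (susceptibility,
GWAS-style) genetics: only five genes sit in both.
"""

from strictscreen import intersect
from strictscreen.data import available_panels, bundled_panel

panels = {name: bundled_panel(name) for name in available_panels()}
for name, panel in panels.items():
    print(f"{name:20s} {len(panel):3d} genes")

ov = intersect(panels["ALS-pathogenicity"], panels["ALS-susceptibility"])
print(f"\nALS pathogenicity x susceptibility: {ov.count_shared} shared genes")
print("  " + ", ".join(sorted(ov.shared)))
# These five genes carry both rare causal mutations and common risk variants.

ov = intersect(panels["HMN"], panels["SMA"])
print(f"HMN x SMA: {ov.count_shared} shared genes ({', '.join(sorted(ov.shared))})")
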