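"""Combine enrichment evidence across independent datasets.

Two simulated cohorts are scored for the same marker panel; Stouffer's
method combines each (cell type, panel) pair's one-sided p-values, and the
Bonferroni family is the pooled cell-type count across cohorts — the same
two-level correction used when replicating an association across a
discovery cohort and replication cohorts.
"""

import pandas as pd

from strictscreen import GenePanel, SimulationConfig, normalize_cpm, simulate
from strictscreen.ewce import bootstrap_enrichment, specificity_matrix
from strictscreen.expression import mean_by_celltype
from strictscreen.meta import meta_frame, meta_table

rows = []
panel_genes = None
# same assignment_seed = same ground-truth biology; different seed = new cells
for label, seed in [("discovery", 21), ("replication", 22)]:
    store, truth = simulate(SimulationConfig(seed=seed, assignment_seed=99))
    if panel_genes is None:
        panel_genes = truth.markers_of("CT00")
    spec = specificity_matrix(mean_by_celltype(normalize_cpm(store)))
    res = bootstrap_enrichment(
        spec, GenePanel.from_symbols("mk", panel_genes), n_boot=10_000, seed=seed
    )
    rows += [
        {"dataset": label, "cell_type": r.cell_type, "panel": "mk", "p": r.p} for r in res
    ]

per_dataset = pd.DataFrame(rows)
meta = meta_frame(meta_table(per_dataset))
print(meta.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
# n_tests = 5 + 5 pooled cell types. A pair that replicates in both cohorts
# gets a combined p smaller than either input; p_bonf = min(1, combined_p * 10).
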