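"""Expression-weighted cell-type enrichment (EWCE).

The specificity of gene *g* in cell type *t* is the mean expression of *g*
in *t* divided by the sum of its mean expression across all cell types, so
each usable gene's specificity row sums to 1. A gene set's enrichment in a
cell type is tested by comparing the summed specificity of the target genes
against the sums of random same-size gene lists (10,000 by default) drawn
without replacement from all usable genes; the bootstrap p-value is the
upper-tail proportion with a +1/(n+1) pseudo-count, and per-dataset p-values
across cell types are adjusted by Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import CellTypeMeans
from .panels import GenePanel, restrict_to_universe

__all__ = [
    "SpecificityMatrix",
    "EnrichmentResult",
    "specificity_matrix",
    "bootstrap_enrichment",
    "enrichment_table",
    "fdr_adjust",
    "size_power_scan",
]

_CHUNK = 1000  # bootstrap replicates sampled per block to bound memory


@dataclass
class SpecificityMatrix:
    """genes x cell types specificity proportions in [0, 1].

    ``usable`` flags genes with nonzero total mean expression; only those
    carry a meaningful (row-sums-to-1) specificity and enter the bootstrap
    null universe.
    """

    spec: pd.DataFrame
    usable: pd.Series

    def __post_init__(self) -> None:
        vals = self.spec.to_numpy()
        if vals.min() < 0 or vals.max() > 1 + 1e-12:
            raise ValueError("specificity entries must lie in [0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.spec.index

    @property
    def cell_type_ids(self) -> pd.Index:
        return self.spec.columns

    @property
    def usable_genes(self) -> pd.Index:
        return self.spec.index[self.usable.to_numpy()]


@dataclass
class EnrichmentResult:
    """Bootstrap enrichment of one gene set in one cell type."""

    cell_type: str
    observed: float
    boot_mean: float
    boot_sd: float
    p: float
    p_fdr: float
    n_target: int
    n_boot: int


def specificity_matrix(means: CellTypeMeans) -> SpecificityMatrix:
    """Proportion of a gene's summed per-type mean expression in each type.

    Genes whose mean is zero in every cell type get an all-zero row and are
    flagged unusable.
    """
    m = means.means.to_numpy(dtype=float)  # types x genes
    totals = m.sum(axis=0)
    usable = totals > 0
    spec = np.zeros_like(m)
    spec[:, usable] = m[:, usable] / totals[usable]
    return SpecificityMatrix(
        spec=pd.DataFrame(spec.T, index=means.means.columns, columns=means.means.index),
        usable=pd.Series(usable, index=means.means.columns),
    )


def _sample_subset_sums(
    values: np.ndarray, size: int, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Sums of ``n_boot`` random ``size``-subsets of the rows of ``values``.

    Subsets are drawn without replacement within each replicate. Returns an
    (n_boot, values.shape[1]) array. Chunked so peak memory stays at
    roughly ``_CHUNK * len(values)`` floats.
    """
    n_genes = values.shape[0]
    if size > n_genes:
        raise ValueError("subset size exceeds universe")
    out = np.empty((n_boot, values.shape[1]), dtype=float)
    done = 0
    while done < n_boot:
        k = min(_CHUNK, n_boot - done)
        keys = rng.random((k, n_genes))
        idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
        out[done : done + k] = values[idx].sum(axis=1)
        done += k
    return out


def bootstrap_enrichment(
    spec: SpecificityMatrix,
    target: GenePanel,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 1,
) -> list[EnrichmentResult]:
    """Test a gene set's summed specificity per cell type against random sets.

    The target is first restricted to the usable gene universe (>= 2 genes
    must remain). The null samples random gene lists of the same size from
    all usable genes (target genes are not excluded), and
    ``p = (1 + #{null >= observed}) / (n_boot + 1)``, upper tail, ties
    counting toward the tail. FDR adjustment is across this call's cell
    types.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = spec.usable_genes
    restricted, _dropped = restrict_to_universe(target, universe)
    if len(restricted) < 2:
        raise ValueError(f"target too small: {len(restricted)} usable gene(s)")
    vals = spec.spec.loc[universe].to_numpy(dtype=float)
    # panel symbols are uppercase-normalized; match the universe case-insensitively
    upper_pos = {str(g).upper(): i for i, g in enumerate(universe)}
    target_idx = np.array([upper_pos[g] for g in restricted.genes])
    observed = vals[target_idx].sum(axis=0)
    null_sums = _sample_subset_sums(vals, len(restricted), n_boot, rng)
    # ties count toward the tail; tolerance absorbs summation-order float noise
    tol = 1e-9 * np.abs(observed)
    ge = (null_sums >= (observed - tol)[None, :]).sum(axis=0)
    p = (1.0 + ge) / (n_boot + 1.0)
    p_fdr = fdr_adjust(list(p))
    boot_mean = null_sums.mean(axis=0)
    boot_sd = null_sums.std(axis=0, ddof=1)
    return [
        EnrichmentResult(
            cell_type=str(ct),
            observed=float(observed[j]),
            boot_mean=float(boot_mean[j]),
            boot_sd=float(boot_sd[j]),
            p=float(p[j]),
            p_fdr=float(p_fdr[j]),
            n_target=len(restricted),
            n_boot=n_boot,
        )
        for j, ct in enumerate(spec.cell_type_ids)
    ]


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment results as a table, one row per cell type."""
    return pd.DataFrame(
        [
            {
                "cell_type": r.cell_type,
                "n_target": r.n_target,
                "observed": r.observed,
                "boot_mean": r.boot_mean,
                "boot_sd": r.boot_sd,
                "p": r.p,
                "p_fdr": r.p_fdr,
            }
            for r in results
        ]
    )


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment (monotone-enforced, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def size_power_scan(
    spec: SpecificityMatrix,
    source_panel: GenePanel,
    sizes: Sequence[int],
    n_rep: int = 20,
    n_boot: int = 10_000,
    seed: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fraction of random sub-panels significant (FDR < alpha) per size.

    For each size *s*, draws ``n_rep`` random *s*-subsets of ``source_panel``
    and runs the bootstrap enrichment; rows are sizes, columns cell types,
    entries the proportion of subsets with adjusted p below ``alpha``. Used
    to map how many genes a panel needs before an association is detectable.
    """
    rng = np.random.default_rng(seed)
    genes = np.array(source_panel.genes)
    for s in sizes:
        if not 2 <= s <= len(genes):
            raise ValueError(f"size {s} outside [2, {len(genes)}]")
    rows = {}
    for s in sizes:
        hits = np.zeros(len(spec.cell_type_ids))
        for _ in range(n_rep):
            sub = rng.choice(genes, size=s, replace=False)
            panel = GenePanel.from_symbols(f"{source_panel.name}[{s}]", sub)
            res = bootstrap_enrichment(spec, panel, n_boot=n_boot, seed=rng)
            hits += np.array([r.p_fdr < alpha for r in res], dtype=float)
        rows[s] = hits / n_rep
    return pd.DataFrame.from_dict(rows, orient="index", columns=spec.cell_type_ids)
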