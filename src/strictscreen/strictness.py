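"""Strictness: a per-gene dosage-requirement statistic for cell populations.

For one gene, each cell's fold change is its expression divided by a
reference mean, ``C_i = E_i / Ebar``; strictness is the inverse of the
sample standard deviation of those fold changes,

    S = 1 / sqrt( sum_i (C_i - Cbar)^2 / (n - 1) ).

A gene whose expression sits in a narrow band around its mean (low
fold-change dispersion) gets a high S and is interpreted as
dosage-sensitive; a gene whose expression tolerates wide excursions gets a
low S. S is invariant to rescaling a gene's expression by any positive
constant, because the constant cancels in the fold change.

Two reference scopes are supported for the denominator ``Ebar``:

* ``"global-ref"`` (default): ``Ebar`` is the gene's mean over ALL cells in
  the dataset, while ``Cbar`` and the standard deviation are taken over the
  cells of the queried population only. This matches asking how strictly a
  gene holds its dataset-wide level within, say, motor neurons.
* ``"within-type"``: ``Ebar`` is the mean over the queried population's own
  cells (so ``Cbar = 1`` exactly and S is the inverse coefficient of
  variation within the population).

Gene-set significance uses the Central Limit Theorem: the observed mean
strictness x of the n panel genes is compared with the means of 10,000
random n-gene sets drawn without replacement from all usable genes; a
normal distribution N(mu, sigma^2) is fitted to those bootstrap means by
maximum likelihood (sample mean; SD with the 1/N denominator) and
``p = 1 - Phi((x - mu) / sigma)``, upper tail. P-values across populations
are Bonferroni-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from .expression import ExpressionStore
from .panels import GenePanel, restrict_to_universe

__all__ = [
    "StrictnessValue",
    "StrictnessTest",
    "fold_change",
    "strictness",
    "strictness_all",
    "geneset_strictness_test",
    "bonferroni_adjust",
    "panel_compare",
]

#: Fold-change sample SDs below this are treated as zero variance.
DEGENERATE_SD = 1e-12

SCOPES = ("global-ref", "within-type")


@dataclass
class StrictnessValue:
    """Strictness of one gene in one cell population."""

    gene: str
    cell_type: str
    S: float
    n_cells: int
    degenerate: bool = False


@dataclass
class StrictnessTest:
    """CLT-based significance of a panel's mean strictness in one population."""

    panel: str
    cell_type: str
    n_genes: int
    observed_mean: float
    null_mu: float
    null_sigma: float
    p: float
    p_bonf: float
    n_boot: int
    empirical_p: float
    scope: str = "global-ref"


def fold_change(expression: Sequence[float] | np.ndarray, reference_mean: float) -> np.ndarray:
    """Per-cell fold changes ``C_i = E_i / Ebar``.

    Raises
    ------
    ValueError
        If ``reference_mean`` is not strictly positive — such a gene carries
        no usable strictness.
    """
    if not reference_mean > 0:
        raise ValueError("reference mean must be > 0; gene is unusable")
    return np.asarray(expression, dtype=float) / reference_mean


def strictness(C: Sequence[float] | np.ndarray, gene: str = "", cell_type: str = "all") -> StrictnessValue:
    """Inverse sample SD of fold changes over one population's cells.

    With fewer than two cells the SD is undefined and an error is raised.
    Zero-variance fold changes (SD below :data:`DEGENERATE_SD`) set the
    ``degenerate`` flag and report ``S = 1/DEGENERATE_SD``.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 1 or C.size < 2:
        raise ValueError("strictness needs >= 2 cells")
    sd = float(C.std(ddof=1))
    if sd < DEGENERATE_SD:
        return StrictnessValue(gene, cell_type, 1.0 / DEGENERATE_SD, C.size, degenerate=True)
    return StrictnessValue(gene, cell_type, 1.0 / sd, C.size, degenerate=False)


def strictness_all(
    store: ExpressionStore,
    cell_type: str | None = None,
    scope: str = "global-ref",
) -> pd.DataFrame:
    """Strictness of every gene in one population (or all cells).

    Returns a DataFrame indexed by gene with columns ``S``, ``n_cells``,
    ``degenerate``, ``usable``. Genes with zero reference mean are unusable
    (S is NaN); zero-variance genes are flagged degenerate. Both classes are
    excluded from the universe of :func:`geneset_strictness_test`.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    X = store.adata.X
    if cell_type is None:
        mask = np.ones(store.n_cells, dtype=bool)
        label = "all"
    else:
        mask = (store.cell_types == cell_type).to_numpy()
        label = cell_type
        if not mask.any():
            raise ValueError(f"no cells of type {cell_type!r}")
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"population {label!r} has {n} cell(s); need >= 2")

    sub = X[np.flatnonzero(mask), :] if sp.issparse(X) else X[mask, :]
    pop_mean = np.asarray(sub.mean(axis=0)).ravel()
    if sp.issparse(sub):
        sq = np.asarray(sub.multiply(sub).mean(axis=0)).ravel()
    else:
        sq = np.asarray((sub**2).mean(axis=0)).ravel()
    # sample variance of E over the population, ddof=1
    var_e = np.maximum(sq - pop_mean**2, 0.0) * (n / (n - 1))
    sd_e = np.sqrt(var_e)

    if scope == "global-ref":
        ref = np.asarray(X.mean(axis=0)).ravel()
    else:
        ref = pop_mean
    usable = ref > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sd_c = sd_e / ref  # SD of E/ref equals SD(E)/ref
    degenerate = usable & (sd_c < DEGENERATE_SD)
    S = np.full(store.n_genes, np.nan)
    ok = usable & ~degenerate
    S[ok] = 1.0 / sd_c[ok]
    S[degenerate] = 1.0 / DEGENERATE_SD
    out = pd.DataFrame(
        {"S": S, "n_cells": n, "degenerate": degenerate, "usable": usable},
        index=store.gene_ids,
    )
    out.attrs["cell_type"] = label
    out.attrs["scope"] = scope
    return out


def _null_mean_samples(
    values: np.ndarray, size: int, n_boot: int, rng: np.random.Generator, chunk: int = 2000
) -> np.ndarray:
    """Means of random ``size``-subsets of ``values``, ``n_boot`` replicates."""
    n = values.size
    out = np.empty(n_boot)
    done = 0
    while done < n_boot:
        k = min(chunk, n_boot - done)
        keys = rng.random((k, n))
        idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
        out[done : done + k] = values[idx].mean(axis=1)
        done += k
    return out


def geneset_strictness_test(
    S_all: pd.DataFrame,
    panel: GenePanel,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 1,
    n_tests: int = 1,
) -> StrictnessTest:
    """CLT significance of a panel's mean strictness against random panels.

    ``S_all`` is the output of :func:`strictness_all` for one population.
    Degenerate and unusable genes are excluded from both the panel and the
    sampling universe. ``empirical_p`` is the direct bootstrap tail
    proportion (with the +1/(n+1) pseudo-count), reported alongside the
    normal-approximation ``p`` as a built-in adequacy check.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ok = S_all["usable"] & ~S_all["degenerate"]
    universe = S_all.index[ok.to_numpy()]
    restricted, _ = restrict_to_universe(panel, universe)
    if len(restricted) < 2:
        raise ValueError(f"panel too small after restriction: {len(restricted)} gene(s)")
    s_vals = S_all.loc[universe, "S"].to_numpy(dtype=float)
    upper_pos = {str(g).upper(): i for i, g in enumerate(universe)}
    target_idx = np.array([upper_pos[g] for g in restricted.genes])
    x = float(s_vals[target_idx].mean())
    null_means = _null_mean_samples(s_vals, len(restricted), n_boot, rng)
    mu = float(null_means.mean())
    sigma = float(null_means.std(ddof=0))  # 1/N denominator: the normal MLE
    if sigma == 0:
        raise ValueError("degenerate null: zero spread of bootstrap means")
    p = float(norm.sf((x - mu) / sigma))
    emp = float((1.0 + (null_means >= x).sum()) / (n_boot + 1.0))
    return StrictnessTest(
        panel=panel.name,
        cell_type=str(S_all.attrs.get("cell_type", "all")),
        n_genes=len(restricted),
        observed_mean=x,
        null_mu=mu,
        null_sigma=sigma,
        p=p,
        p_bonf=bonferroni_adjust(max(p, 1e-300), n_tests),
        n_boot=n_boot,
        empirical_p=emp,
        scope=str(S_all.attrs.get("scope", "global-ref")),
    )


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """Bonferroni adjustment ``min(1, p * n_tests)``."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def panel_compare(
    store: ExpressionStore,
    panels: Sequence[GenePanel],
    cell_populations: Sequence[str | None],
    n_boot: int = 10_000,
    seed: int = 1,
    scope: str = "global-ref",
) -> pd.DataFrame:
    """Strictness tests for each panel in each cell population.

    ``cell_populations`` entries are cell-type labels, or ``None`` for the
    whole dataset. Bonferroni ``n_tests`` is the number of populations
    tested per panel. Returns one row per panel x population with the test
    summary (p, p_bonf, null moments, scope).
    """
    if not panels or not cell_populations:
        raise ValueError("need >= 1 panel and >= 1 population")
    rng = np.random.default_rng(seed)
    n_tests = len(cell_populations)
    s_tables = {pop: strictness_all(store, cell_type=pop, scope=scope) for pop in cell_populations}
    rows = []
    for panel in panels:
        for pop in cell_populations:
            t = geneset_strictness_test(s_tables[pop], panel, n_boot=n_boot, seed=rng, n_tests=n_tests)
            rows.append(
                {
                    "panel": t.panel,
                    "cell_type": t.cell_type,
                    "n_genes": t.n_genes,
                    "observed_mean": t.observed_mean,
                    "null_mu": t.null_mu,
                    "null_sigma": t.null_sigma,
                    "p": t.p,
                    "p_bonf": t.p_bonf,
                    "n_boot": t.n_boot,
                    "scope": t.scope,
                }
            )
    return pd.DataFrame(rows)
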