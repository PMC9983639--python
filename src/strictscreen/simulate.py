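"""Synthetic single-cell count data with known ground truth.

Generates datasets with the statistical structure the analysis assumes:

* a handful of cell types (5–75 in the real tissues this emulates), each
  with a set of marker genes whose mean expression is elevated in that type
  by ``marker_fold``;
* negative-binomial counts — for mean ``m`` and dispersion ``theta`` the
  variance is ``m + m^2/theta``, so larger ``theta`` means tighter,
  Poisson-like expression;
* designated "strict" (dosage-sensitive analogue; high ``theta``, narrow
  expression) and "tolerant" (low ``theta``, overdispersed) gene subsets,
  disjoint from the markers, which serve as positive/negative ground truth
  for the strictness statistic;
* per-cell library-size variation, log-normal multiplicative on the means,
  which downstream CPM normalization should largely remove.

Fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .expression import ExpressionStore, load_matrix

__all__ = ["SimulationConfig", "SimulationTruth", "simulate", "write_fixture"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic single-cell generator.

    ``cells_per_type`` may be an int or an inclusive ``(low, high)`` range
    sampled per type. ``dispersion_background`` may be a scalar or a
    ``(low, high)`` range: with a range, each background gene draws its own
    theta log-uniformly, giving a per-gene dispersion continuum (useful for
    rank-recovery checks). ``marker_fold = 1`` and zero strict/tolerant
    genes give an exchangeable null dataset.

    ``assignment_seed`` fixes the structural ground truth (which genes are
    markers/strict/tolerant and each gene's theta) separately from ``seed``
    (the count noise): cohorts simulated with the same ``assignment_seed``
    but different ``seed`` emulate independent replication datasets of the
    same biology. When ``None``, structure follows ``seed``.
    """

    n_cell_types: int = 5
    cells_per_type: int | tuple[int, int] = 200
    n_genes: int = 2000
    n_markers_per_type: int = 25
    marker_fold: float = 5.0
    baseline_mean: float = 2.0
    dispersion_tolerant: float = 0.5
    dispersion_strict: float = 5.0
    dispersion_background: float | tuple[float, float] = 2.0
    n_strict_genes: int = 100
    n_tolerant_genes: int = 100
    depth_variation: float = 0.3
    seed: int = 1
    assignment_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cell_types < 1 or self.n_genes < 1 or self.n_markers_per_type < 0:
            raise ValueError("counts must be positive (markers may be 0)")
        lo = self.cells_per_type if isinstance(self.cells_per_type, int) else self.cells_per_type[0]
        if lo < 2:
            raise ValueError("need >= 2 cells per type")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if self.baseline_mean <= 0 or self.depth_variation < 0:
            raise ValueError("baseline_mean > 0 and depth_variation >= 0 required")
        if not (self.dispersion_strict > self.dispersion_tolerant > 0):
            raise ValueError("need dispersion_strict > dispersion_tolerant > 0")
        if self.n_strict_genes < 0 or self.n_tolerant_genes < 0:
            raise ValueError("strict/tolerant gene counts must be >= 0")
        reserved = (
            self.n_strict_genes
            + self.n_tolerant_genes
            + self.n_cell_types * self.n_markers_per_type
        )
        if reserved > self.n_genes:
            raise ValueError(
                f"{reserved} strict+tolerant+marker genes exceed n_genes={self.n_genes}"
            )

    def null(self) -> "SimulationConfig":
        """An exchangeable-null variant: no markers, no depth spread, one theta."""
        return replace(
            self,
            marker_fold=1.0,
            n_markers_per_type=0,
            n_strict_genes=0,
            n_tolerant_genes=0,
            depth_variation=0.0,
        )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    marker_assignment: dict[str, str]  # gene -> cell type
    strict_genes: frozenset[str]
    tolerant_genes: frozenset[str]
    dispersion: pd.Series = field(repr=False)  # per-gene true theta

    def __post_init__(self) -> None:
        if self.strict_genes & self.tolerant_genes:
            raise ValueError("strict and tolerant gene sets overlap")

    def markers_of(self, cell_type: str) -> tuple[str, ...]:
        return tuple(g for g, t in self.marker_assignment.items() if t == cell_type)


def simulate(config: SimulationConfig) -> tuple[ExpressionStore, SimulationTruth]:
    """Draw one dataset from the generator.

    Counts for cell *c*, gene *g* are negative binomial with mean
    ``baseline_mean * marker_fold^{[g marks c's type]} * depth_c`` and the
    gene's class dispersion; ``depth_c`` is log-normal with log-SD
    ``depth_variation``.
    """
    rng = np.random.default_rng(config.seed)
    rng_struct = np.random.default_rng(
        config.seed if config.assignment_seed is None else config.assignment_seed
    )
    G = config.n_genes
    genes = np.array([f"G{i:05d}" for i in range(G)])
    types = [f"CT{t:02d}" for t in range(config.n_cell_types)]

    # gene classes: strict, tolerant, then markers from the remaining pool
    order = rng_struct.permutation(G)
    strict_idx = order[: config.n_strict_genes]
    tol_idx = order[config.n_strict_genes : config.n_strict_genes + config.n_tolerant_genes]
    pool = order[config.n_strict_genes + config.n_tolerant_genes :]
    marker_idx = {
        t: pool[i * config.n_markers_per_type : (i + 1) * config.n_markers_per_type]
        for i, t in enumerate(types)
    }

    theta = np.empty(G)
    if isinstance(config.dispersion_background, tuple):
        lo, hi = config.dispersion_background
        theta[:] = np.exp(rng_struct.uniform(np.log(lo), np.log(hi), size=G))
    else:
        theta[:] = config.dispersion_background
    theta[strict_idx] = config.dispersion_strict
    theta[tol_idx] = config.dispersion_tolerant

    if isinstance(config.cells_per_type, int):
        n_per_type = [config.cells_per_type] * config.n_cell_types
    else:
        lo, hi = config.cells_per_type
        n_per_type = list(rng.integers(lo, hi + 1, size=config.n_cell_types))

    blocks, labels = [], []
    for t, n_t in zip(types, n_per_type):
        mean_g = np.full(G, config.baseline_mean)
        mean_g[marker_idx[t]] *= config.marker_fold
        depth = (
            np.exp(rng.normal(0.0, config.depth_variation, size=n_t))
            if config.depth_variation > 0
            else np.ones(n_t)
        )
        m = depth[:, None] * mean_g[None, :]
        counts = rng.negative_binomial(theta[None, :], theta[None, :] / (theta[None, :] + m))
        blocks.append(counts)
        labels.extend([t] * n_t)

    X = np.vstack(blocks).astype(np.float64)
    cells = [f"CELL{i:06d}" for i in range(X.shape[0])]
    store = ExpressionStore.from_arrays(
        sp.csr_matrix(X), genes, cells, pd.Series(labels, index=cells)
    )
    truth = SimulationTruth(
        marker_assignment={genes[i]: t for t, idx in marker_idx.items() for i in idx},
        strict_genes=frozenset(genes[strict_idx]),
        tolerant_genes=frozenset(genes[tol_idx]),
        dispersion=pd.Series(theta, index=genes, name="theta"),
    )
    return store, truth


def write_fixture(store: ExpressionStore, truth: SimulationTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as plain-text files.

    Produces ``matrix.mtx`` (genes-as-rows MatrixMarket), ``genes.txt``,
    ``cells.txt``, ``annotation.tsv`` plus ground-truth tables
    ``truth_markers.tsv`` and ``truth_dispersion.tsv``. The expression files
    round-trip losslessly through :func:`strictscreen.expression.load_matrix`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "matrix": "matrix.mtx", "genes": "genes.txt", "cells": "cells.txt",
        "annotation": "annotation.tsv", "markers": "truth_markers.tsv",
        "dispersion": "truth_dispersion.tsv",
    }.items()}
    X = store.values()
    mat = sp.coo_matrix(X.T if sp.issparse(X) else sp.csr_matrix(X).T)
    scipy.io.mmwrite(str(paths["matrix"]), mat)
    paths["genes"].write_text("\n".join(store.gene_ids) + "\n")
    paths["cells"].write_text("\n".join(store.cell_ids) + "\n")
    ann = pd.DataFrame({"cell_id": store.cell_ids, "cell_type": store.cell_types.to_numpy()})
    ann.to_csv(paths["annotation"], sep="\t", header=False, index=False)
    markers = pd.DataFrame(
        sorted(truth.marker_assignment.items()), columns=["gene", "cell_type"]
    )
    markers.to_csv(paths["markers"], sep="\t", index=False)
    cls = pd.Series("background", index=truth.dispersion.index, name="class")
    cls[list(truth.strict_genes)] = "strict"
    cls[list(truth.tolerant_genes)] = "tolerant"
    disp = pd.DataFrame({"gene": truth.dispersion.index, "theta": truth.dispersion.to_numpy(),
                         "class": cls.to_numpy()})
    disp.to_csv(paths["dispersion"], sep="\t", index=False)
    return paths


def load_fixture(out_dir: str | Path) -> ExpressionStore:
    """Reload a dataset written by :func:`write_fixture`."""
    out = Path(out_dir)
    return load_matrix(
        out / "matrix.mtx", out / "genes.txt", out / "cells.txt", out / "annotation.tsv",
        orientation="genes-as-rows",
    )
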