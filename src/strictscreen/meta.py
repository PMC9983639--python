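"""Combine per-dataset enrichment p-values across datasets.

A (cell type, panel) association observed in several independent datasets —
e.g. a discovery cohort plus replication and validation cohorts — is
summarized by combining the one-sided bootstrap p-values with Stouffer's
z-score method (unweighted by default; Fisher's method available), then
Bonferroni-adjusting over the pooled cell-type count of all contributing
datasets. Cell-type labels must be harmonized by the caller (an explicit
mapping table; no fuzzy matching).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

from .strictness import bonferroni_adjust

log = logging.getLogger(__name__)

__all__ = ["MetaResult", "combine_p", "meta_table", "harmonize_labels"]

_P_CLAMP = 1e-15


@dataclass
class MetaResult:
    """Meta-analytic summary for one (cell type, panel) pair."""

    cell_type: str
    panel: str
    per_dataset_p: tuple[tuple[str, float], ...]
    combined_p: float
    p_bonf: float
    n_tests: int
    method: str = "stouffer"


def combine_p(
    p_list: Sequence[float],
    weights: Sequence[float] | None = None,
    method: str = "stouffer",
) -> float:
    """Combine one-sided p-values across datasets.

    Stouffer (default): ``z_k = Phi^-1(1 - p_k)``; combined
    ``z = sum(w_k z_k) / sqrt(sum(w_k^2))`` with ``w_k = 1`` unless given;
    combined ``p = 1 - Phi(z)``. ``method="fisher"`` uses Fisher's
    chi-square statistic instead (unweighted).

    Boundary p-values (0 or 1) are clamped to ``[1e-15, 1 - 1e-15]`` with a
    warning; a single p is returned unchanged with a warning.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ((p <= 0) | (p >= 1)).any():
        log.warning("clamping boundary p-value(s) to [%g, %g]", _P_CLAMP, 1 - _P_CLAMP)
        p = np.clip(p, _P_CLAMP, 1 - _P_CLAMP)
    if p.size == 1:
        log.warning("single p-value: returned unchanged, nothing to combine")
        return float(p[0])
    if method == "stouffer":
        w = np.ones_like(p) if weights is None else np.asarray(list(weights), dtype=float)
        if w.shape != p.shape or (w <= 0).any():
            raise ValueError("weights must be positive and match p_list")
        z = norm.isf(p)
        return float(norm.sf((w * z).sum() / np.sqrt((w**2).sum())))
    if method == "fisher":
        chi2 = -2.0 * np.log(p).sum()
        return float(stats.chi2.sf(chi2, 2 * p.size))
    raise ValueError(f"unknown method {method!r}")


def harmonize_labels(table: pd.DataFrame, mapping: Mapping[tuple[str, str], str]) -> pd.DataFrame:
    """Replace each dataset's local cell-type label by its harmonized label.

    ``mapping`` keys are ``(dataset, local_label)``; rows without a mapping
    keep their local label.
    """
    out = table.copy()
    out["cell_type"] = [
        mapping.get((d, c), c) for d, c in zip(out["dataset"], out["cell_type"])
    ]
    return out


def meta_table(
    results: pd.DataFrame,
    n_tests: int | None = None,
    weights: Mapping[str, float] | None = None,
    method: str = "stouffer",
) -> list[MetaResult]:
    """Combine per-dataset enrichment rows into one result per pair.

    ``results`` needs columns ``dataset``, ``cell_type``, ``panel``, ``p``
    (one row per dataset per pair; harmonized labels). Pairs present in
    fewer than two datasets are excluded with a warning. ``n_tests``
    defaults to the pooled cell-type count — the sum over datasets of the
    number of distinct cell types each contributes — which is the
    Bonferroni family for the combined p-values.
    """
    required = {"dataset", "cell_type", "panel", "p"}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    dup = results.duplicated(["dataset", "cell_type", "panel"])
    if dup.any():
        raise ValueError("each dataset may contribute at most one p per (cell type, panel)")
    if n_tests is None:
        n_tests = int(results.groupby("dataset")["cell_type"].nunique().sum())
    out: list[MetaResult] = []
    for (ct, panel), grp in results.groupby(["cell_type", "panel"], sort=True):
        if len(grp) < 2:
            log.warning("(%s, %s) present in one dataset only; excluded from meta", ct, panel)
            continue
        grp = grp.sort_values("dataset")
        w = None if weights is None else [weights[d] for d in grp["dataset"]]
        combined = combine_p(grp["p"].to_numpy(), weights=w, method=method)
        out.append(
            MetaResult(
                cell_type=str(ct),
                panel=str(panel),
                per_dataset_p=tuple(zip(grp["dataset"].astype(str), grp["p"].astype(float))),
                combined_p=combined,
                p_bonf=bonferroni_adjust(max(combined, 1e-300), n_tests),
                n_tests=n_tests,
                method=method,
            )
        )
    if not out:
        raise ValueError("no (cell type, panel) pair shared by >= 2 datasets")
    return out


def meta_frame(results: list[MetaResult]) -> pd.DataFrame:
    """Meta results as a table (dataset p-values semicolon-joined)."""
    return pd.DataFrame(
        [
            {
                "cell_type": r.cell_type,
                "panel": r.panel,
                "dataset_ps": ";".join(f"{d}:{p:.6g}" for d, p in r.per_dataset_p),
                "combined_p": r.combined_p,
                "n_tests": r.n_tests,
                "p_bonf": r.p_bonf,
                "method": r.method,
            }
            for r in results
        ]
    )
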