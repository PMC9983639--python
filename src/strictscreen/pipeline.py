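"""End-to-end orchestration: panels -> enrichment -> strictness -> meta.

One :class:`RunConfig` (usually parsed from YAML) describes the datasets,
panels, and statistical settings; :func:`run_all` executes every stage,
writes TSV tables plus a JSON manifest into the output directory, and is
deterministic under a fixed seed. Multiple-testing policy: FDR across cell
types within each dataset's enrichment stage, Bonferroni over the pooled
cell-type count at the meta stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import ExpressionStore, load_matrix, mean_by_celltype, normalize_cpm
from .ewce import bootstrap_enrichment, enrichment_table, specificity_matrix
from .meta import harmonize_labels, meta_frame, meta_table
from .panels import GenePanel, load_panel, overlap_report
from .strictness import panel_compare

log = logging.getLogger(__name__)

__all__ = ["DatasetConfig", "RunConfig", "run_all"]


@dataclass(frozen=True)
class DatasetConfig:
    label: str
    matrix: str
    annotation: str
    genes: str | None = None
    cells: str | None = None
    orientation: str = "genes-as-rows"
    normalize: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Settings for one full run."""

    datasets: tuple[DatasetConfig, ...]
    panels: tuple[str, ...]
    output_dir: str
    n_boot: int = 10_000
    seed: int = 1
    min_cells_per_type: int = 10
    scope: str = "global-ref"
    harmonization_map: str | None = None

    def __post_init__(self) -> None:
        if not self.datasets or not self.panels:
            raise ValueError("need >= 1 dataset and >= 1 panel")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        datasets = tuple(DatasetConfig(**d) for d in raw.pop("datasets"))
        panels = tuple(raw.pop("panels"))
        return cls(datasets=datasets, panels=panels, **raw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {
            "datasets": [vars(d) for d in config.datasets],
            "panels": list(config.panels),
            "n_boot": config.n_boot,
            "seed": config.seed,
            "min_cells_per_type": config.min_cells_per_type,
            "scope": config.scope,
            "harmonization_map": config.harmonization_map,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_harmonization(path: str | Path) -> dict[tuple[str, str], str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"dataset", "local_label", "harmonized_label"}
    if not need.issubset(df.columns):
        raise ValueError(f"harmonization map needs columns {sorted(need)}")
    return {(r.dataset, r.local_label): r.harmonized_label for r in df.itertuples()}


def _load_dataset(d: DatasetConfig) -> ExpressionStore:
    store = load_matrix(d.matrix, d.genes, d.cells, d.annotation, orientation=d.orientation)
    return normalize_cpm(store) if d.normalize else store


def run_all(config: RunConfig) -> dict[str, object]:
    """Run every stage; return tables and write them under ``output_dir``.

    Stages: panel overlaps; per-dataset enrichment (one TSV per dataset) and
    strictness across each dataset's retained cell types; meta-analysis when
    at least two datasets are configured (skipped with a warning otherwise);
    a JSON manifest with versions, seed, and a config hash.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    panels = [load_panel(p) for p in config.panels]

    overlaps = overlap_report(panels) if len(panels) > 1 else pd.DataFrame()
    if not overlaps.empty:
        overlaps.to_csv(out / "panel_overlaps.tsv", sep="\t", index=False)

    enrich_frames, strict_frames = [], []
    pooled_celltypes = 0
    for i, d in enumerate(config.datasets):
        t_stage = time.time()
        store = _load_dataset(d)
        means = mean_by_celltype(store, min_cells_per_type=config.min_cells_per_type)
        spec = specificity_matrix(means)
        pooled_celltypes += len(spec.cell_type_ids)
        rows = []
        for j, panel in enumerate(panels):
            res = bootstrap_enrichment(
                spec, panel, n_boot=config.n_boot, seed=config.seed + 1000 * i + j
            )
            tab = enrichment_table(res)
            tab.insert(0, "panel", panel.name)
            rows.append(tab)
        enr = pd.concat(rows, ignore_index=True)
        enr.insert(0, "dataset", d.label)
        enr.to_csv(out / f"enrichment_{d.label}.tsv", sep="\t", index=False)
        enrich_frames.append(enr)

        populations = list(means.n_cells.index)
        stab = panel_compare(
            store, panels, populations,
            n_boot=config.n_boot, seed=config.seed + 7000 + i, scope=config.scope,
        )
        stab.insert(0, "dataset", d.label)
        stab.to_csv(out / f"strictness_{d.label}.tsv", sep="\t", index=False)
        strict_frames.append(stab)
        log.info("dataset %s done in %.1fs (%d cell types, %d genes)",
                 d.label, time.time() - t_stage, len(spec.cell_type_ids), store.n_genes)

    enrichment = pd.concat(enrich_frames, ignore_index=True)
    strictness = pd.concat(strict_frames, ignore_index=True)

    meta = pd.DataFrame()
    if len(config.datasets) >= 2:
        per_ds = enrichment[["dataset", "cell_type", "panel", "p"]]
        if config.harmonization_map:
            per_ds = harmonize_labels(per_ds, _load_harmonization(config.harmonization_map))
        meta = meta_frame(meta_table(per_ds, n_tests=pooled_celltypes))
        meta.to_csv(out / "meta.tsv", sep="\t", index=False)
    else:
        log.warning("single dataset: meta-analysis stage skipped")

    manifest = {
        "package": "strictscreen",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "config_hash": _config_hash(config),
        "pooled_cell_types": pooled_celltypes,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {
        "enrichment": enrichment,
        "strictness": strictness,
        "meta": meta,
        "overlaps": overlaps,
        "manifest": manifest,
    }
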