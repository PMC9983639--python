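"""Disease and control gene panels.

A :class:`GenePanel` is a named, ordered set of gene symbols (a disease gene
list curated from OMIM, GWAS, or similar sources). Panels are the query gene
sets for both the cell-type enrichment test and the strictness test. Symbols
are uppercase-normalized so that human panels can be scored against mouse
datasets (human ``SOD1`` matches mouse ``Sod1``); no ortholog table is used —
matching is by case-insensitive symbol equality only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "GenePanel",
    "PanelOverlap",
    "load_panel",
    "load_gmt",
    "intersect",
    "restrict_to_universe",
    "overlap_report",
]


def _normalize(symbols: Iterable[str]) -> list[str]:
    """Trim, uppercase, and deduplicate symbols, keeping first occurrence."""
    seen: dict[str, None] = {}
    n_dup = 0
    for raw in symbols:
        sym = raw.strip().upper()
        if not sym:
            continue
        if sym in seen:
            n_dup += 1
            continue
        seen[sym] = None
    if n_dup:
        log.warning("dropped %d duplicate symbol(s) after normalization", n_dup)
    return list(seen)


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols with provenance.

    Parameters
    ----------
    name
        Panel label, e.g. ``"ALS-pathogenicity"``.
    genes
        Ordered, uppercase-normalized, duplicate-free gene symbols.
    source
        Free-text provenance, e.g. ``"OMIM PS105400"`` or ``"GWAS"``.
    """

    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.name!r} contains duplicate symbols")

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str], source: str = "") -> "GenePanel":
        """Build a panel, normalizing symbols (trim / uppercase / dedup)."""
        return cls(name=name, genes=tuple(_normalize(symbols)), source=source)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in set(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class PanelOverlap:
    """Pairwise overlap between two panels."""

    panel_a: str
    panel_b: str
    shared: frozenset[str]
    count_a: int
    count_b: int
    count_shared: int

    def __post_init__(self) -> None:
        if self.count_shared > min(self.count_a, self.count_b):
            raise ValueError("count_shared exceeds a panel size")


def load_panel(path: str | Path, name: str | None = None, source: str = "") -> GenePanel:
    """Load a panel from a plain-text file, one symbol per line.

    Lines starting with ``#`` are comments. Symbols are trimmed, uppercased,
    and deduplicated preserving first occurrence.

    Raises
    ------
    ValueError
        If the file contains no symbols ("empty panel").
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    symbols = [ln for ln in (s.strip() for s in lines) if ln and not ln.startswith("#")]
    if not symbols:
        raise ValueError(f"empty panel: {path}")
    return GenePanel.from_symbols(name or path.stem, symbols, source=source or str(path))


def load_gmt(path: str | Path) -> list[GenePanel]:
    """Load panels from a GMT file (tab-separated: name, description, symbols...)."""
    path = Path(path)
    panels: list[GenePanel] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT row needs name, description, >=1 symbol")
        panels.append(GenePanel.from_symbols(fields[0], fields[2:], source=fields[1]))
    if not panels:
        raise ValueError(f"empty panel: {path}")
    return panels


def intersect(a: GenePanel, b: GenePanel) -> PanelOverlap:
    """Intersection of two panels under normalized symbols."""
    shared = a.gene_set & b.gene_set
    return PanelOverlap(
        panel_a=a.name,
        panel_b=b.name,
        shared=frozenset(shared),
        count_a=len(a),
        count_b=len(b),
        count_shared=len(shared),
    )


def restrict_to_universe(
    panel: GenePanel, universe: Iterable[str]
) -> tuple[GenePanel, tuple[str, ...]]:
    """Restrict a panel to a dataset's gene universe (case-insensitive).

    Returns the restricted panel plus the dropped symbols. The restricted
    panel keeps the panel's own (uppercase) symbol spelling.

    Raises
    ------
    ValueError
        If the universe is empty, or if no panel symbol is found in it
        ("panel disjoint from dataset").
    """
    uni = {u.strip().upper() for u in universe}
    if not uni:
        raise ValueError("empty universe")
    retained = tuple(g for g in panel.genes if g in uni)
    dropped = tuple(g for g in panel.genes if g not in uni)
    if not retained:
        raise ValueError(f"panel {panel.name!r} disjoint from dataset")
    if dropped:
        log.info("panel %s: %d/%d symbols not in dataset", panel.name, len(dropped), len(panel))
    return GenePanel(panel.name, retained, panel.source), dropped


def overlap_report(panels: Sequence[GenePanel]) -> "pandas.DataFrame":  # noqa: F821
    """All pairwise overlaps as a table.

    Columns: panel_a, panel_b, count_a, count_b, count_shared, shared
    (comma-joined, sorted).
    """
    import pandas as pd

    rows = []
    for i, a in enumerate(panels):
        for b in panels[i + 1 :]:
            ov = intersect(a, b)
            rows.append(
                {
                    "panel_a": ov.panel_a,
                    "panel_b": ov.panel_b,
                    "count_a": ov.count_a,
                    "count_b": ov.count_b,
                    "count_shared": ov.count_shared,
                    "shared": ",".join(sorted(ov.shared)),
                }
            )
    return pd.DataFrame(rows, columns=["panel_a", "panel_b", "count_a", "count_b", "count_shared", "shared"])
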