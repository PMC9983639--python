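"""Bundled disease gene panels.

The six panels (ALS-pathogenicity, ALS-susceptibility, HMN, SA, SMA, SPG)
are synthetic reconstructions assembled from public OMIM/GWAS domain
knowledge; they reproduce the curated panels' sizes (32, 48, 36, 15, 20,
57 genes) and the documented pairwise overlaps (pathogenicity and
susceptibility share exactly C9ORF72, KIF5A, NEK1, SOD1, TBK1; HMN and
SMA share five genes), but they are stand-ins, not authoritative
published curations.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..panels import GenePanel, load_panel

_PANEL_FILES = {
    "ALS-pathogenicity": "als_pathogenicity.synthetic.txt",
    "ALS-susceptibility": "als_susceptibility.synthetic.txt",
    "HMN": "hmn.synthetic.txt",
    "SA": "sa.synthetic.txt",
    "SMA": "sma.synthetic.txt",
    "SPG": "spg.synthetic.txt",
}

__all__ = ["available_panels", "bundled_panel", "bundled_panel_path"]


def available_panels() -> tuple[str, ...]:
    """Names of the bundled disease panels."""
    return tuple(_PANEL_FILES)


def bundled_panel_path(name: str) -> Path:
    """Filesystem path of a bundled panel file."""
    try:
        fname = _PANEL_FILES[name]
    except KeyError:
        raise KeyError(f"unknown panel {name!r}; choose from {sorted(_PANEL_FILES)}") from None
    return Path(str(resources.files(__package__) / "panels" / fname))


def bundled_panel(name: str) -> GenePanel:
    """Load a bundled panel by name (e.g. ``"ALS-pathogenicity"``)."""
    return load_panel(bundled_panel_path(name), name=name, source="bundled synthetic reconstruction")
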