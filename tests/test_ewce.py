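import itertools

import numpy as np
import pandas as pd
import pytest

from strictscreen.expression import CellTypeMeans, mean_by_celltype, normalize_cpm
from strictscreen.ewce import (
    bootstrap_enrichment,
    enrichment_table,
    fdr_adjust,
    size_power_scan,
    specificity_matrix,
)
from strictscreen.panels import GenePanel


def make_spec(spec_df: pd.DataFrame):
    """Build a SpecificityMatrix from per-type means given as genes x types."""
    means = CellTypeMeans(
        means=spec_df.T, n_cells=pd.Series(1, index=spec_df.columns)
    )
    return specificity_matrix(means)


class TestSpecificity:
    def test_hand_proportions(self):
        spec = make_spec(pd.DataFrame({"A": [3.0], "B": [1.0]}, index=["g1"]))
        assert spec.spec.loc["g1", "A"] == pytest.approx(0.75)
        assert spec.spec.loc["g1", "B"] == pytest.approx(0.25)

    def test_single_support_and_symmetry(self):
        df = pd.DataFrame(
            {"A": [5.0, 2.0], "B": [0.0, 2.0], "C": [0.0, 2.0], "D": [0.0, 2.0]},
            index=["only_a", "flat"],
        )
        spec = make_spec(df)
        assert spec.spec.loc["only_a"].to_list() == [1.0, 0.0, 0.0, 0.0]
        np.testing.assert_allclose(spec.spec.loc["flat"], 0.25)

    def test_zero_gene_flagged_unusable(self):
        spec = make_spec(pd.DataFrame({"A": [0.0, 1.0], "B": [0.0, 1.0]}, index=["dead", "ok"]))
        assert not spec.usable["dead"] and spec.usable["ok"]
        assert spec.spec.loc["dead"].sum() == 0.0
        assert list(spec.usable_genes) == ["OK"] or list(spec.usable_genes) == ["ok"]

    def test_rows_sum_to_one_on_simulation(self, sim_default):
        store, _ = sim_default
        spec = specificity_matrix(mean_by_celltype(normalize_cpm(store)))
        sums = spec.spec.loc[spec.usable_genes].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, rtol=1e-9)


def exhaustive_enrichment_p(spec_values: np.ndarray, target_idx, cell_type: int) -> float:
    """Exact upper-tail proportion over all same-size subsets (ties to the tail)."""
    s = len(target_idx)
    observed = spec_values[list(target_idx), cell_type].sum()
    sums = [
        spec_values[list(combo), cell_type].sum()
        for combo in itertools.combinations(range(spec_values.shape[0]), s)
    ]
    return float(np.mean([x >= observed - 1e-12 for x in sums]))


class TestBootstrapEnrichment:
    def test_matches_exhaustive_enumeration_small_universe(self):
        rng = np.random.default_rng(5)
        raw = rng.gamma(1.0, 1.0, size=(4, 3))
        df = pd.DataFrame(raw, index=[f"g{i}" for i in range(4)], columns=["A", "B", "C"])
        spec = make_spec(df)
        panel = GenePanel.from_symbols("t", ["g0", "g2"])
        res = bootstrap_enrichment(spec, panel, n_boot=10_000, seed=11)
        vals = spec.spec.to_numpy()
        for j, r in enumerate(res):
            exact = exhaustive_enrichment_p(vals, [0, 2], j)
            # +1/(n+1) pseudo-count keeps p above the exact proportion slightly
            assert r.p == pytest.approx(exact, abs=0.02)

    def test_whole_universe_target_gives_p_one(self):
        df = pd.DataFrame(
            np.random.default_rng(0).gamma(1, 1, (5, 2)),
            index=[f"g{i}" for i in range(5)], columns=["A", "B"],
        )
        spec = make_spec(df)
        res = bootstrap_enrichment(spec, GenePanel.from_symbols("all", df.index), seed=3)
        assert all(r.p == 1.0 for r in res)

    def test_target_too_small_rejected(self):
        df = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [1.0, 1.0, 1.0]},
                          index=["g0", "g1", "g2"])
        with pytest.raises(ValueError, match="too small"):
            bootstrap_enrichment(make_spec(df), GenePanel.from_symbols("one", ["g0"]))

    def test_fixed_seed_reproducible(self, sim_default):
        store, truth = sim_default
        spec = specificity_matrix(mean_by_celltype(store))
        panel = GenePanel.from_symbols("m", truth.markers_of("CT00"))
        a = bootstrap_enrichment(spec, panel, n_boot=500, seed=42)
        b = bootstrap_enrichment(spec, panel, n_boot=500, seed=42)
        assert [(r.p, r.observed, r.boot_mean) for r in a] == [
            (r.p, r.observed, r.boot_mean) for r in b
        ]

    def test_p_has_pseudocount_floor_and_table_shape(self, sim_default):
        store, truth = sim_default
        spec = specificity_matrix(mean_by_celltype(store))
        panel = GenePanel.from_symbols("m", truth.markers_of("CT01"))
        res = bootstrap_enrichment(spec, panel, n_boot=200, seed=9)
        tab = enrichment_table(res)
        assert (tab.p >= 1 / 201).all() and (tab.p_fdr >= tab.p).all()
        assert list(tab.columns) == [
            "cell_type", "n_target", "observed", "boot_mean", "boot_sd", "p", "p_fdr",
        ]


class TestFdrAdjust:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_known_adjustments(self, raw, expected):
        np.testing.assert_allclose(fdr_adjust(raw), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            fdr_adjust([1.5])

    def test_matches_statsmodels_and_dominates_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1.0, 40)
        adj = np.array(fdr_adjust(p))
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


class TestSizePowerScan:
    def test_full_size_matches_full_panel_call(self, sim_default):
        store, truth = sim_default
        spec = specificity_matrix(mean_by_celltype(store))
        panel = GenePanel.from_symbols("m", truth.markers_of("CT02"))
        scan = size_power_scan(spec, panel, sizes=[len(panel)], n_rep=2, n_boot=500, seed=4)
        full = bootstrap_enrichment(spec, panel, n_boot=500, seed=99)
        calls = {r.cell_type: float(r.p_fdr < 0.05) for r in full}
        for ct in scan.columns:
            assert scan.loc[len(panel), ct] == calls[str(ct)]

    def test_size_outside_panel_rejected(self, sim_default):
        store, truth = sim_default
        spec = specificity_matrix(mean_by_celltype(store))
        panel = GenePanel.from_symbols("m", truth.markers_of("CT00"))
        with pytest.raises(ValueError, match="outside"):
            size_power_scan(spec, panel, sizes=[len(panel) + 1], n_rep=1, n_boot=200)

    def test_power_rises_with_panel_size(self, sim_default):
        store, truth = sim_default
        spec = specificity_matrix(mean_by_celltype(normalize_cpm(store)))
        panel = GenePanel.from_symbols("m", truth.markers_of("CT03"))
        scan = size_power_scan(spec, panel, sizes=[3, 10, 25], n_rep=10, n_boot=1000, seed=8)
        power = scan["CT03"]
        assert power.loc[25] >= power.loc[3] - 0.15  # non-decreasing within MC error
        assert power.loc[25] >= 0.9
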