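import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from strictscreen.panels import GenePanel
from strictscreen.strictness import (
    DEGENERATE_SD,
    bonferroni_adjust,
    fold_change,
    geneset_strictness_test,
    panel_compare,
    strictness,
    strictness_all,
)

from conftest import random_store


class TestFoldChange:
    def test_hand_division(self):
        np.testing.assert_allclose(fold_change([1, 2, 3], 2.0), [0.5, 1.0, 1.5])

    def test_constant_expression_gives_unit_fold_change(self):
        np.testing.assert_array_equal(fold_change([4.0, 4.0, 4.0], 4.0), [1.0, 1.0, 1.0])

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="unusable"):
            fold_change([1.0, 2.0], 0.0)


class TestStrictness:
    def test_hand_value(self):
        # C = [0.5, 1.0, 1.5]: sum of squared deviations 0.5, /(n-1) = 0.25, SD 0.5
        assert strictness([0.5, 1.0, 1.5]).S == pytest.approx(2.0)

    def test_zero_variance_is_degenerate(self):
        v = strictness([1.0, 1.0, 1.0])
        assert v.degenerate and v.S == pytest.approx(1.0 / DEGENERATE_SD)

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            strictness([1.0])

    @given(
        expr=st.lists(st.floats(0.01, 100.0), min_size=3, max_size=30),
        k=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, expr, k):
        e = np.asarray(expr)
        if e.std(ddof=1) / e.mean() < 1e-9:
            return  # degenerate inputs carry no strictness
        s1 = strictness(fold_change(e, e.mean())).S
        s2 = strictness(fold_change(k * e, (k * e).mean())).S
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_strictly_decreasing_in_fold_change_sd(self):
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.1, 50)
        widened = 1.0 + (base - 1.0) * 2.5
        assert strictness(base).S > strictness(widened).S


class TestStrictnessAll:
    @pytest.mark.parametrize("scope", ["global-ref", "within-type"])
    def test_matches_per_gene_loop(self, scope):
        rng = np.random.default_rng(21)
        store = random_store(rng, n_cells=30, n_genes=8, n_types=2)
        table = strictness_all(store, cell_type="T0", scope=scope)
        X = store.values(dense=True)
        mask = (store.cell_types == "T0").to_numpy()
        for j, g in enumerate(store.gene_ids):
            ref = X[:, j].mean() if scope == "global-ref" else X[mask, j].mean()
            expected = strictness(fold_change(X[mask, j], ref)).S
            assert table.loc[g, "S"] == pytest.approx(expected, rel=1e-9)

    def test_unusable_and_degenerate_flags(self):
        from strictscreen.expression import ExpressionStore

        values = np.array([[0.0, 2.0, 1.0], [0.0, 2.0, 3.0]])
        store = ExpressionStore.from_arrays(
            values, ["dead", "flat", "ok"], ["c1", "c2"], {"c1": "A", "c2": "A"}
        )
        t = strictness_all(store)
        assert not t.loc["DEAD", "usable"]
        assert t.loc["FLAT", "degenerate"]
        assert t.loc["OK", "usable"] and not t.loc["OK", "degenerate"]

    def test_unknown_population_rejected(self, tiny_store):
        with pytest.raises(ValueError, match="no cells"):
            strictness_all(tiny_store, cell_type="missing")


@pytest.fixture(scope="module")
def s_table(sim_default):
    store, _ = sim_default
    return strictness_all(store, cell_type="CT00")


class TestGenesetTest:
    def test_normal_tail_relation(self, s_table, sim_default):
        _, truth = sim_default
        panel = GenePanel.from_symbols("strict", truth.strict_genes)
        t = geneset_strictness_test(s_table, panel, n_boot=2000, seed=5)
        z = (t.observed_mean - t.null_mu) / t.null_sigma
        assert t.p == pytest.approx(float(norm.sf(z)))
        assert 0 < t.p < 1

    def test_normal_p_close_to_empirical_tail(self, s_table):
        rng = np.random.default_rng(17)
        universe = s_table.index[(s_table.usable & ~s_table.degenerate).to_numpy()]
        panel = GenePanel.from_symbols("rand", rng.choice(universe, 25, replace=False))
        t = geneset_strictness_test(s_table, panel, n_boot=10_000, seed=6)
        assert t.p == pytest.approx(t.empirical_p, abs=0.01)

    def test_small_panel_rejected(self, s_table):
        with pytest.raises(ValueError, match="too small"):
            geneset_strictness_test(s_table, GenePanel.from_symbols("p", [s_table.index[0]]))

    def test_seeded_determinism(self, s_table, sim_default):
        _, truth = sim_default
        panel = GenePanel.from_symbols("tol", truth.tolerant_genes)
        a = geneset_strictness_test(s_table, panel, n_boot=1000, seed=3)
        b = geneset_strictness_test(s_table, panel, n_boot=1000, seed=3)
        assert (a.p, a.null_mu, a.null_sigma) == (b.p, b.null_mu, b.null_sigma)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,n,expected",
        [(0.001, 56, 0.056), (0.2, 1, 0.2), (0.5, 10, 1.0)],
    )
    def test_known_values(self, p, n, expected):
        assert bonferroni_adjust(p, n) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.0, 5)
        with pytest.raises(ValueError):
            bonferroni_adjust(0.5, 0)


class TestPanelCompare:
    def test_ground_truth_separation(self, sim_default):
        store, truth = sim_default
        strict_p = GenePanel.from_symbols("strict-like", truth.strict_genes)
        tol_p = GenePanel.from_symbols("tolerant-like", truth.tolerant_genes)
        tab = panel_compare(store, [strict_p, tol_p], ["CT00", "CT01"], n_boot=2000, seed=2)
        assert len(tab) == 4
        strict_rows = tab[tab.panel == "strict-like"]
        tol_rows = tab[tab.panel == "tolerant-like"]
        assert (strict_rows.p_bonf < 0.05).all()
        assert (tol_rows.p > 0.05).all()
        # Bonferroni family = number of populations tested
        np.testing.assert_allclose(
            tab.p_bonf, np.minimum(1.0, tab.p * 2), rtol=1e-12
        )

    def test_empty_inputs_rejected(self, sim_default):
        store, truth = sim_default
        with pytest.raises(ValueError, match=">= 1"):
            panel_compare(store, [], ["CT00"])
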