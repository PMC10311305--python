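import numpy as np
import pytest

from cellbrf import (
    ImportanceVector,
    SelectionConfig,
    dynamic_threshold,
    redundancy_prune,
    select_features,
    three_sigma_cut,
)

from conftest import make_matrix
from oracles import oracle_pearson, oracle_redundancy_scan


def importance_from(f):
    return ImportanceVector(f=np.asarray(f, dtype=float), n_trees=1)


class TestThreeSigmaCut:
    def test_spike_over_flat_background(self):
        f = np.full(100, 0.01)
        f[17] = 0.5
        imp = importance_from(f)
        # independent mu + 3 sigma arithmetic
        cutoff = f.mean() + 3 * f.std()
        assert 0.01 < cutoff < 0.5
        assert three_sigma_cut(imp) == [17]

    def test_all_equal_selects_everything(self):
        imp = importance_from(np.full(10, 0.1))
        assert three_sigma_cut(imp) == list(range(10))

    def test_matches_exhaustive_filter_on_ramp(self):
        # convex ramp: a thin top tail clears the mu + 3 sigma cut
        f = np.linspace(1.0, 0.0, 1000) ** 8
        imp = importance_from(f)
        expected = [i for i in range(1000) if f[i] >= f.mean() + 3 * f.std()]
        assert len(expected) > 0
        assert three_sigma_cut(imp) == expected

    def test_sorted_by_importance_descending(self, rng):
        f = rng.random(50) ** 4
        result = three_sigma_cut(importance_from(f))
        assert list(f[result]) == sorted(f[result], reverse=True)

    def test_empty_cut_falls_back_to_top_gene(self):
        # heavy-tailed negative skew: no value reaches mu + 3 sigma
        f = np.array([0.5, 0.5, 0.5, 0.5, 0.0])
        imp = importance_from(f)
        assert (f >= imp.mu + 3 * imp.sigma).sum() == 0
        with pytest.warns(UserWarning, match="top gene"):
            assert three_sigma_cut(imp) == [0]


class TestDynamicThreshold:
    @pytest.mark.parametrize("L,expected", [(1, 0.85), (4, 0.82)])
    def test_known_values(self, L, expected):
        assert dynamic_threshold(SelectionConfig(), L) == pytest.approx(expected)

    def test_monotone_decreasing_to_v(self):
        cfg = SelectionConfig()
        vals = [dynamic_threshold(cfg, L) for L in range(200)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(cfg.v, abs=1e-3)


class TestRedundancyPrune:
    def test_identical_columns_lower_importance_removed(self, rng):
        vals = np.abs(rng.normal(3, 1, size=(3, 40)))
        vals[1] = vals[0]
        m = make_matrix(vals, layer="lognorm")
        sel = redundancy_prune(m, ["g0", "g1", "g2"])
        assert "g0" in sel.ordered_genes
        assert [r.gene for r in sel.removed] == ["g1"]
        assert sel.removed[0].removed_by == "g0"
        assert sel.removed[0].correlation == pytest.approx(1.0)

    def test_orthogonal_genes_all_survive(self, rng):
        vals = np.abs(rng.normal(5, 1, size=(6, 200)))
        m = make_matrix(vals, layer="lognorm")
        genes = [f"g{i}" for i in range(6)]
        sel = redundancy_prune(m, genes)
        assert sel.ordered_genes == genes
        assert sel.removed == []

    def test_matches_manual_scan_oracle(self, rng):
        # six genes with strong pairwise correlations via shared factors
        base = rng.normal(size=(3, 60))
        vals = np.vstack([
            base[0],
            base[0] + 0.1 * rng.normal(size=60),
            base[1],
            base[0] + 0.15 * rng.normal(size=60),
            base[1] + 0.1 * rng.normal(size=60),
            base[2],
        ])
        vals -= vals.min()
        m = make_matrix(vals, layer="lognorm")
        genes = [f"g{i}" for i in range(6)]
        corr = {
            (a, b): oracle_pearson(vals[i], vals[j])
            for i, a in enumerate(genes)
            for j, b in enumerate(genes)
            if i < j
        }
        survivors, removed = oracle_redundancy_scan(genes, corr, v=0.8, v_prime=0.1)
        sel = redundancy_prune(m, genes)
        assert sel.ordered_genes == survivors
        assert [r.gene for r in sel.removed] == removed
        assert len(removed) > 0  # fixture actually exercises removals

    def test_zero_variance_gene_never_removed(self, rng):
        vals = np.abs(rng.normal(3, 1, size=(3, 30)))
        vals[2] = 4.0  # constant gene
        m = make_matrix(vals, layer="lognorm")
        with pytest.warns(UserWarning, match="zero variance"):
            sel = redundancy_prune(m, ["g0", "g1", "g2"])
        assert "g2" in sel.ordered_genes

    def test_anticorrelated_genes_kept(self, rng):
        a = rng.normal(5, 1, size=40)
        vals = np.vstack([a, 10 - a + 0.01 * rng.normal(size=40)])
        vals -= vals.min()
        m = make_matrix(vals, layer="lognorm")
        sel = redundancy_prune(m, ["g0", "g1"])
        # signed correlation ~ -1 never exceeds the (positive) threshold
        assert sel.ordered_genes == ["g0", "g1"]

    def test_correlation_matches_direct_formula(self, rng):
        vals = np.abs(rng.normal(3, 1, size=(2, 50)))
        vals[1] = vals[0] * 1.3 + rng.normal(0, 0.05, size=50)
        vals -= vals.min()
        m = make_matrix(vals, layer="lognorm")
        sel = redundancy_prune(m, ["g0", "g1"])
        s = oracle_pearson(vals[0], vals[1])
        if sel.removed:
            assert sel.removed[0].correlation == pytest.approx(s, abs=1e-12)

    def test_top_gene_never_removed(self, rng):
        vals = np.abs(rng.normal(3, 1, size=(5, 30)))
        vals[1] = vals[0]
        vals[2] = vals[0]
        m = make_matrix(vals, layer="lognorm")
        genes = [f"g{i}" for i in range(5)]
        sel = redundancy_prune(m, genes)
        assert sel.ordered_genes[0] == "g0"


class TestSelectFeatures:
    def test_output_ordered_by_importance(self, rng):
        vals = np.abs(rng.normal(3, 1, size=(30, 50)))
        m = make_matrix(vals, layer="lognorm")
        f = rng.random(30) ** 6
        imp = ImportanceVector(f=f, n_trees=1)
        sel = select_features(m, imp)
        imps = [f[m.gene_index(g)] for g in sel.ordered_genes]
        assert imps == sorted(imps, reverse=True)

    def test_duplicate_groups_reduced_to_single_survivor(self, rng):
        g, c = 400, 60
        vals = np.abs(rng.normal(3, 1, size=(g, c)))
        f = np.full(g, 0.0005)
        for src, dst in [(0, 30), (1, 31), (2, 32)]:
            vals[dst] = vals[src]
            f[src] = 0.2
            f[dst] = 0.15
        m = make_matrix(vals, layer="lognorm")
        sel = select_features(m, ImportanceVector(f=f, n_trees=1))
        for src, dst in [(0, 30), (1, 31), (2, 32)]:
            kept = {f"g{src}", f"g{dst}"} & set(sel.ordered_genes)
            assert len(kept) == 1
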