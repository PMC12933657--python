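"""Synthetic-data generators: determinism and distributional ground truth."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import divpath as dp


class TestSimulateTree:
    def test_pure_birth_is_ultrametric(self):
        t = dp.simulate_tree(1.0, 0.0, 5, seed=1)
        assert t.n_tips == 5
        assert t.is_ultrametric()

    def test_seed_determinism(self):
        a = dp.simulate_tree(1.0, 0.0, 5, seed=1).to_newick()
        b = dp.simulate_tree(1.0, 0.0, 5, seed=1).to_newick()
        assert a == b
        c = dp.simulate_tree(1.0, 0.0, 5, seed=2).to_newick()
        assert a != c

    def test_yule_mean_root_age(self):
        """Root age of an n-tip Yule tree has mean sum_{k=2..n} 1/(k b)."""
        n, b, reps = 8, 1.0, 1000
        expected = sum(1.0 / (k * b) for k in range(2, n + 1))
        ages = [dp.simulate_tree(b, 0.0, n, seed=s).tip_depths().mean()
                for s in range(reps)]
        se = np.std(ages) / np.sqrt(reps)
        assert abs(np.mean(ages) - expected) < 4 * se

    def test_birth_death_prunes_extinct(self):
        t = dp.simulate_tree(1.0, 0.5, 20, seed=3)
        assert t.n_tips == 20

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            dp.simulate_tree(0.0, 0.0, 5, seed=1)


class TestSimulateBm:
    def test_zero_rate_constant(self, yule50):
        vals = dp.simulate_bm(yule50, {0: 0.0}, {yule50.root: 0}, 3.0, seed=1)
        assert np.allclose(vals, 3.0)

    def test_star_tree_variance(self):
        star = dp.PhyloTree.from_newick("(" + ",".join(f"t{i}:1" for i in range(40)) + "):0;")
        draws = np.concatenate([
            dp.simulate_bm(star, {0: 1.0}, {star.root: 0}, 0.0, seed=s).to_numpy()
            for s in range(50)
        ])  # 2000 independent BM endpoints, variance sigma^2 * t = 1
        assert abs(draws.var() - 1.0) < 0.15

    def test_two_regime_covariance(self, yule50):
        """Sample covariance matches the regime-weighted expectation."""
        shift_node = next(v for v in range(yule50.n_nodes)
                          if yule50.children(v) and v != yule50.root
                          and len(yule50.subtree_tips(v)) >= 10)
        shifts = {yule50.root: 0, shift_node: 1}
        sig = {0: 1.0, 1: 10.0}
        from divpath.trait_rates import regime_weighted_vcv
        Ws = regime_weighted_vcv(yule50, shifts)
        expected = sum(sig[r] * W for r, W in Ws.items())
        X = np.stack([
            dp.simulate_bm(yule50, sig, shifts, 0.0, seed=s).to_numpy()
            for s in range(2000)
        ])
        emp = np.cov(X.T, bias=True)
        scale = np.abs(expected).max()
        assert np.abs(emp - expected).max() < 0.15 * scale

    def test_unassigned_root_errors(self, yule50):
        with pytest.raises(ValueError, match="root"):
            dp.simulate_bm(yule50, {0: 1.0}, {}, 0.0, seed=1)


class TestSimulateDagData:
    def test_empty_dag_independent_columns(self, yule300):
        g = nx.DiGraph()
        g.add_nodes_from("WXYZ")
        df = dp.simulate_dag_data(yule300, g, {}, seed=5)
        coefs = []
        for a in "WXY":
            for b in "XYZ":
                if a >= b:
                    continue
                fit = dp.fit_pgls(df, b, [a], yule300)
                coefs.append(abs(fit.coef[a]))
        assert np.mean(coefs) < 0.15

    def test_single_edge_slope_recovered(self, yule300):
        g = nx.DiGraph([("X", "Y")])
        df = dp.simulate_dag_data(yule300, g, {("X", "Y"): 0.8}, seed=6)
        fit = dp.fit_pgls(df, "Y", ["X"], yule300)
        assert abs(fit.coef["X"] - 0.8) < 0.15

    def test_chain_partial_coefficient_near_zero(self, yule300, chain_dag):
        df = dp.simulate_dag_data(
            yule300, chain_dag, {("X", "Y"): 0.7, ("Y", "Z"): 0.7}, seed=7)
        fit = dp.fit_pgls(df, "Z", ["X", "Y"], yule300)
        assert abs(fit.coef["X"]) < 0.15
        assert fit.coef["Y"] > 0.3

    def test_columns_standardized(self, yule300, chain_dag):
        df = dp.simulate_dag_data(
            yule300, chain_dag, {("X", "Y"): 0.7, ("Y", "Z"): 0.7}, seed=8)
        assert np.allclose(df.mean(), 0.0, atol=1e-9)
        assert np.allclose(df.std(ddof=0), 1.0, atol=1e-9)

    def test_cyclic_dag_rejected(self, yule50):
        g = nx.DiGraph([("X", "Y"), ("Y", "X")])
        with pytest.raises(ValueError, match="acyclic"):
            dp.simulate_dag_data(yule50, g, {("X", "Y"): .5, ("Y", "X"): .5}, seed=1)


class TestSimulateChrom:
    def test_zero_rates_invariant(self, yule50):
        tips = dp.simulate_chrom(yule50, dp.ChromParams(), None, 9, seed=1)
        assert (tips == 9).all()

    def test_gain_only_poisson_expectation(self):
        """Gain-only: tip state = root + Poisson(rate * depth)."""
        star = dp.PhyloTree.from_newick("(" + ",".join(f"t{i}:1" for i in range(40)) + "):0;")
        prm = dp.ChromParams(lambda0=2.0)
        draws = np.concatenate([
            dp.simulate_chrom(star, prm, None, 10, seed=s).to_numpy()
            for s in range(50)
        ])
        # 2000 draws, expected increase = 2.0 events over 1 Myr
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 12.0) < 4 * se

    def test_determinism_and_bounds(self, yule50):
        m1 = dp.ChromParams(rho=0.007, lambda0=2.035, delta0=1.610,
                            lambda1=0.062, delta1=0.102)
        a = dp.simulate_chrom(yule50, m1, None, 12, seed=9)
        b = dp.simulate_chrom(yule50, m1, None, 12, seed=9)
        assert (a == b).all()
        assert a.min() >= 1

    def test_root_state_out_of_bounds(self, yule50):
        with pytest.raises(ValueError, match="state space"):
            dp.simulate_chrom(yule50, dp.ChromParams(), None, 500, seed=1)


def test_fixture_writer_roundtrip(tmp_path):
    cfg = dp.SimConfig(seed=3, n_tips=30, birth=0.5, death=0.1)
    paths = dp.write_fixture(cfg, tmp_path / "fx")
    tree = dp.read_newick(paths["tree"])
    table = dp.read_trait_table(paths["traits"])
    diff = dp.validate_species(table, tree)
    assert not diff["missing_from_table"] and not diff["extra_in_table"]
    assert "chrom_n" in table.columns and "div_rate" in table.columns
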