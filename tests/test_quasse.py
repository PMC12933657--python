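"""Trait-dependent diversification: rate families, PDE likelihood, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import divpath as dp
from divpath.quasse import (QuasseModel, RateFn, TraitGrid, eval_rate_fn,
                            quasse_loglik)


class TestRateFunctions:
    def test_constant(self):
        assert eval_rate_fn("constant", {"c": 0.3}, 1.7) == 0.3

    def test_sigmoid_midpoint(self):
        v = eval_rate_fn("sigmoid", {"y0": 0.1, "y1": 0.5, "xmid": 2.0, "r": 1.0}, 2.0)
        assert np.isclose(v, 0.3)

    def test_hump_peak_and_tails(self):
        p = {"y0": 0.1, "y1": 0.5, "xmid": 0.0, "s": 1.0}
        assert np.isclose(eval_rate_fn("hump", p, 0.0), 0.5)
        assert np.isclose(eval_rate_fn("hump", p, 50.0), 0.1)

    def test_linear_clamped(self):
        assert eval_rate_fn("linear", {"a": 0.1, "b": -1.0}, 10.0) == 0.0


def scalar_bd_loglik(tree, lam, mu):
    """Constant-rate birth-death log-likelihood with the same conventions as
    the PDE pruning (flat root, conditioned on survival); trait-free."""
    r = lam - mu

    def E_of_t(t):
        if mu == 0:
            return 0.0
        e = np.exp(-r * t)
        return mu * (1 - e) / (lam - mu * e)

    def branch_factor(t0, t1):
        v, _ = quad(lambda u: -(lam + mu) + 2 * lam * E_of_t(u), t0, t1,
                    limit=200)
        return v

    depth = tree.depths()
    T = tree.tip_depths().mean()
    age = T - depth
    logD = 0.0
    for v in tree.postorder:
        p = tree.parent[v]
        if p >= 0:
            logD += branch_factor(age[v], age[p])
        if tree.children(v):
            logD += np.log(lam) * (len(tree.children(v)) - 1)
    return logD - np.log(lam) - 2 * np.log(1 - E_of_t(T))


def bm_flat_loglik(tree, y, s2, tip_sd):
    """Felsenstein BM likelihood with tip measurement error, flat root."""
    n = len(y)
    V = dp.phylo_vcv(tree).loc[y.index, y.index].to_numpy() * s2 \
        + np.eye(n) * tip_sd ** 2
    yv = y.to_numpy()
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    mu = one @ Vi @ yv / (one @ Vi @ one)
    r = yv - mu
    _, logdet = np.linalg.slogdet(V)
    return -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet
                   + np.log(one @ Vi @ one) + r @ Vi @ r)


@pytest.fixture(scope="module")
def bd_fixture():
    tree = dp.simulate_tree(1.0, 0.0, 20, seed=3)
    s2 = 0.05
    vals = dp.simulate_bm(tree, {0: s2}, {tree.root: 0}, 0.0, seed=4)
    return tree, vals, s2


class TestLoglik:
    def test_constant_rates_match_closed_form(self, bd_fixture):
        """With trait-independent rates the likelihood factorizes into the
        birth-death closed form times the Brownian trait likelihood."""
        tree, vals, s2 = bd_fixture
        lam, mu = 0.9, 0.3
        model = QuasseModel(RateFn("constant", {"c": lam}),
                            RateFn("constant", {"c": mu}), s2)
        T = tree.tip_depths().mean()
        grid = TraitGrid.from_data(vals.to_numpy(), s2, T, 512, pad_sd=6)
        ll = quasse_loglik(tree, vals, model, grid=grid, tip_sd=0.05,
                           root="flat")
        target = scalar_bd_loglik(tree, lam, mu) \
            + bm_flat_loglik(tree, vals, s2, 0.05)
        assert abs(ll - target) / abs(target) < 1e-3

    def test_yule_special_case(self, bd_fixture):
        tree, vals, s2 = bd_fixture
        lam = 1.0
        model = QuasseModel(RateFn("constant", {"c": lam}),
                            RateFn("constant", {"c": 0.0}), s2)
        T = tree.tip_depths().mean()
        grid = TraitGrid.from_data(vals.to_numpy(), s2, T, 512, pad_sd=6)
        ll = quasse_loglik(tree, vals, model, grid=grid, tip_sd=0.05,
                           root="flat")
        target = scalar_bd_loglik(tree, lam, 0.0) \
            + bm_flat_loglik(tree, vals, s2, 0.05)
        assert abs(ll - target) / abs(target) < 1e-3

    def test_grid_self_convergence(self, bd_fixture):
        tree, vals, s2 = bd_fixture
        model = QuasseModel(RateFn("constant", {"c": 0.9}),
                            RateFn("constant", {"c": 0.3}), s2)
        T = tree.tip_depths().mean()
        lls = []
        for nb in (512, 1024):
            grid = TraitGrid.from_data(vals.to_numpy(), s2, T, nb, pad_sd=6)
            # fixed tip_sd so only the discretization changes between grids
            lls.append(quasse_loglik(tree, vals, model, grid=grid,
                                     tip_sd=0.05, root="flat"))
        assert abs(lls[1] - lls[0]) < 1e-3

    def test_extinction_bounded_and_positive_d(self, bd_fixture):
        tree, vals, s2 = bd_fixture
        from divpath.quasse import _Stepper
        model = QuasseModel(
            RateFn("hump", {"y0": 0.4, "y1": 1.2, "xmid": 0.0, "s": 0.5}),
            RateFn("sigmoid", {"y0": 0.05, "y1": 0.4, "xmid": 0.0, "r": 0.3}),
            s2, drift=(0.2, 0.0))
        grid = TraitGrid(256, -3, 3)
        stepper = _Stepper(model, grid, 0.01)
        E = np.zeros(grid.n_bins)
        D = np.exp(-0.5 * (grid.xs / 0.05) ** 2)
        for _ in range(300):
            E, D = stepper.step(E, D)
            assert E.min() >= 0.0 and E.max() <= 1.0
            assert D.min() >= 0.0

    def test_child_rotation_invariance(self):
        tree = dp.PhyloTree.from_newick("((A:1,B:1):1,C:2):0;")
        rotated = dp.PhyloTree.from_newick("(C:2,(B:1,A:1):1):0;")
        vals = pd.Series({"A": 0.2, "B": -0.1, "C": 0.4})
        model = QuasseModel(RateFn("constant", {"c": 0.8}),
                            RateFn("constant", {"c": 0.2}), 0.1)
        grid = TraitGrid(256, -3, 3)
        a = quasse_loglik(tree, vals, model, grid=grid, tip_sd=0.05)
        b = quasse_loglik(rotated, vals, model, grid=grid, tip_sd=0.05)
        assert abs(a - b) < 1e-8

    def test_narrow_grid_rejected(self, bd_fixture):
        tree, vals, s2 = bd_fixture
        model = QuasseModel(RateFn("constant", {"c": 0.9}),
                            RateFn("constant", {"c": 0.3}), 5.0)
        grid = TraitGrid(64, vals.min(), vals.max())
        with pytest.raises(ValueError, match="widen"):
            quasse_loglik(tree, vals, model, grid=grid)

    def test_nonultrametric_rejected(self):
        tree = dp.PhyloTree.from_newick("((A:1,B:2):1,C:2):0;")
        vals = pd.Series({"A": 0., "B": 1., "C": 2.})
        model = QuasseModel(RateFn("constant", {"c": 1.0}),
                            RateFn("constant", {"c": 0.0}), 1.0)
        with pytest.raises(ValueError, match="ultrametric"):
            quasse_loglik(tree, vals, model)


class TestFit:
    def test_single_candidate_returned(self, bd_fixture):
        tree, vals, s2 = bd_fixture
        with pytest.warns(UserWarning):
            out = dp.fit_quasse(tree, vals,
                                candidates=[("constant", "constant", "bm")],
                                n_bins=128, maxiter=40)
        assert len(out) == 1
        assert out.loc[0, "model"] == "bm.constant.constant"

    def test_aic_recomputable(self, bd_fixture):
        tree, vals, s2 = bd_fixture
        with pytest.warns(UserWarning):
            out = dp.fit_quasse(tree, vals,
                                candidates=[("constant", "constant", "bm")],
                                n_bins=128, maxiter=40)
        row = out.iloc[0]
        assert np.isclose(row.AIC, -2 * row.logL + 2 * row.k)

    def test_constant_data_prefers_constant(self):
        """Trait-independent diversification: the extra hump parameters
        should not buy more than the AIC penalty in most replicates."""
        wins = 0
        for rep in range(3):
            tree = dp.simulate_tree(1.0, 0.0, 60, seed=300 + rep)
            vals = dp.simulate_bm(tree, {0: 0.1}, {tree.root: 0}, 0.0,
                                  seed=400 + rep)
            out = dp.fit_quasse(tree, vals,
                                candidates=[("constant", "constant", "bm"),
                                            ("hump", "constant", "bm")],
                                n_bins=96, maxiter=80)
            best = out.set_index("model")
            daic = best.loc["bm.constant.constant", "AIC"] - out.AIC.min()
            wins += daic <= 2.0
        assert wins >= 2
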