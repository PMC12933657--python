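"""Chromosome-number CTMC: rate matrices, pruning oracle, fitting, tip rates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

import divpath as dp
from divpath.chromevol import build_rate_matrix, default_state_bounds

M1 = dp.ChromParams(rho=0.007, lambda0=2.035, delta0=1.610,
                    lambda1=0.062, delta1=0.102)


class TestRateMatrix:
    def test_zero_params_zero_matrix(self):
        Q = build_rate_matrix(dp.ChromParams(), 2, 6)
        assert np.allclose(Q, 0.0)

    def test_gain_only_structure(self):
        Q = build_rate_matrix(dp.ChromParams(lambda0=1.0), 2, 4)
        assert Q[0, 1] == 1.0 and Q[1, 2] == 1.0
        assert np.allclose(Q[2], 0.0)  # top state has no out-of-range gain

    def test_rows_sum_to_zero_random(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = dp.ChromParams(*rng.uniform(0, 2, 5))
            Q = build_rate_matrix(p, 5, 40)
            assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_transition_matrices_stochastic(self):
        Q = build_rate_matrix(M1, 1, 60)
        P = expm(Q * 2.5)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        assert P.min() > -1e-12


def brute_force_loglik(tree, tips, params, n_min, n_max, root_prior="uniform"):
    """Exhaustive sum over internal-node states (test oracle)."""
    Q = build_rate_matrix(params, n_min, n_max)
    P = {v: expm(Q * tree.lengths[v]) for v in range(tree.n_nodes)
         if tree.parent[v] >= 0}
    S = n_max - n_min + 1
    internals = [v for v in range(tree.n_nodes) if tree.children(v)]
    per_root = np.zeros(S)
    for assign in itertools.product(range(S), repeat=len(internals)):
        state = dict(zip(internals, assign))
        for t in tree.tip_ids:
            state[t] = tips[tree.labels[t]] - n_min
        lik = 1.0
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p >= 0:
                lik *= P[v][state[p], state[v]]
        per_root[state[tree.root]] += lik
    nz = per_root > 0
    return np.log(per_root[nz].sum() / nz.sum())


class TestLoglik:
    def test_matches_exhaustive_enumeration(self, three_tip_tree):
        rng = np.random.default_rng(3)
        tips = pd.Series({"A": 4, "B": 6, "C": 5})
        for _ in range(5):
            prm = dp.ChromParams(*rng.uniform(0.05, 1.0, 5))
            brute = brute_force_loglik(three_tip_tree, tips, prm, 3, 8)
            mine = dp.chrom_loglik(three_tip_tree, tips, prm, n_min=3, n_max=8)
            assert abs(brute - mine) < 1e-10

    def test_zero_rates_invariant_tips_loglik_zero(self, yule50):
        tips = pd.Series(9, index=yule50.tip_labels)
        assert dp.chrom_loglik(yule50, tips, dp.ChromParams()) == 0.0

    def test_unreachable_state_hurts(self, yule50):
        tips = pd.Series(9, index=yule50.tip_labels)
        near_zero = dp.ChromParams(lambda0=1e-4, delta0=1e-4)
        base = dp.chrom_loglik(yule50, tips, near_zero)
        tips2 = tips.copy()
        tips2.iloc[0] = 15
        worse = dp.chrom_loglik(yule50, tips2, near_zero)
        assert worse < base - 5

    def test_invariant_to_child_rotation(self):
        a = dp.PhyloTree.from_newick("((A:1,B:2):1,C:2):0;")
        b = dp.PhyloTree.from_newick("(C:2,(B:2,A:1):1):0;")
        tips = pd.Series({"A": 5, "B": 7, "C": 6})
        prm = dp.ChromParams(0.1, 0.8, 0.5, 0.02, 0.01)
        la = dp.chrom_loglik(a, tips, prm, n_min=2, n_max=12)
        lb = dp.chrom_loglik(b, tips, prm, n_min=2, n_max=12)
        assert abs(la - lb) < 1e-10

    def test_tip_state_out_of_bounds(self, three_tip_tree):
        tips = pd.Series({"A": 4, "B": 6, "C": 40})
        with pytest.raises(ValueError, match="state space"):
            dp.chrom_loglik(three_tip_tree, tips, M1, n_min=3, n_max=8)


class TestTipRates:
    def _fit_like(self, tree, tips, params):
        return dp.ChromFit(tree, tips, {tree.root: 0}, {0: params}, 0.0, 1, 90)

    def test_model1_formula(self, yule50):
        tips = pd.Series(30, index=yule50.tip_labels)
        fit = self._fit_like(yule50, tips, M1)
        rate = dp.tip_dysploidy_rate(fit, yule50.tip_labels[0])
        assert np.isclose(rate, 8.565)
        gain = dp.tip_dysploidy_rate(fit, yule50.tip_labels[0], mode="gain")
        loss = dp.tip_dysploidy_rate(fit, yule50.tip_labels[0], mode="loss")
        assert np.isclose(gain + loss, rate)

    def test_zero_regime_rate_zero(self, yule50):
        tips = pd.Series(9, index=yule50.tip_labels)
        fit = self._fit_like(yule50, tips, dp.ChromParams())
        assert dp.tip_dysploidy_rate(fit, yule50.tip_labels[0]) == 0.0

    def test_nondecreasing_in_n(self, yule50):
        rates = []
        for n in (5, 15, 30, 60):
            tips = pd.Series(n, index=yule50.tip_labels)
            fit = self._fit_like(yule50, tips, M1)
            rates.append(dp.tip_dysploidy_rate(fit, yule50.tip_labels[0]))
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_unknown_species_errors(self, yule50):
        tips = pd.Series(9, index=yule50.tip_labels)
        fit = self._fit_like(yule50, tips, M1)
        with pytest.raises(KeyError):
            dp.tip_dysploidy_rate(fit, "nope")


class TestFit:
    def test_state_bounds(self):
        assert default_state_bounds(np.array([12, 20, 38])) == (2, 86)
        assert default_state_bounds(np.array([3, 5])) == (1, 20)

    def test_max_regimes_one_forces_single_regime(self, yule50):
        tips = dp.simulate_chrom(yule50, M1, None, 12, seed=21)
        fit = dp.fit_chrom_model(yule50, tips, allow_shifts=True, max_regimes=1,
                                 seed=0, n_starts=1, maxiter=20)
        assert fit.n_regimes == 1

    def test_single_regime_parameters_reasonable(self, yule300):
        """Moderate-scale sanity: fitted total dysploidy rate near truth."""
        tips = dp.simulate_chrom(yule300, M1, None, 12, seed=22)
        fit = dp.fit_chrom_model(yule300, tips, allow_shifts=False, seed=0,
                                 n_starts=2)
        n_bar = tips.mean()
        truth = (M1.lambda0 + M1.lambda1 * n_bar) + (M1.delta0 + M1.delta1 * n_bar)
        p = fit.params[0]
        est = (p.lambda0 + p.lambda1 * n_bar) + (p.delta0 + p.delta1 * n_bar)
        assert 0.4 * truth < est < 2.5 * truth
        assert fit.loglik >= dp.chrom_loglik(yule300, tips, M1) - 1.0
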