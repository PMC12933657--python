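"""Multi-regime Brownian motion for continuous traits.

A continuous trait evolves by Brownian motion whose diffusion rate sigma^2
(trait-units^2 Myr^-1) may shift at clades.  The model is fitted by maximum
likelihood under the regime-weighted tree covariance, and shifts are added
greedily while they improve AICc.  The quantity the path analyses consume is
the per-species evolutionary rate: the sigma^2 of the regime governing each
tip's terminal branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .phylo import PhyloTree
from .regimes import branch_regime_array

__all__ = ["BmRegimeModel", "fit_bm_regimes", "tip_trait_rate", "regime_weighted_vcv"]


def regime_weighted_vcv(tree: PhyloTree, shifts: dict) -> dict:
    """Per-regime shared-path-length matrices W_r over tips, so that the trait
    covariance is ``sum_r sigma2_r * W_r``."""
    reg = branch_regime_array(tree, shifts)
    tips = tree.tip_ids
    pos = {t: k for k, t in enumerate(tips)}
    n = len(tips)
    out = {r: np.zeros((n, n)) for r in np.unique(reg)}
    # accumulate branch-by-branch: a branch adds its length to every tip pair
    # whose paths to the root both traverse it
    for v in range(tree.n_nodes):
        if tree.parent[v] < 0:
            continue
        below = [pos[t] for t in tree.subtree_tips(v)]
        idx = np.ix_(below, below)
        out[reg[v]][idx] += tree.lengths[v]
    return out


@dataclass
class BmRegimeModel:
    """Fitted shift configuration for one trait."""

    trait: str
    shifts: dict          # node id -> regime id, root included
    sigma2: dict          # regime id -> rate
    root_value: float
    loglik: float
    n: int
    tree: PhyloTree

    @property
    def n_regimes(self):
        return len(self.sigma2)

    @property
    def aicc(self):
        # each extra regime costs its sigma^2 AND its shift location; not
        # charging for the location lets the best of ~n/min_clade candidate
        # shifts win by selection bias alone
        k = self.n_regimes + (self.n_regimes - 1) + 1
        if self.n - k - 1 <= 0:
            return np.inf
        return -2 * self.loglik + 2 * k + 2 * k * (k + 1) / (self.n - k - 1)

    def tip_rates(self) -> pd.Series:
        reg = branch_regime_array(self.tree, self.shifts)
        return pd.Series(
            [self.sigma2[reg[i]] for i in self.tree.tip_ids],
            index=self.tree.tip_labels, name=f"r_{self.trait}",
        )


def _bm_profile(y, Ws, log_ratios):
    """Profile log-likelihood over rate ratios; the overall scale sigma_1^2
    and the root value have closed-form ML solutions."""
    V0 = Ws[0] + sum(np.exp(r) * W for r, W in zip(log_ratios, Ws[1:]))
    n = len(y)
    try:
        c, low = cho_factor(V0, check_finite=False)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    one = np.ones(n)
    Vi_y = cho_solve((c, low), y, check_finite=False)
    Vi_1 = cho_solve((c, low), one, check_finite=False)
    mu = float(one @ Vi_y) / float(one @ Vi_1)
    r = y - mu
    Vi_r = cho_solve((c, low), r, check_finite=False)
    s2_hat = float(r @ Vi_r) / n
    if s2_hat <= 0:
        return -np.inf, np.nan, np.nan
    logdet = 2.0 * np.log(np.diag(c)).sum()
    ll = -0.5 * (n * (np.log(2 * np.pi) + np.log(s2_hat) + 1.0) + logdet)
    return ll, s2_hat, mu


def _fit_sigmas(y, Ws, start_log_s2):
    start_log_s2 = np.asarray(start_log_s2, dtype=float)
    if len(Ws) == 1:
        ll, s2, mu = _bm_profile(y, Ws, [])
        return np.array([s2]), ll, mu
    start_ratios = start_log_s2[1:] - start_log_s2[0]
    res = minimize(lambda t: -_bm_profile(y, Ws, t)[0], start_ratios,
                   method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 200})
    ll, s2, mu = _bm_profile(y, Ws, res.x)
    return s2 * np.concatenate([[1.0], np.exp(res.x)]), ll, mu


def fit_bm_regimes(tree: PhyloTree, values: pd.Series, max_shifts: int = 5,
                   min_clade: int = 10, trait: str = "trait") -> BmRegimeModel:
    """Fit multi-regime BM by greedy forward AICc search.

    Starts from a single regime; at each round a shift is proposed at every
    internal node with at least ``min_clade`` descendant tips and the best
    AICc improvement is kept.  With zero trait variance a single regime at
    the numerical floor is returned.
    """
    if tree.n_tips < 10:
        raise ValueError("need at least 10 tips")
    y = values.reindex(tree.tip_labels)
    if y.isna().any():
        raise ValueError(f"missing values for {list(y.index[y.isna()])}")
    y = y.to_numpy(dtype=float)
    n = len(y)
    if np.allclose(y, y[0]):
        import warnings

        warnings.warn("trait has zero variance; sigma^2 at lower bound")
        return BmRegimeModel(trait, {tree.root: 0}, {0: 1e-12}, float(y[0]),
                             np.inf, n, tree)

    depth = tree.tip_depths().mean()
    s2_0 = np.var(y) / depth
    shifts = {tree.root: 0}
    Ws = list(regime_weighted_vcv(tree, shifts).values())
    s2, ll, mu = _fit_sigmas(y, Ws, np.log([s2_0]))
    model = BmRegimeModel(trait, dict(shifts), {0: float(s2[0])}, mu, ll, n, tree)

    candidates = [v for v in range(tree.n_nodes)
                  if tree.children(v) and v != tree.root
                  and len(tree.subtree_tips(v)) >= min_clade]
    # the best of many candidate shift locations wins ~2 ln(#candidates) in
    # log-likelihood by selection alone; require the AICc gain to clear it
    guard = 2.0 * np.log(max(len(candidates), 1))
    while model.n_regimes - 1 < max_shifts:
        best = None
        new_id = max(model.sigma2) + 1
        for v in candidates:
            if v in model.shifts:
                continue
            shifts_v = dict(model.shifts)
            shifts_v[v] = new_id
            Wmap = regime_weighted_vcv(tree, shifts_v)
            regs = sorted(Wmap)
            Ws = [Wmap[r] for r in regs]
            start = np.log([model.sigma2.get(r, s2_0) for r in regs])
            s2, ll, mu = _fit_sigmas(y, Ws, start)
            cand = BmRegimeModel(trait, shifts_v,
                                 {r: float(s) for r, s in zip(regs, s2)},
                                 mu, ll, n, tree)
            if best is None or cand.aicc < best.aicc:
                best = cand
        if best is None or best.aicc >= model.aicc - guard:
            break
        model = best
    return model


def tip_trait_rate(model: BmRegimeModel, species: str) -> float:
    """sigma^2 of the regime governing the species' terminal branch."""
    rates = model.tip_rates()
    if species not in rates.index:
        raise KeyError(f"unknown species {species!r}")
    return float(rates[species])
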