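"""Phylogenetic generalized least squares (PGLS).

The atomic unit of phylogenetic path analysis: every d-separation test and
every path coefficient is one GLS regression whose residual covariance is the
(optionally Pagel-lambda-scaled) Brownian covariance of the tree.  Variables
are z-scored before fitting so coefficients are standardized (bounded by
[-1, 1] up to estimation noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .phylo import PhyloTree, phylo_vcv

__all__ = ["PglsFit", "fit_pgls"]


@dataclass
class PglsFit:
    """One fitted phylogenetic regression."""

    response: str
    predictors: tuple
    coef: pd.Series       # standardized coefficients, incl. "Intercept"
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    loglik: float
    lam: float            # Pagel's lambda actually used

    def pvalue_of(self, predictor: str) -> float:
        return float(self.pvalues[predictor])


def _lambda_scale(V: np.ndarray, lam: float) -> np.ndarray:
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


def fit_pgls(table: pd.DataFrame, response: str, predictors, tree: PhyloTree = None,
             lambda_mode: str = "fixed1", vcv: pd.DataFrame = None,
             standardize: bool = True) -> PglsFit:
    """GLS regression of ``response`` on ``predictors`` under tree covariance.

    ``lambda_mode`` is ``"fixed1"`` (pure Brownian residuals, the default used
    throughout the path analyses) or ``"ml"`` (profile Pagel's lambda over
    [0, 1]).  Either ``tree`` or a precomputed ``vcv`` (species x species,
    matching the table) must be given.  With ``vcv`` proportional to the
    identity the fit reduces exactly to OLS.
    """
    predictors = list(predictors)
    cols = [response] + predictors
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in trait table: {missing}")
    if vcv is None:
        if tree is None:
            raise ValueError("either tree or vcv is required")
        vcv = phylo_vcv(tree)
    not_in_vcv = [s for s in table.index if s not in vcv.index]
    if not_in_vcv:
        raise ValueError(f"species missing from covariance matrix: {not_in_vcv}")
    n = len(table)
    if n <= len(predictors) + 2:
        raise ValueError(f"n={n} too small for {len(predictors)} predictors")

    data = table[cols].astype(float)
    if standardize:
        sd = data.std(ddof=0)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])
            raise ValueError(f"zero-variance columns cannot be standardized: {bad}")
        data = (data - data.mean()) / sd
    y = data[response].to_numpy()
    X = np.column_stack([np.ones(n)] + [data[p].to_numpy() for p in predictors])
    names = ["Intercept"] + predictors
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design matrix; collinear columns among {names}")
    V = vcv.loc[table.index, table.index].to_numpy()

    def fit_at(lam):
        return sm.GLS(y, X, sigma=_lambda_scale(V, lam)).fit()

    if lambda_mode == "fixed1":
        lam = 1.0
        res = fit_at(lam)
    elif lambda_mode == "ml":
        opt = minimize_scalar(lambda l: -fit_at(l).llf, bounds=(0.0, 1.0),
                              method="bounded", options={"xatol": 1e-4})
        lam = float(opt.x)
        res = fit_at(lam)
    else:
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")

    idx = pd.Index(names)
    return PglsFit(
        response=response,
        predictors=tuple(predictors),
        coef=pd.Series(res.params, index=idx),
        se=pd.Series(res.bse, index=idx),
        tvalues=pd.Series(res.tvalues, index=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        df_resid=int(res.df_resid),
        loglik=float(res.llf),
        lam=lam,
    )
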