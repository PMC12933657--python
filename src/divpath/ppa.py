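"""Phylogenetic path analysis (PPA).

Candidate causal models (DAGs over trait-table columns) are compared through
their d-separation basis sets: every pair of non-adjacent variables must be
conditionally independent given the union of both variables' parents.  Each
independence claim is tested with one PGLS regression; the claim p-values
combine into Fisher's C, models are ranked by the small-sample information
criterion CICc = C + 2q * n/(n - 1 - q), and standardized path coefficients
are model-averaged over all candidates within a CICc cutoff, imputing zero
for absent paths ("full" averaging).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .pgls import PglsFit, fit_pgls
from .phylo import PhyloTree, phylo_vcv

__all__ = [
    "IndependenceClaim",
    "PathModelFit",
    "AveragedModel",
    "ggm_toporder",
    "basis_set",
    "fisher_c",
    "cicc",
    "fit_model_set",
    "average_models",
]


@dataclass(frozen=True)
class IndependenceClaim:
    """Claim that ``x`` is independent of ``y`` given ``given``.

    ``y`` is the regression response (the later variable in the model's
    topological order); the claim is tested by the p-value of ``x`` in the
    PGLS regression ``y ~ x + given``.
    """

    x: str
    y: str
    given: tuple

    @property
    def regression_key(self):
        """Dedup key: one regression per (response, full predictor set)."""
        return (self.y, frozenset((self.x,) + self.given))


def _check_dag(dag: nx.DiGraph):
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("path model must be an acyclic digraph")
    if any(u == v for u, v in dag.edges):
        raise ValueError("self-loops are not allowed")


def ggm_toporder(dag: nx.DiGraph, order) -> list:
    """Topological sort with the tie-breaking behaviour of the reference
    R implementation (a LIFO stack seeded with parentless variables in
    reverse canonical order; freed children pushed in canonical order).

    The resulting claim orientation is deterministic given the canonical
    variable ``order``, which is part of each model family's definition.
    """
    order = list(order)
    extra = [n for n in dag.nodes if n not in order]
    cols = order + sorted(extra)
    pos = {c: i for i, c in enumerate(cols)}
    indeg = {c: 0 for c in cols}
    children = {c: [] for c in cols}
    for a, b in dag.edges:
        indeg[b] += 1
        children[a].append(b)
    for c in cols:
        children[c].sort(key=pos.get)
    stack = []
    for c in cols:
        if indeg[c] == 0:
            stack.insert(0, c)
    out = []
    while stack:
        v = stack.pop(0)
        out.append(v)
        for k in children[v]:
            indeg[k] -= 1
            if indeg[k] == 0:
                stack.insert(0, k)
    if len(out) != len(cols):
        raise ValueError("graph is cyclic")
    return out


def basis_set(dag: nx.DiGraph, order=None) -> list:
    """Shipley d-separation basis set of a DAG.

    One claim per non-adjacent pair, conditioned on the union of the two
    variables' parents; the later variable (under :func:`ggm_toporder`) is
    the response.  ``order`` is the canonical variable order of the model
    family (defaults to sorted node names).
    """
    _check_dag(dag)
    if order is None:
        order = sorted(dag.nodes)
    top = ggm_toporder(dag, order)
    parents = {v: [u for u in top if dag.has_edge(u, v)] for v in top}
    claims = []
    for i, r in enumerate(top):
        for s in top[i + 1:]:
            if dag.has_edge(r, s) or dag.has_edge(s, r):
                continue
            given = [p for p in parents[r] if p not in (r, s)]
            given += [p for p in parents[s] if p not in given and p not in (r, s)]
            claims.append(IndependenceClaim(x=r, y=s, given=tuple(given)))
    return claims


def fisher_c(p_values) -> float:
    """Fisher's C = -2 * sum(log p) over the basis-set p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return 0.0
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; a non-positive value "
                         "signals a numerically degenerate regression")
    return float(-2.0 * np.log(p).sum())


def cicc(C: float, q: int, n: int) -> float:
    """C-statistic information criterion with small-sample correction."""
    if n <= q + 1:
        raise ValueError(f"model overparameterized: n={n} <= q+1={q + 1}")
    return float(C + 2.0 * q * n / (n - 1.0 - q))


@dataclass
class PathModelFit:
    """One candidate causal model evaluated against the data."""

    model_id: str
    dag: nx.DiGraph
    claims: list
    p_values: list
    C: float
    q: int
    n: int
    CICc: float
    delta: float = np.nan
    weight: float = np.nan

    @property
    def n_edges(self):
        return self.dag.number_of_edges()


def _param_count(dag: nx.DiGraph) -> int:
    """q = #edges + #endogenous nodes (one intercept per regression)."""
    endo = sum(1 for v in dag.nodes if dag.in_degree(v) > 0)
    return dag.number_of_edges() + endo


class _RegressionCache:
    """Dedup PGLS regressions across models by (response, predictor set)."""

    def __init__(self, table, vcv, lambda_mode):
        self.table = table
        self.vcv = vcv
        self.lambda_mode = lambda_mode
        self._store = {}
        self.requests = 0

    def fit(self, response: str, predictors: frozenset) -> PglsFit:
        self.requests += 1
        key = (response, predictors)
        if key not in self._store:
            self._store[key] = fit_pgls(
                self.table, response, sorted(predictors), vcv=self.vcv,
                lambda_mode=self.lambda_mode,
            )
        return self._store[key]

    @property
    def n_unique(self):
        return len(self._store)


def fit_model_set(models, table: pd.DataFrame, tree: PhyloTree = None,
                  order=None, lambda_mode: str = "fixed1",
                  vcv: pd.DataFrame = None) -> list:
    """Evaluate and rank a set of candidate DAGs.

    ``models`` is a mapping model_id -> DAG (or a ModelSet, whose null model
    and canonical order are used automatically).  Returns PathModelFits
    sorted by CICc (ties: fewer edges, then model id), carrying delta-CICc
    and Akaike-style weights over the whole candidate set.
    """
    from .model_sets import ModelSet  # local import to avoid cycle

    if isinstance(models, ModelSet):
        order = list(models.nodes)
        items = list(models.with_null().items())
    else:
        items = list(models.items())
        if order is None:
            nodes = set()
            for _, d in items:
                nodes |= set(d.nodes)
            order = sorted(nodes)
    node_set = set(order)
    for mid, dag in items:
        missing = [v for v in dag.nodes if v not in table.columns]
        if missing:
            raise KeyError(f"model {mid!r}: nodes {missing} not in trait table")
        if not set(dag.nodes) <= node_set:
            raise ValueError(f"model {mid!r} uses nodes outside the declared set")
    if vcv is None:
        if tree is None:
            raise ValueError("either tree or vcv is required")
        vcv = phylo_vcv(tree)
    cache = _RegressionCache(table, vcv, lambda_mode)
    n = len(table)
    fits = []
    for mid, dag in items:
        full = nx.DiGraph()
        full.add_nodes_from(order)
        full.add_edges_from(dag.edges)
        claims = basis_set(full, order)
        pvals = []
        for cl in claims:
            reg = cache.fit(*cl.regression_key)
            pvals.append(max(reg.pvalue_of(cl.x), 1e-300))
        C = fisher_c(pvals)
        q = _param_count(full)
        fits.append(PathModelFit(mid, full, claims, pvals, C, q, n, cicc(C, q, n)))
    fits.sort(key=lambda f: (f.CICc, f.n_edges, f.model_id))
    best = fits[0].CICc
    raw = np.array([np.exp(-(f.CICc - best) / 2.0) for f in fits])
    raw /= raw.sum()
    for f, w in zip(fits, raw):
        f.delta = f.CICc - best
        f.weight = float(w)
        f._cache = cache
    return fits


@dataclass
class AveragedModel:
    """Full model average of standardized path coefficients."""

    nodes: tuple
    coef: pd.DataFrame   # from x to, averaged standardized coefficient
    se: pd.DataFrame
    model_ids: tuple     # models inside the cutoff
    weights: tuple

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a in self.coef.index:
            for b in self.coef.columns:
                if self.coef.loc[a, b] != 0.0:
                    rows.append((a, b, self.coef.loc[a, b], self.se.loc[a, b]))
        return pd.DataFrame(rows, columns=["from", "to", "coefficient", "se"])

    def to_dot(self) -> str:
        """GraphViz source; edge width tracks |coefficient|."""
        lines = ["digraph averaged {", "  rankdir=LR;"]
        for _, row in self.edge_table().iterrows():
            w = max(abs(row.coefficient) * 5, 0.3)
            lines.append(
                f'  {row["from"]} -> {row["to"]} '
                f'[label="{row.coefficient:.2f}", penwidth={w:.2f}];')
        lines.append("}")
        return "\n".join(lines)


def average_models(fits, cutoff: float = 2.0, mode: str = "full") -> AveragedModel:
    """Average standardized path coefficients over models within ``cutoff``
    CICc units of the best model (closed interval).

    Weights are proportional to exp(-delta/2) renormalized within the subset.
    ``mode="full"`` imputes coefficient 0 (and variance 0) for paths absent
    from a model; ``mode="conditional"`` averages only over models containing
    the path.
    """
    if not fits:
        raise ValueError("empty candidate list")
    if mode not in ("full", "conditional"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    best = min(f.CICc for f in fits)
    subset = [f for f in fits if f.CICc - best <= cutoff]
    if not subset:
        raise ValueError("no models within the CICc cutoff")
    w = np.array([np.exp(-(f.CICc - best) / 2.0) for f in subset])
    w /= w.sum()
    nodes = tuple(subset[0].dag.nodes)
    coef = pd.DataFrame(0.0, index=nodes, columns=nodes)
    var = pd.DataFrame(0.0, index=nodes, columns=nodes)
    present = pd.DataFrame(0.0, index=nodes, columns=nodes)
    cache = getattr(subset[0], "_cache", None)
    if cache is None:
        raise ValueError("fits must come from fit_model_set")
    for f, wm in zip(subset, w):
        for v in f.dag.nodes:
            parents = sorted(f.dag.predecessors(v))
            if not parents:
                continue
            reg = cache.fit(v, frozenset(parents))
            for p in parents:
                coef.loc[p, v] += wm * reg.coef[p]
                var.loc[p, v] += wm * reg.se[p] ** 2
                present.loc[p, v] += wm
    if mode == "conditional":
        nz = present > 0
        coef[nz] = coef[nz] / present[nz]
        var[nz] = var[nz] / present[nz]
    return AveragedModel(
        nodes=nodes,
        coef=coef,
        se=np.sqrt(var),
        model_ids=tuple(f.model_id for f in subset),
        weights=tuple(float(x) for x in w),
    )


def model_set_report(fits) -> pd.DataFrame:
    """Ranked summary table: id, #edges, #claims, C, q, CICc, delta, weight."""
    return pd.DataFrame(
        {
            "model": [f.model_id for f in fits],
            "n_edges": [f.n_edges for f in fits],
            "n_claims": [len(f.claims) for f in fits],
            "C": [f.C for f in fits],
            "q": [f.q for f in fits],
            "CICc": [f.CICc for f in fits],
            "delta_CICc": [f.delta for f in fits],
            "weight": [f.weight for f in fits],
        }
    )
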