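"""Synthetic trees, traits and chromosome numbers with known ground truth.

Everything downstream (PGLS, path analysis, chromosome CTMC fitting, QuaSSE)
is exercised on data from this module, so each generator states exactly what
it draws:

* birth--death trees conditioned on a tip count (simple forward sampling);
* Brownian-motion traits with clade-specific rate regimes;
* trait tables wired by a user-supplied causal DAG with phylogenetically
  correlated (Brownian) residuals;
* chromosome numbers evolved by a gain/loss/duplication jump process.

All functions are deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .chromevol import ChromParams
from .phylo import PhyloTree
from .regimes import branch_regime_array

__all__ = [
    "SimConfig",
    "simulate_tree",
    "simulate_bm",
    "simulate_dag_data",
    "simulate_chrom",
    "branch_regimes",
    "write_fixture",
]


@dataclass
class SimConfig:
    """Bundle of generator settings for an end-to-end synthetic dataset."""

    seed: int = 1
    n_tips: int = 300
    birth: float = 0.15  # Myr^-1
    death: float = 0.05  # Myr^-1
    # edges of the generating causal model over trait-table column names
    dag_edges: tuple = (("r_BIO4", "r_chrom"), ("r_chrom", "div_rate"))
    path_coefficients: dict = field(
        default_factory=lambda: {("r_BIO4", "r_chrom"): 0.6, ("r_chrom", "div_rate"): 0.6}
    )
    chrom_params: ChromParams = field(
        default_factory=lambda: ChromParams(rho=0.007, lambda0=2.035, delta0=1.610,
                                            lambda1=0.062, delta1=0.102)
    )
    chrom_root_state: int = 12
    bm_rates: dict = field(default_factory=lambda: {0: 1.0})

    def __post_init__(self):
        if not self.birth > self.death >= 0:
            raise ValueError("need birth > death >= 0")
        for e, c in self.path_coefficients.items():
            if abs(c) > 1:
                raise ValueError(f"path coefficient out of [-1, 1] for edge {e}")


def simulate_tree(birth: float, death: float, n_tips: int, seed: int,
                  max_retries: int = 100) -> PhyloTree:
    """Simulate a birth--death tree conditioned on ``n_tips`` surviving tips.

    Forward (Gillespie) simulation from a single lineage; the process is
    stopped at the moment the (n+1)-th extant lineage would appear, so for a
    pure-birth process the expected root age is ``sum_{k=2..n} 1/(k * birth)``.
    Extinct lineages are pruned.  Replicates that die out are retried up to
    ``max_retries`` times.
    """
    if not birth > 0:
        raise ValueError("birth rate must be positive")
    if n_tips < 3:
        raise ValueError("need n_tips >= 3")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        tree = _forward_bd(birth, death, n_tips, rng)
        if tree is not None:
            return tree
    raise RuntimeError(
        f"birth-death simulation failed to reach {n_tips} surviving tips "
        f"in {max_retries} attempts (birth={birth}, death={death})"
    )


def _forward_bd(birth, death, n_tips, rng):
    # node bookkeeping: lists indexed by node id
    parent, birth_time, death_time, children = [-1], [0.0], [None], [[]]
    extant = [0]
    t = 0.0
    while True:
        k = len(extant)
        if k == 0:
            return None
        total = k * (birth + death)
        t += rng.exponential(1.0 / total)
        v = extant[rng.integers(k)]
        if rng.random() < birth / (birth + death):
            if k == n_tips:  # would create lineage n+1: sample tree now
                break
            for _ in range(2):
                parent.append(v)
                birth_time.append(t)
                death_time.append(None)
                children.append([])
                children[v].append(len(parent) - 1)
            death_time[v] = t
            extant.remove(v)
            extant.extend([len(parent) - 2, len(parent) - 1])
        else:
            death_time[v] = t
            extant.remove(v)
    # survivors live to time t
    for v in extant:
        death_time[v] = t
    # keep only lineages with extant descendants
    keep = set()
    for v in extant:
        while v != -1 and v not in keep:
            keep.add(v)
            v = parent[v]
    # collapse unary nodes (extinct side pruned)
    return _build_pruned(parent, birth_time, death_time, children, keep, extant)


def _build_pruned(parent, birth_time, death_time, children, keep, extant):
    kept_children = {v: [c for c in children[v] if c in keep] for v in keep}
    extant = set(extant)

    def resolve(v):
        # follow unary chains downward; return representative node
        while v not in extant and len(kept_children[v]) == 1:
            v = kept_children[v][0]
        return v

    root = resolve(min(keep))
    new_parent, new_len, labels = [-1], [0.0], {}
    index = {root: 0}
    stack = [root]
    while stack:
        v = stack.pop()
        i = index[v]
        if v in extant:
            labels[i] = f"t{len(labels) + 1}"
            continue
        for c in kept_children[v]:
            r = resolve(c)
            index[r] = len(new_parent)
            new_parent.append(i)
            new_len.append(death_time[r] - birth_time[c])
            stack.append(r)
    return PhyloTree(np.array(new_parent), np.array(new_len), labels)


def branch_regimes(tree: PhyloTree, shifts: dict) -> np.ndarray:
    """Alias of :func:`divpath.regimes.branch_regime_array`."""
    return branch_regime_array(tree, shifts)


def simulate_bm(tree: PhyloTree, sigma2_by_regime: dict, shifts: dict,
                root_value: float, seed: int) -> pd.Series:
    """Brownian motion along the tree with per-regime diffusion rate sigma^2
    (trait-units^2 Myr^-1).  Returns tip values indexed by label."""
    reg = branch_regimes(tree, shifts)
    missing = set(np.unique(reg)) - set(sigma2_by_regime)
    if missing:
        raise ValueError(f"no sigma^2 supplied for regimes {sorted(missing)}")
    rng = np.random.default_rng(seed)
    x = np.zeros(tree.n_nodes)
    x[tree.root] = root_value
    for v in tree.postorder[::-1]:
        p = tree.parent[v]
        if p < 0:
            continue
        s2 = sigma2_by_regime[reg[v]]
        x[v] = x[p] + rng.normal(0.0, np.sqrt(s2 * tree.lengths[v])) if s2 > 0 else x[p]
    return pd.Series(x[tree.tip_ids], index=tree.tip_labels)


def simulate_dag_data(tree: PhyloTree, dag: nx.DiGraph, path_coefficients: dict,
                      seed: int, standardize: bool = True) -> pd.DataFrame:
    """Tip data wired by a known linear causal DAG with Brownian residuals.

    Exogenous variables are independent Brownian motions on the tree;
    each endogenous variable is the coefficient-weighted sum of its parents
    plus an independent Brownian residual scaled so that the column variance
    stays near one.  Columns are z-scored afterwards (default), so fitted
    standardized path coefficients estimate the generating ones.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("causal graph must be acyclic")
    for e in dag.edges:
        if e not in path_coefficients:
            raise ValueError(f"missing path coefficient for edge {e}")
    rng = np.random.default_rng(seed)
    cols = {}
    for node in nx.topological_sort(dag):
        bm = simulate_bm(tree, {0: 1.0}, {tree.root: 0}, 0.0,
                         seed=rng.integers(2**31 - 1))
        bm = (bm - bm.mean()) / bm.std(ddof=0)
        parents = list(dag.predecessors(node))
        if not parents:
            cols[node] = bm
        else:
            betas = np.array([path_coefficients[(p, node)] for p in parents])
            resid_sd = np.sqrt(max(1.0 - float(betas @ betas), 0.05))
            val = sum(b * cols[p] for b, p in zip(betas, parents)) + resid_sd * bm
            cols[node] = val
    df = pd.DataFrame(cols, index=tree.tip_labels)
    if standardize:
        df = (df - df.mean()) / df.std(ddof=0)
    df.index.name = "species"
    return df


def simulate_chrom(tree: PhyloTree, chrom_params, regime_map: dict, root_state: int,
                   seed: int, n_max: int = 200) -> pd.Series:
    """Evolve haploid chromosome numbers by a jump process along each branch.

    Events: +1 (ascending dysploidy, rate ``max(0, lambda0 + lambda1*n)``),
    -1 (descending dysploidy, ``max(0, delta0 + delta1*n)``) and doubling
    (``rho``), with the doubled state truncated at ``n_max``.  ``regime_map``
    maps node id -> ChromParams-holding regime id; parameters per regime are
    given either directly as ChromParams values or via a dict.
    """
    if isinstance(chrom_params, ChromParams):
        params_by_regime = {0: chrom_params}
        regime_map = {tree.root: 0}
    else:
        params_by_regime = dict(chrom_params)
    if not 1 <= root_state <= n_max:
        raise ValueError(f"root_state {root_state} outside state space [1, {n_max}]")
    reg = branch_regimes(tree, regime_map)
    rng = np.random.default_rng(seed)
    state = np.zeros(tree.n_nodes, dtype=int)
    state[tree.root] = root_state
    for v in tree.postorder[::-1]:
        p = tree.parent[v]
        if p < 0:
            continue
        state[v] = _gillespie_branch(state[p], tree.lengths[v],
                                     params_by_regime[reg[v]], rng, n_max)
    return pd.Series(state[tree.tip_ids], index=tree.tip_labels)


def _gillespie_branch(n, t_total, prm, rng, n_max):
    t = 0.0
    while True:
        up = max(0.0, prm.lambda0 + prm.lambda1 * n) if n < n_max else 0.0
        down = max(0.0, prm.delta0 + prm.delta1 * n) if n > 1 else 0.0
        dup = prm.rho if n < n_max else 0.0
        total = up + down + dup
        if total <= 0:
            return n
        t += rng.exponential(1.0 / total)
        if t >= t_total:
            return n
        u = rng.random() * total
        if u < up:
            n += 1
        elif u < up + down:
            n -= 1
        else:
            n = min(2 * n, n_max)
    return n


def write_fixture(config: SimConfig, out_dir) -> dict:
    """Generate and write a complete synthetic dataset: ``tree.nwk``,
    ``traits.csv`` and a YAML echo of the configuration.  Returns paths."""
    import os

    import yaml

    os.makedirs(out_dir, exist_ok=True)
    tree = simulate_tree(config.birth, config.death, config.n_tips, config.seed)
    dag = nx.DiGraph()
    dag.add_nodes_from(
        ["BIO1", "BIO4", "BIO7", "BIO12", "culm", "spike", "div_rate",
         "r_BIO4", "r_chrom", "r_culm", "r_spike"]
    )
    dag.add_edges_from(config.dag_edges)
    table = simulate_dag_data(tree, dag, config.path_coefficients, config.seed + 1)
    # map standardized columns onto field-plausible units (monotone, so the
    # generating causal structure survives): temperatures in deg C, lengths
    # lognormal in cm/mm, rates positive
    units = {
        "BIO1": lambda z: 12 + 8 * z,
        "BIO4": lambda z: 600 + 150 * z,
        "BIO7": lambda z: 30 + 8 * z,
        "BIO12": lambda z: 800 * np.exp(0.3 * z),
        "culm": lambda z: 50 * np.exp(0.5 * z),
        "spike": lambda z: 12 * np.exp(0.5 * z),
        "div_rate": lambda z: 0.3 + 0.1 * z,
    }
    for col, f in units.items():
        if col in table.columns:
            table[col] = f(table[col])
    for col in table.columns:
        if col.startswith("r_"):
            table[col] = 0.1 * np.exp(0.5 * table[col])
    chrom = simulate_chrom(tree, config.chrom_params, None, config.chrom_root_state,
                           config.seed + 2)
    table.insert(0, "chrom_n", chrom)
    order = ["chrom_n", "BIO1", "BIO4", "BIO7", "BIO12", "culm", "spike",
             "div_rate", "r_chrom", "r_BIO4", "r_culm", "r_spike"]
    table = table[[c for c in order if c in table.columns]]
    tree_path = os.path.join(out_dir, "tree.nwk")
    traits_path = os.path.join(out_dir, "traits.csv")
    cfg_path = os.path.join(out_dir, "config.yaml")
    tree.write(tree_path)
    table.to_csv(traits_path)
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(
            {
                "seed": config.seed,
                "n_tips": config.n_tips,
                "birth": config.birth,
                "death": config.death,
                "dag_edges": [list(e) for e in config.dag_edges],
                "path_coefficients": {f"{a}->{b}": c for (a, b), c in
                                      config.path_coefficients.items()},
                "chrom_params": vars(config.chrom_params),
                "chrom_root_state": config.chrom_root_state,
            },
            fh,
        )
    return {"tree": tree_path, "traits": traits_path, "config": cfg_path}
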