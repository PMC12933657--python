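import networkx as nx
import numpy as np
import pandas as pd
import pytest

import divpath as dp


@pytest.fixture(scope="session")
def three_tip_tree():
    return dp.PhyloTree.from_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture(scope="session")
def yule50():
    """Shared 50-tip pure-birth tree."""
    return dp.simulate_tree(1.0, 0.0, 50, seed=101)


@pytest.fixture(scope="session")
def yule300():
    """Shared 300-tip pure-birth tree (used by the recovery tests)."""
    return dp.simulate_tree(1.0, 0.0, 300, seed=202)


@pytest.fixture(scope="session")
def chain_dag():
    """X -> Y -> Z generating model."""
    g = nx.DiGraph()
    g.add_edges_from([("X", "Y"), ("Y", "Z")])
    return g


def bm_tips_via_cholesky(tree, n_cols, rng, sigma2=1.0):
    """Independent-of-package Brownian tip sampler (test oracle)."""
    V = dp.phylo_vcv(tree).to_numpy() * sigma2
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
    cols = L @ rng.standard_normal((len(V), n_cols))
    return pd.DataFrame(cols, index=tree.tip_labels,
                        columns=[f"c{i}" for i in range(n_cols)])
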