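"""Phylogenetic trees, trait tables and Brownian covariance utilities.

Trees are stored as flat arrays (parent pointers, branch lengths, labels)
for fast likelihood traversals; Newick reading/writing is delegated to
:mod:`dendropy`.  Branch lengths are interpreted as time in Myr throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "read_newick",
    "phylo_vcv",
    "read_trait_table",
    "validate_species",
    "TRAIT_SCHEMA",
]


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed or lacks branch lengths."""


@dataclass
class PhyloTree:
    """Rooted phylogeny with branch lengths.

    Nodes are integers ``0..n_nodes-1`` in preorder (root first).  ``parent[i]``
    is the parent of node ``i`` (``-1`` for the root) and ``lengths[i]`` the
    length of the branch subtending ``i`` (0 for the root).  Tips carry unique
    string labels.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: dict  # node id -> tip label (tips only)

    _children: list = field(default=None, repr=False, compare=False)
    _postorder: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if (self.parent == -1).sum() != 1:
            raise ValueError("tree must have exactly one root")
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise ValueError("branch lengths must be finite and non-negative")
        n = len(self.parent)
        self._children = [[] for _ in range(n)]
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                self._children[p].append(i)
        tips = [i for i in range(n) if not self._children[i]]
        if set(self.labels) != set(tips):
            raise ValueError("labels must cover exactly the tip nodes")
        names = list(self.labels.values())
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        # depth-first postorder
        post, stack = [], [self.root]
        while stack:
            v = stack.pop()
            post.append(v)
            stack.extend(self._children[v])
        self._postorder = np.array(post[::-1], dtype=np.int64)

    # ------------------------------------------------------------------ basic
    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def children(self, i: int) -> list:
        return self._children[i]

    @property
    def postorder(self) -> np.ndarray:
        """Node ids, children always before parents."""
        return self._postorder

    @property
    def tip_ids(self) -> list:
        return sorted(self.labels)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_ids]

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    def node_of(self, label: str) -> int:
        for i, lab in self.labels.items():
            if lab == label:
                return i
        raise KeyError(label)

    def depths(self) -> np.ndarray:
        """Root-to-node distance for every node."""
        d = np.zeros(self.n_nodes)
        for v in self._postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    def tip_depths(self) -> np.ndarray:
        return self.depths()[self.tip_ids]

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return np.ptp(d) <= rtol * max(d.max(), 1e-12)

    def subtree_tips(self, node: int) -> list:
        """Tip node ids descending from ``node`` (including itself if a tip)."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if not self._children[v]:
                out.append(v)
            else:
                stack.extend(self._children[v])
        return sorted(out)

    def extract_subtree(self, node: int) -> "PhyloTree":
        """The clade rooted at ``node`` as a standalone tree (the branch
        above ``node`` is dropped)."""
        if not self.children(node):
            raise ValueError("cannot extract a subtree rooted at a tip")
        index = {node: 0}
        parent, lengths, labels = [-1], [0.0], {}
        stack = [node]
        while stack:
            v = stack.pop()
            for c in self._children[v]:
                index[c] = len(parent)
                parent.append(index[v])
                lengths.append(self.lengths[c])
                if not self._children[c]:
                    labels[index[c]] = self.labels[c]
                stack.append(c)
        return PhyloTree(np.array(parent), np.array(lengths), labels)

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes))
        labels = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    what = nd.taxon.label if nd.taxon else "an internal node"
                    raise NewickError(f"missing branch length on the edge above {what}")
                lengths[i] = nd.edge.length
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise NewickError("unlabeled tip in Newick input")
                labels[i] = nd.taxon.label
        return cls(parent, lengths, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            offset = getattr(exc, "column", None)
            loc = f" near character {offset}" if offset is not None else ""
            raise NewickError(f"malformed Newick{loc}: {exc}") from exc
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        parts = {}
        for v in self._postorder:
            if not self._children[v]:
                parts[v] = f"{self.labels[v]}:{self.lengths[v]:.17g}"
            else:
                inner = ",".join(parts[c] for c in self._children[v])
                if self.parent[v] == -1:
                    parts[v] = f"({inner}):{self.lengths[v]:.17g};"
                else:
                    parts[v] = f"({inner}):{self.lengths[v]:.17g}"
        return parts[self.root]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def read_newick(path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths from ``path``."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def phylo_vcv(tree: PhyloTree) -> pd.DataFrame:
    """Brownian-motion covariance among tips: shared root-to-MRCA path length.

    Returns a symmetric positive semi-definite matrix indexed by tip label,
    with root-to-tip distances on the diagonal.
    """
    if tree.n_tips < 2:
        raise ValueError("need at least two tips")
    depths = tree.depths()
    tips = tree.tip_ids
    pos = {t: k for k, t in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))
    V[np.diag_indices(n)] = depths[tips]
    # off-diagonals: for each internal node, tips in different child subtrees
    # share exactly depth[node]
    for v in range(tree.n_nodes):
        kids = tree.children(v)
        if len(kids) < 2:
            continue
        groups = [[pos[t] for t in tree.subtree_tips(c)] for c in kids]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.array(groups[a])[:, None]
                ib = np.array(groups[b])[None, :]
                V[ia, ib] = depths[v]
                V[ib.T, ia.T] = depths[v]
    return pd.DataFrame(V, index=tree.tip_labels, columns=tree.tip_labels)


#: default column schema for trait tables: name -> (dtype kind, constraint)
TRAIT_SCHEMA = {
    "chrom_n": ("int", "ge1"),
    "BIO1": ("float", None),
    "BIO4": ("float", None),
    "BIO7": ("float", None),
    "BIO12": ("float", None),
    "culm": ("float", "positive"),
    "spike": ("float", "positive"),
    "div_rate": ("float", None),
    "r_chrom": ("float", "nonneg"),
    "r_BIO4": ("float", "nonneg"),
    "r_culm": ("float", "nonneg"),
    "r_spike": ("float", "nonneg"),
}


def read_trait_table(path, schema: dict = None, sep: str = ",") -> pd.DataFrame:
    """Read a species-by-variable table; validate types against ``schema``.

    The table must have a ``species`` column, which becomes the index.  Only
    columns present in both the file and the schema are type-checked; extra
    file columns are kept as-is.
    """
    schema = TRAIT_SCHEMA if schema is None else schema
    df = pd.read_csv(path, sep=sep)
    if "species" not in df.columns:
        raise ValueError("trait table must contain a 'species' column")
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"].unique())
        raise ValueError(f"duplicated species: {dupes}")
    df = df.set_index("species")
    for col, (kind, constraint) in schema.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            rows = sorted(df.index[bad | df[col].isna()])
            raise ValueError(f"non-numeric or missing values in column {col!r}, rows {rows}")
        if kind == "int":
            if not np.allclose(vals, np.round(vals)):
                rows = sorted(df.index[~np.isclose(vals, np.round(vals))])
                raise ValueError(f"column {col!r} must be integer-valued; offending rows {rows}")
            df[col] = vals.round().astype(int)
        else:
            df[col] = vals.astype(float)
        if constraint == "ge1" and (df[col] < 1).any():
            raise ValueError(f"column {col!r} must be >= 1")
        if constraint == "positive" and (df[col] <= 0).any():
            raise ValueError(f"column {col!r} must be > 0")
        if constraint == "nonneg" and (df[col] < 0).any():
            raise ValueError(f"column {col!r} must be >= 0")
    return df


def validate_species(table: pd.DataFrame, tree: PhyloTree) -> dict:
    """Report set differences between table species and tree tips.

    Returns ``{"missing_from_table": [...], "extra_in_table": [...]}`` without
    dropping anything; callers decide how to reconcile.
    """
    tips = set(tree.tip_labels)
    spp = set(table.index)
    return {
        "missing_from_table": sorted(tips - spp),
        "extra_in_table": sorted(spp - tips),
    }
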