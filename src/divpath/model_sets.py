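"""Enumerated families of candidate causal models.

Three families of path hypotheses relate diversification (DI) to chromosome
number evolution, climate and morphology:

* ``rates`` — 48 models over evolutionary rates {R2n, RB4, RLI, RCU, DI};
* ``means`` — the same 48 structural templates over species means
  {C2n, B1, B4, B7, B12, LI, CU, DI};
* ``combined`` — 332 models over the union of both node sets, built from
  seven template groups (see :func:`build_combined_models`).

Every family carries a null (edge-free) competitor in addition to the
enumerated hypotheses, and a canonical variable order that fixes the
orientation of d-separation claims; both are part of the family definition
and are what make the family's regression counts well defined.

Structural templates
--------------------
Each model is one of six base hypotheses about the chromosome axis
(chromosome -> diversification, chromosome -> morphology, or both; each
optionally with climate -> chromosome), expanded by direct morphology and/or
climate effects on diversification (x4) and doubled by optional
climate -> morphology edges (x2): 6 x 4 x 2 = 48 templates.  A template is
instantiated by substituting node blocks for the chromosome / climate /
morphology roles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .ppa import basis_set

__all__ = [
    "ModelSet",
    "build_rate_models",
    "build_mean_models",
    "build_combined_models",
    "count_regressions",
    "group_sizes",
    "parse_dot_code",
    "model_to_dot_code",
]

#: trait-table column behind each model node
COLUMN_OF = {
    "DI": "div_rate",
    "C2n": "chrom_n",
    "B1": "BIO1",
    "B4": "BIO4",
    "B7": "BIO7",
    "B12": "BIO12",
    "LI": "spike",
    "CU": "culm",
    "R2n": "r_chrom",
    "RB4": "r_BIO4",
    "RLI": "r_spike",
    "RCU": "r_culm",
}

RATE_NODES = ("R2n", "RLI", "RCU", "RB4", "DI")
MEAN_NODES = ("C2n", "LI", "CU", "B1", "B4", "B7", "B12", "DI")
COMBINED_NODES = ("DI", "C2n", "R2n", "B1", "B4", "B7", "B12", "RB4",
                  "LI", "CU", "RLI", "RCU")

# the six base hypotheses: (chrom->DI, chrom->morph, bio->chrom)
_BASES = [(1, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
_EXPANSIONS = [(0, 0), (1, 0), (0, 1), (1, 1)]  # (morph->DI, bio->DI)


@dataclass(frozen=True)
class _Roles:
    """Node blocks substituted into the structural templates."""

    chrom: tuple
    bio: tuple
    morph: tuple
    tokens: dict  # role -> dot-code token


def _template_edges(roles, base, expansion, bio_morph):
    chrom_di, chrom_morph, bio_chrom = base
    morph_di, bio_di = expansion
    edges = set()
    if chrom_di:
        edges |= {(c, "DI") for c in roles.chrom}
    if chrom_morph:
        edges |= {(c, m) for c in roles.chrom for m in roles.morph}
    if bio_chrom:
        edges |= {(b, c) for b in roles.bio for c in roles.chrom}
    if morph_di:
        edges |= {(m, "DI") for m in roles.morph}
    if bio_di:
        edges |= {(b, "DI") for b in roles.bio}
    if bio_morph:
        edges |= {(b, m) for b in roles.bio for m in roles.morph}
    return frozenset(edges)


def _dot_code(roles, base, expansion, bio_morph):
    chrom_di, chrom_morph, bio_chrom = base
    morph_di, bio_di = expansion
    t = roles.tokens
    segments = []
    di_sources = ([t["chrom"]] if chrom_di else []) + \
                 ([t["morph"]] if morph_di else []) + \
                 ([t["bio"]] if bio_di else [])
    if di_sources:
        segments.append(".".join(["d"] + di_sources))
    if bio_chrom:
        segments.append(f"{t['chrom']}.{t['bio']}")
    morph_sources = ([t["chrom"]] if chrom_morph else []) + \
                    ([t["bio"]] if bio_morph else [])
    if morph_sources:
        segments.append(".".join([t["morph"]] + morph_sources))
    return "..".join(segments) if segments else "null"


def _instantiate_family(roles):
    """48 (model id, edge set) pairs in canonical template order."""
    out = []
    for bio_morph in (0, 1):
        for base in _BASES:
            for expansion in _EXPANSIONS:
                out.append((_dot_code(roles, base, expansion, bio_morph),
                            _template_edges(roles, base, expansion, bio_morph)))
    return out


def parse_dot_code(code: str, roles: _Roles) -> frozenset:
    """Parse a model code like ``d.2n..2n.bio..mor.bio`` back to an edge set.

    Grammar: segments joined by ``..``; segment ``d.<tok>...`` lists the
    predictors of DI; segment ``<tok>.<tok>...`` lists the predictors of its
    first token.  Tokens expand to the role's node block.
    """
    if code == "null":
        return frozenset()
    block = {roles.tokens["chrom"]: roles.chrom,
             roles.tokens["bio"]: roles.bio,
             roles.tokens["morph"]: roles.morph}
    edges = set()
    for seg in code.split(".."):
        parts = seg.split(".")
        head, sources = parts[0], parts[1:]
        targets = ("DI",) if head == "d" else block[head]
        for src in sources:
            edges |= {(a, b) for a in block[src] for b in targets}
    return frozenset(edges)


def model_to_dot_code(edges: frozenset, roles: _Roles) -> str:
    """Inverse of :func:`parse_dot_code` for models built from the templates."""
    for bio_morph in (0, 1):
        for base in _BASES:
            for expansion in _EXPANSIONS:
                if _template_edges(roles, base, expansion, bio_morph) == frozenset(edges):
                    return _dot_code(roles, base, expansion, bio_morph)
    raise ValueError("edge set does not match any structural template")


@dataclass
class ModelSet:
    """A named family of candidate DAGs sharing one variable universe.

    ``models`` holds the enumerated hypothesis models (id -> DAG); the null
    competitor is implicit and supplied by :meth:`with_null`, which is what
    ranking and regression counting operate on.
    """

    name: str
    nodes: tuple
    models: dict
    groups: dict = field(default_factory=dict)  # model id -> provenance group

    def __post_init__(self):
        seen = set()
        for mid, dag in self.models.items():
            if not nx.is_directed_acyclic_graph(dag):
                raise ValueError(f"model {mid!r} is cyclic")
            key = frozenset(dag.edges)
            if key in seen:
                raise ValueError(f"duplicate model {mid!r}")
            seen.add(key)

    def __len__(self):
        return len(self.models)

    def with_null(self) -> dict:
        """Hypothesis models plus the edge-free null competitor."""
        null = nx.DiGraph()
        null.add_nodes_from(self.nodes)
        out = dict(self.models)
        out["null"] = null
        return out

    def manifest(self):
        import pandas as pd

        rows = [(mid, self.groups.get(mid, self.name),
                 dag.number_of_edges(),
                 ";".join(f"{a}->{b}" for a, b in sorted(dag.edges)))
                for mid, dag in self.models.items()]
        return pd.DataFrame(rows, columns=["model", "group", "n_edges", "edges"])


def _as_digraph(edges, nodes):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


_RATE_ROLES = _Roles(chrom=("R2n",), bio=("RB4",), morph=("RLI", "RCU"),
                     tokens={"chrom": "r2n", "bio": "rbio", "morph": "rmor"})
_MEAN_ROLES = _Roles(chrom=("C2n",), bio=("B1", "B4", "B7", "B12"), morph=("LI", "CU"),
                     tokens={"chrom": "2n", "bio": "bio", "morph": "mor"})

#: the seven template groups of the combined family, in dedup order
_COMBINED_ROLES = [
    ("rates", _RATE_ROLES),
    ("means", _MEAN_ROLES),
    ("rates_chrom_both", _Roles(chrom=("C2n", "R2n"), bio=("RB4",),
                                morph=("RLI", "RCU"),
                                tokens={"chrom": "b2n", "bio": "rbio", "morph": "rmor"})),
    ("means_chrom_both", _Roles(chrom=("C2n", "R2n"), bio=("B1", "B4", "B7", "B12"),
                                morph=("LI", "CU"),
                                tokens={"chrom": "b2n", "bio": "bio", "morph": "mor"})),
    ("means_chrom_rates", _Roles(chrom=("R2n",), bio=("B1", "B4", "B7", "B12"),
                                 morph=("LI", "CU"),
                                 tokens={"chrom": "r2n", "bio": "bio", "morph": "mor"})),
    ("rates_chrom_means", _Roles(chrom=("C2n",), bio=("RB4",), morph=("RLI", "RCU"),
                                 tokens={"chrom": "2n", "bio": "rbio", "morph": "rmor"})),
    ("all_means_and_rates", _Roles(chrom=("C2n", "R2n"),
                                   bio=("B1", "B4", "B7", "B12", "RB4"),
                                   morph=("LI", "CU", "RLI", "RCU"),
                                   tokens={"chrom": "b2n", "bio": "bbio", "morph": "bmor"})),
]


def build_rate_models() -> ModelSet:
    """The 48 evolutionary-rate models over {R2n, RB4, RLI, RCU, DI}."""
    models, groups = {}, {}
    for mid, edges in _instantiate_family(_RATE_ROLES):
        models[mid] = _as_digraph(edges, RATE_NODES)
        groups[mid] = "rates"
    return ModelSet("rates", RATE_NODES, models, groups)


def build_mean_models() -> ModelSet:
    """The 48 species-mean models over {C2n, B1, B4, B7, B12, LI, CU, DI}."""
    models, groups = {}, {}
    for mid, edges in _instantiate_family(_MEAN_ROLES):
        models[mid] = _as_digraph(edges, MEAN_NODES)
        groups[mid] = "means"
    return ModelSet("means", MEAN_NODES, models, groups)


def build_combined_models() -> ModelSet:
    """The 332 combined models over all twelve variables.

    Seven template groups are instantiated and deduplicated in order: the
    rates family, the means family, both families with the chromosome role
    widened to {C2n, R2n}, the means family with C2n replaced by R2n, the
    rates family with R2n replaced by C2n, and the all-blocks group in which
    every role carries both the species means and their rates.  Each group
    after the third loses exactly its base model (chromosome -> DI only) to
    an earlier group, giving 3 x 48 + 4 x 47 = 332 distinct models.
    """
    models, groups, seen = {}, {}, set()
    for group_name, roles in _COMBINED_ROLES:
        for mid, edges in _instantiate_family(roles):
            if edges in seen:
                continue
            seen.add(edges)
            models[mid] = _as_digraph(edges, COMBINED_NODES)
            groups[mid] = group_name
    return ModelSet("combined", COMBINED_NODES, models, groups)


def group_sizes(model_set: ModelSet) -> dict:
    """Number of models retained per provenance group after deduplication."""
    out = {}
    for mid in model_set.models:
        g = model_set.groups.get(mid, model_set.name)
        out[g] = out.get(g, 0) + 1
    return out


def count_regressions(model_set: ModelSet) -> tuple:
    """(total, unique) d-separation regressions over the family.

    Total sums basis-set sizes over all candidates (hypotheses plus the null
    competitor); unique counts distinct regressions keyed by (response,
    predictor set), the deduplication the regression cache performs when the
    family is fitted.
    """
    total = 0
    uniq = set()
    for mid, dag in model_set.with_null().items():
        claims = basis_set(dag, model_set.nodes)
        total += len(claims)
        uniq |= {c.regression_key for c in claims}
    return total, len(uniq)
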