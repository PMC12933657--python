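"""Clade regime assignment shared by simulators and multi-regime fitters."""

from __future__ import annotations

import numpy as np

from .phylo import PhyloTree

__all__ = ["branch_regime_array"]


def branch_regime_array(tree: PhyloTree, shifts: dict) -> np.ndarray:
    """Regime id of every branch (indexed by child node), inherited from the
    nearest ancestral shift.  ``shifts`` maps node id -> regime id; the shift
    applies to the branch subtending the node and everything below it.  The
    root must be assigned."""
    if tree.root not in shifts:
        raise ValueError("shift map must assign a regime to the root")
    reg = np.full(tree.n_nodes, -1, dtype=int)
    for v in tree.postorder[::-1]:  # preorder
        if v in shifts:
            reg[v] = shifts[v]
        else:
            reg[v] = reg[tree.parent[v]]
    return reg
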