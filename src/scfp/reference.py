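"""Declarative reference implementation of the connectivity rule.

The production :func:`scfp.fingerprint.connect_hits` walks breadth-first from
each hit through unmatched atoms.  This module restates the rule
declaratively — two hits are connected iff they share an atom or some simple
path between their atom sets has every interior atom unmatched by every hit —
and checks it by exhaustive simple-path enumeration with networkx.

It is deliberately independent of the BFS code (no shared traversal logic)
and exponential in molecule size, so it is suitable only for validating the
fast implementation on small molecules (roughly <= 12 heavy atoms).
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx

from .chem_graph import MolecularGraph
from .fingerprint import SubstructureHit


def connected_pairs_bruteforce(mol: MolecularGraph,
                               hits: Sequence[SubstructureHit],
                               cutoff: int | None = None) -> set[frozenset[int]]:
    """All connected hit pairs by exhaustive simple-path enumeration."""
    g = nx.Graph()
    g.add_nodes_from(range(mol.num_atoms))
    g.add_edges_from((i, j) for i, j, _ in mol.bonds)

    matched: set[int] = set()
    for h in hits:
        matched |= h.atom_indices

    pairs: set[frozenset[int]] = set()
    for hi in range(len(hits)):
        for hj in range(hi + 1, len(hits)):
            a_atoms, b_atoms = hits[hi].atom_indices, hits[hj].atom_indices
            if a_atoms & b_atoms:
                pairs.add(frozenset((hi, hj)))
                continue
            if _joined_by_unmatched_path(g, a_atoms, b_atoms, matched, cutoff):
                pairs.add(frozenset((hi, hj)))
    return pairs


def _joined_by_unmatched_path(g: nx.Graph, a_atoms: frozenset[int],
                              b_atoms: frozenset[int], matched: set[int],
                              cutoff: int | None) -> bool:
    for a in a_atoms:
        for b in b_atoms:
            for path in nx.all_simple_paths(g, a, b, cutoff=cutoff):
                interior = path[1:-1]
                if all(atom not in matched for atom in interior):
                    return True
    return False
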