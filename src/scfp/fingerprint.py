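"""Substructural connectivity fingerprints (SCFP).

A key-based fingerprint records, for each SMARTS key, whether it occurs in a
molecule.  The SCFP extends this to a K x K symmetric binary matrix: the
diagonal records key occurrence and an off-diagonal bit (i, j) records that
some match of key i is *connected* to some match of key j in the molecular
graph.

Connectivity semantics
----------------------
Two substructure hits are connected iff

* their atom sets share at least one atom (atom-sharing connection), or
* some path in the molecular graph from an atom of one hit to an atom of the
  other has every interior atom unmatched by *every* hit (any matched
  substructure blocks, including other instances of the same key).

The implementation walks breadth-first from each hit's atoms through
unmatched atoms only; :mod:`scfp.reference` provides the equivalent
declarative path-enumeration definition used as a test oracle.

Connection multiplicity is not recorded: repeated connections between the
same pair of keys collapse to a single bit, and a connection between two
instances of the same key is absorbed into that key's (already set)
diagonal occurrence bit.
"""

from __future__ import annotations

import csv
import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chem_graph import KeySet, MolecularGraph

MAX_DENSE_K = 1024  # dense export guard: KR-sized key sets stay sparse


@dataclass(frozen=True)
class SubstructureHit:
    """One match of one key: key index plus the matched atom-index set."""

    key_index: int
    atom_indices: frozenset[int]

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise ValueError("a hit must cover at least one atom")


@dataclass
class SubstructureGraph:
    """Reduced graph whose nodes are hits plus unmatched-atom singletons.

    Two nodes are adjacent iff their atom sets intersect or a molecular bond
    joins them.  Every atom of the molecule is covered by at least one node.
    """

    hit_nodes: list[SubstructureHit]
    singleton_atoms: list[int]  # atoms matched by no key, each its own node
    edges: set[tuple[int, int]]  # node indices (hits first, then singletons)

    @property
    def num_nodes(self) -> int:
        return len(self.hit_nodes) + len(self.singleton_atoms)

    def node_atoms(self, node: int) -> frozenset[int]:
        if node < len(self.hit_nodes):
            return self.hit_nodes[node].atom_indices
        return frozenset({self.singleton_atoms[node - len(self.hit_nodes)]})


def find_hits(mol: MolecularGraph, keys: KeySet) -> list[SubstructureHit]:
    """All distinct atom-set matches of every key against the molecule.

    Symmetry-equivalent matches covering identical atom sets are
    deduplicated; matches with distinct atom sets are distinct hits.
    """
    hits: list[SubstructureHit] = []
    for key in keys:
        seen: set[frozenset[int]] = set()
        for match in mol.rdmol.GetSubstructMatches(key.pattern, uniquify=True,
                                                   maxMatches=100000):
            atoms = frozenset(match)
            if atoms not in seen:
                seen.add(atoms)
                hits.append(SubstructureHit(key.key_index, atoms))
    return hits


def build_substructure_graph(mol: MolecularGraph,
                             hits: Sequence[SubstructureHit]) -> SubstructureGraph:
    """Substitute the molecular graph with the reduced substructure graph."""
    matched: set[int] = set()
    for h in hits:
        matched |= h.atom_indices
    singletons = [a for a in range(mol.num_atoms) if a not in matched]
    nodes_atoms = [h.atom_indices for h in hits] + [frozenset({a}) for a in singletons]
    adj = mol.neighbors()
    edges: set[tuple[int, int]] = set()
    for u in range(len(nodes_atoms)):
        for v in range(u + 1, len(nodes_atoms)):
            au, av = nodes_atoms[u], nodes_atoms[v]
            if au & av:
                edges.add((u, v))
                continue
            if any(nb in av for a in au for nb in adj[a]):
                edges.add((u, v))
    return SubstructureGraph(hit_nodes=list(hits), singleton_atoms=singletons,
                             edges=edges)


def connect_hits(mol: MolecularGraph,
                 hits: Sequence[SubstructureHit]) -> set[frozenset[int]]:
    """Connected pairs of hits, as frozensets of two hit list-indices.

    Breadth-first walk from each hit's atoms through unmatched atoms only;
    reaching an atom of another hit records a connection and stops the walk
    along that branch (a matched substructure blocks).  Hits sharing an atom
    are connected outright.
    """
    atom_to_hits: dict[int, set[int]] = {}
    for hi, h in enumerate(hits):
        for a in h.atom_indices:
            atom_to_hits.setdefault(a, set()).add(hi)

    pairs: set[frozenset[int]] = set()
    # atom-sharing connections
    for owners in atom_to_hits.values():
        if len(owners) > 1:
            owners_sorted = sorted(owners)
            for x in range(len(owners_sorted)):
                for y in range(x + 1, len(owners_sorted)):
                    pairs.add(frozenset((owners_sorted[x], owners_sorted[y])))

    adj = mol.neighbors()
    for hi, h in enumerate(hits):
        visited: set[int] = set(h.atom_indices)
        queue: deque[int] = deque(h.atom_indices)
        while queue:
            a = queue.popleft()
            for nb in adj[a]:
                if nb in visited:
                    continue
                owners = atom_to_hits.get(nb)
                if owners:
                    # matched atom: record connections, do not walk through
                    for hj in owners:
                        if hj != hi:
                            pairs.add(frozenset((hi, hj)))
                else:
                    visited.add(nb)
                    queue.append(nb)
    return pairs


@dataclass(frozen=True)
class FingerprintVector:
    """Binary fingerprint vector: plain (length K) or linearized SCFP
    (length K(K+1)/2, upper triangle row-major including the diagonal)."""

    bits: np.ndarray
    kind: str  # "plain" | "scfp_linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.uint8))
        if self.kind not in ("plain", "scfp_linear"):
            raise ValueError(f"unknown fingerprint kind: {self.kind!r}")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")

    @property
    def length(self) -> int:
        return int(self.bits.size)

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FingerprintVector):
            return NotImplemented
        return self.kind == other.kind and np.array_equal(self.bits, other.bits)


def _tri_index(i: int, j: int, K: int) -> int:
    """Row-major upper-triangle (incl. diagonal) position of (i, j), i <= j."""
    return i * K - (i * (i - 1)) // 2 + (j - i)


@dataclass
class SCFPMatrix:
    """K x K symmetric binary occurrence-and-connection matrix.

    Stored sparsely as the set of set bits ``(i, j)`` with ``i <= j`` in the
    upper triangle; ``(i, i)`` records occurrence of key i, ``(i, j)`` with
    ``i < j`` records a connection between keys i and j.
    """

    K: int
    bits: frozenset[tuple[int, int]]
    key_set_name: str = ""
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.bits = frozenset(
            (min(i, j), max(i, j)) for i, j in self.bits
        )
        for i, j in self.bits:
            if not (0 <= i <= j < self.K):
                raise ValueError(f"bit ({i},{j}) out of range for K={self.K}")
        diag = {i for i, j in self.bits if i == j}
        for i, j in self.bits:
            if i != j and (i not in diag or j not in diag):
                raise ValueError(
                    f"connection bit ({i},{j}) without both occurrence bits"
                )

    def __getitem__(self, ij: tuple[int, int]) -> int:
        i, j = ij
        return 1 if (min(i, j), max(i, j)) in self.bits else 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SCFPMatrix):
            return NotImplemented
        return self.K == other.K and self.bits == other.bits

    @property
    def diagonal(self) -> np.ndarray:
        d = np.zeros(self.K, dtype=np.uint8)
        for i, j in self.bits:
            if i == j:
                d[i] = 1
        return d

    def to_dense(self) -> np.ndarray:
        if self.K > MAX_DENSE_K:
            raise ValueError(
                f"dense export disallowed for K={self.K} > {MAX_DENSE_K}"
            )
        m = np.zeros((self.K, self.K), dtype=np.uint8)
        for i, j in self.bits:
            m[i, j] = m[j, i] = 1
        return m

    def to_linear(self) -> FingerprintVector:
        """Upper triangle incl. diagonal, row-major by ascending key index."""
        vec = np.zeros(self.K * (self.K + 1) // 2, dtype=np.uint8)
        for i, j in self.bits:
            vec[_tri_index(i, j, self.K)] = 1
        return FingerprintVector(bits=vec, kind="scfp_linear")

    def to_coordinate(self) -> list[tuple[int, int]]:
        """Ascending lexicographic list of set bits (i, j), i <= j, 0-based."""
        return sorted(self.bits)

    @classmethod
    def from_linear(cls, vec: FingerprintVector | np.ndarray, K: int,
                    **meta: str) -> "SCFPMatrix":
        bits_arr = vec.bits if isinstance(vec, FingerprintVector) else np.asarray(vec)
        if bits_arr.size != K * (K + 1) // 2:
            raise ValueError("linear vector length does not match K(K+1)/2")
        bits = set()
        pos = 0
        for i in range(K):
            for j in range(i, K):
                if bits_arr[pos]:
                    bits.add((i, j))
                pos += 1
        return cls(K=K, bits=frozenset(bits), **meta)

    @classmethod
    def from_coordinate(cls, coords: Iterable[tuple[int, int]], K: int,
                        **meta: str) -> "SCFPMatrix":
        return cls(K=K, bits=frozenset((int(i), int(j)) for i, j in coords), **meta)


def compute_scfp(mol: MolecularGraph, keys: KeySet) -> SCFPMatrix:
    """Build the SCFP matrix of a molecule under a key set."""
    hits = find_hits(mol, keys)
    bits: set[tuple[int, int]] = {(h.key_index, h.key_index) for h in hits}
    for pair in connect_hits(mol, hits):
        pair_list = sorted(pair)
        ki = hits[pair_list[0]].key_index
        kj = hits[pair_list[1]].key_index
        if ki != kj:  # same-key connections are absorbed into the diagonal
            bits.add((min(ki, kj), max(ki, kj)))
    return SCFPMatrix(K=keys.K, bits=frozenset(bits),
                      key_set_name=keys.name, molecule_id=mol.source_id)


def compute_plain_fp(mol: MolecularGraph, keys: KeySet) -> FingerprintVector:
    """Plain key-based fingerprint: bit k set iff key k matches the molecule.

    Equals the diagonal of :func:`compute_scfp` by construction.
    """
    bits = np.zeros(keys.K, dtype=np.uint8)
    for key in keys:
        if mol.rdmol.HasSubstructMatch(key.pattern):
            bits[key.key_index] = 1
    return FingerprintVector(bits=bits, kind="plain")


# --- serialization -----------------------------------------------------------

def write_linear_csv(path: str | Path, ids: Sequence[str],
                     vectors: Sequence[FingerprintVector],
                     key_set_name: str, K: int) -> None:
    """Linear notation: CSV ``id,bitstring`` plus a JSON sidecar recording
    the key set, K, notation and the fixed ordering convention."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "bitstring"])
        for mol_id, vec in zip(ids, vectors):
            writer.writerow([mol_id, vec.to_bitstring()])
    sidecar = {
        "key_set_name": key_set_name,
        "K": K,
        "notation": {v.kind for v in vectors}.pop() if vectors else "scfp_linear",
        "ordering": "upper triangle row-major including diagonal, 0-based",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def write_coordinate_file(path: str | Path, ids: Sequence[str],
                          matrices: Sequence[SCFPMatrix]) -> None:
    """Coordinate notation: ``id <TAB> i:j,i:j,...`` per molecule."""
    lines = ["# 0-based, upper triangle, diagonal=occurrence"]
    for mol_id, m in zip(ids, matrices):
        coords = ",".join(f"{i}:{j}" for i, j in m.to_coordinate())
        lines.append(f"{mol_id}\t{coords}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_coordinate_file(path: str | Path, K: int) -> list[SCFPMatrix]:
    matrices = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        mol_id, _, coords = line.partition("\t")
        bits = []
        if coords.strip():
            for tok in coords.strip().split(","):
                i, _, j = tok.partition(":")
                bits.append((int(i), int(j)))
        matrices.append(SCFPMatrix.from_coordinate(bits, K=K, molecule_id=mol_id))
    return matrices


def write_matrix_files(outdir: str | Path, ids: Sequence[str],
                       matrices: Sequence[SCFPMatrix]) -> list[Path]:
    """Matrix notation: one sparse coordinate-list file per molecule."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for mol_id, m in zip(ids, matrices):
        p = outdir / f"{mol_id}.scfp"
        lines = [f"# SCFP sparse matrix, K={m.K}, key_set={m.key_set_name}",
                 "# 0-based (i, j) upper-triangle set bits, diagonal=occurrence"]
        lines += [f"{i}\t{j}" for i, j in m.to_coordinate()]
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    return paths
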