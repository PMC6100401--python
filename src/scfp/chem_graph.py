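"""Molecular graphs and SMARTS key sets.

Molecules are parsed with RDKit into hydrogen-suppressed graphs (implicit
hydrogens satisfy SMARTS H-count constraints, as is standard for key-based
fingerprints).  Substructure key sets are ordered lists of SMARTS patterns
with stable 0-based indices; a bundled MACCS-166-style set is provided and
user key files are plain two-column text (``key_id <TAB> SMARTS``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import rdBase

logger = logging.getLogger(__name__)

#: How aromaticity is perceived; recorded in run metadata because MACCS-style
#: SMARTS are dialect-sensitive.
AROMATICITY_MODEL = "rdkit-default"


class MoleculeParseError(ValueError):
    """A molecule record could not be parsed."""


class KeySetError(ValueError):
    """A key set failed validation (bad SMARTS, duplicate ids, ...)."""


@dataclass(frozen=True)
class Atom:
    symbol: str
    formal_charge: int
    aromatic: bool


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed atom/bond graph of one compound.

    Atom indices are 0-based and contiguous, in RDKit's (deterministic)
    input order.  The graph may be disconnected (salts / multi-fragment
    records are kept as-is).
    """

    atoms: list[Atom]
    bonds: set[tuple[int, int, str]]  # (i, j, bond type) with i < j
    source_id: str
    source_text: str
    rdmol: Chem.Mol = field(repr=False, compare=False, default=None)

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    @property
    def num_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self) -> dict[int, set[int]]:
        """Adjacency map over atom indices."""
        adj: dict[int, set[int]] = {i: set() for i in range(self.num_atoms)}
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def to_canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)


@dataclass(frozen=True)
class Key:
    key_index: int
    key_id: str
    smarts: str
    pattern: Chem.Mol = field(repr=False, compare=False)


@dataclass
class KeySet:
    """Ordered list of SMARTS substructure keys with stable indices."""

    keys: list[Key]
    name: str

    def __post_init__(self) -> None:
        if not self.keys:
            raise KeySetError("a key set must contain at least one key")
        ids = [k.key_id for k in self.keys]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise KeySetError(f"duplicate key_id(s): {dup}")
        for pos, k in enumerate(self.keys):
            if k.key_index != pos:
                raise KeySetError(
                    f"key_index {k.key_index} does not match position {pos}"
                )

    @property
    def K(self) -> int:
        return len(self.keys)

    def __len__(self) -> int:
        return len(self.keys)

    def __iter__(self):
        return iter(self.keys)

    def index_of(self, key_id: str) -> int:
        for k in self.keys:
            if k.key_id == key_id:
                return k.key_index
        raise KeyError(key_id)


def _graph_from_rdmol(mol: Chem.Mol, source_id: str, source_text: str) -> MolecularGraph:
    atoms = [
        Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
        for a in mol.GetAtoms()
    ]
    bonds: set[tuple[int, int, str]] = set()
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        bonds.add((i, j, str(b.GetBondType())))
    return MolecularGraph(atoms=atoms, bonds=bonds, source_id=source_id,
                          source_text=source_text, rdmol=mol)


def parse_molecule(text: str, fmt: str = "smiles", source_id: str = "") -> MolecularGraph:
    """Parse one molecule record into a :class:`MolecularGraph`.

    Parameters
    ----------
    text : the record -- a SMILES string or a MOL/SDF V2000 block.
    fmt : one of ``smiles``, ``mol``, ``sdf``.
    """
    if not text or not text.strip():
        raise MoleculeParseError("empty molecule record")
    fmt = fmt.lower()
    with rdBase.BlockLogs():
        if fmt == "smiles":
            smiles = text.strip().split()[0]
            mol = Chem.MolFromSmiles(smiles)
        elif fmt in ("mol", "sdf"):
            mol = Chem.MolFromMolBlock(text)
        else:
            raise ValueError(f"unknown molecule format: {fmt!r}")
    if mol is None:
        raise MoleculeParseError(f"could not parse {fmt} record: {text.strip()[:80]!r}")
    mol = Chem.RemoveHs(mol)
    return _graph_from_rdmol(mol, source_id, text.strip())


@dataclass(frozen=True)
class MoleculeRecord:
    """One line of a SMILES file: SMILES plus optional id / activity columns."""

    smiles: str
    mol_id: str
    activity_nM: float | None = None
    activity_type: str | None = None  # "Ki" or "IC50"
    label: int | None = None


def read_smiles_records(path: str | Path) -> list[MoleculeRecord]:
    """Read a SMILES file: one record per line, tab-separated optional columns
    ``SMILES <TAB> id <TAB> activity_nM <TAB> activity_type(Ki|IC50)``.

    A third column that is an integer 0/1 is interpreted as a class label
    (the dataset dialect written by the synthetic generator).
    """
    records: list[MoleculeRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        smiles = cols[0].strip()
        mol_id = cols[1].strip() if len(cols) > 1 and cols[1].strip() else f"mol_{lineno}"
        activity = None
        act_type = None
        label = None
        if len(cols) > 2 and cols[2].strip():
            third = cols[2].strip()
            if len(cols) > 3 and cols[3].strip().upper() in ("KI", "IC50"):
                activity = float(third)
                act_type = "Ki" if cols[3].strip().upper() == "KI" else "IC50"
            elif third in ("0", "1"):
                label = int(third)
            else:
                activity = float(third)
                act_type = "Ki"
        records.append(MoleculeRecord(smiles, mol_id, activity, act_type, label))
    return records


def parse_molecule_file(path: str | Path, fmt: str = "smiles",
                        strict: bool = False) -> list[MolecularGraph]:
    """Parse every record of a molecule file, preserving file order.

    Records that fail to parse are skipped with a warning, or fatal when
    ``strict`` is set.  An empty file yields an empty list plus a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt.lower()
    graphs: list[MolecularGraph] = []
    if fmt == "smiles":
        records = read_smiles_records(path)
        if not records:
            warnings.warn(f"no molecule records in {path}")
            return []
        for recno, rec in enumerate(records, start=1):
            try:
                graphs.append(parse_molecule(rec.smiles, "smiles", source_id=rec.mol_id))
            except MoleculeParseError as exc:
                if strict:
                    raise MoleculeParseError(f"record {recno} of {path}: {exc}") from exc
                warnings.warn(f"skipping record {recno} of {path}: {exc}")
    elif fmt in ("sdf", "mol"):
        with rdBase.BlockLogs():
            supplier = Chem.SDMolSupplier(str(path), removeHs=True)
            mols = list(supplier)
        if not mols:
            warnings.warn(f"no molecule records in {path}")
            return []
        for recno, mol in enumerate(mols, start=1):
            if mol is None:
                msg = f"unparsable record {recno} of {path}"
                if strict:
                    raise MoleculeParseError(msg)
                warnings.warn("skipping " + msg)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol_{recno}"
            graphs.append(_graph_from_rdmol(mol, name, Chem.MolToSmiles(mol)))
    else:
        raise ValueError(f"unknown molecule format: {fmt!r}")
    return graphs


# --- key sets ---------------------------------------------------------------

#: MACCS keys that are count-based in the original definition (number of
#: isotopes / aromatic rings / fragments) and have no single-SMARTS form.
#: They are kept as inert placeholders so the set keeps K = 166 stable
#: indices; the placeholder matches no organic molecule.
_MACCS_COUNT_KEYS = {1, 125, 166}
_INERT_SMARTS = "[#104]"


def _maccs_key_set() -> KeySet:
    from rdkit.Chem import MACCSkeys

    keys: list[Key] = []
    for pos, num in enumerate(sorted(MACCSkeys.smartsPatts)):
        smarts, _count = MACCSkeys.smartsPatts[num]
        if smarts == "?":
            assert num in _MACCS_COUNT_KEYS
            smarts = _INERT_SMARTS
        pattern = Chem.MolFromSmarts(smarts)
        if pattern is None:  # pragma: no cover - library data is well-formed
            raise KeySetError(f"MACCS key {num}: bad SMARTS {smarts!r}")
        keys.append(Key(pos, f"MACCS_{num}", smarts, pattern))
    return KeySet(keys=keys, name="maccs")


def key_set_from_pairs(pairs: Iterable[tuple[str, str]], name: str) -> KeySet:
    """Build a validated KeySet from ``(key_id, smarts)`` pairs, order kept."""
    keys: list[Key] = []
    seen: set[str] = set()
    for pos, (key_id, smarts) in enumerate(pairs):
        if key_id in seen:
            raise KeySetError(f"duplicate key_id: {key_id!r}")
        seen.add(key_id)
        with rdBase.BlockLogs():
            pattern = Chem.MolFromSmarts(smarts)
        if pattern is None:
            raise KeySetError(f"key {key_id!r}: malformed SMARTS {smarts!r}")
        keys.append(Key(pos, key_id, smarts, pattern))
    return KeySet(keys=keys, name=name)


def load_key_set(path_or_name: str | Path) -> KeySet:
    """Load a key set by built-in name (``maccs``) or from a two-column file.

    File format: one key per line, ``key_id <TAB> SMARTS``; lines starting
    with ``#`` are ignored.  Every SMARTS is validated at load time.
    """
    if str(path_or_name).lower() == "maccs":
        return _maccs_key_set()
    path = Path(path_or_name)
    if not path.exists():
        raise FileNotFoundError(f"key set file not found: {path}")
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(parts) != 2:
            raise KeySetError(f"{path}:{lineno}: expected 'key_id<TAB>SMARTS'")
        pairs.append((parts[0].strip(), parts[1].strip()))
    if not pairs:
        raise KeySetError(f"{path}: no keys found")
    return key_set_from_pairs(pairs, name=path.stem)
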