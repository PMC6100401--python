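"""Synthetic molecule sets with controlled connectivity degeneracy.

Key-based fingerprints cannot distinguish molecules that contain the same
functional groups in different arrangements.  This module generates exactly
such molecules: linear alkyl scaffolds carrying two terminal groups and two
in-chain groups, where reordering the in-chain groups preserves the plain
key-based fingerprint but changes which groups are connected, hence the
SCFP.  Every emitted pair is verified against the fingerprint module at
generation time; non-conforming draws are rejected and resampled.

The group library (hydroxyl, primary amine, carbonyl, carboxyl, aromatic
ring, halogen, ether) is chosen so that both blocking cases (an intervening
matched group severs a connection) and atom-sharing cases (the carboxyl
match overlaps the hydroxyl and carbonyl matches) occur.

Activity labeling follows the usual virtual-screening convention: actives
are compounds with Ki < 100 nM, inactives Ki > 1000 nM, the band between is
discarded, and IC50 values are converted with Ki = IC50 / 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .chem_graph import KeySet, key_set_from_pairs, parse_molecule
from .fingerprint import SCFPMatrix, compute_plain_fp, compute_scfp

logger = logging.getLogger(__name__)

ACTIVE_THRESHOLD_NM = 100.0
INACTIVE_THRESHOLD_NM = 1000.0


class GenerationError(RuntimeError):
    """The generator exhausted its resampling budget or produced one class."""


# --- activity labeling --------------------------------------------------------

@dataclass(frozen=True)
class ActivityRecord:
    molecule_id: str
    value: float  # nM
    type: str  # "Ki" | "IC50"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"{self.molecule_id}: activity must be positive")
        if self.type not in ("Ki", "IC50"):
            raise ValueError(f"{self.molecule_id}: unknown activity type {self.type!r}")

    @property
    def ki_nM(self) -> float:
        return self.value / 2.0 if self.type == "IC50" else self.value


def label_by_activity(records: Sequence[ActivityRecord]) -> list[str]:
    """Ki < 100 nM -> ``active``; Ki > 1000 nM -> ``inactive``; the band in
    between (inclusive of the thresholds) -> ``discarded``.  IC50 values are
    converted first via Ki = IC50/2.  Discarded compounds are returned
    explicitly so set sizes stay auditable."""
    labels = []
    for rec in records:
        ki = rec.ki_nM
        if ki < ACTIVE_THRESHOLD_NM:
            labels.append("active")
        elif ki > INACTIVE_THRESHOLD_NM:
            labels.append("inactive")
        else:
            labels.append("discarded")
    return labels


# --- functional group library ---------------------------------------------------

@dataclass(frozen=True)
class Group:
    name: str
    smarts: str
    terminal: str | None  # SMILES token usable at the chain end (right form)
    terminal_left: str | None  # prefix form; None = same as terminal
    inchain: str | None  # SMILES token usable inside the chain

    def left(self) -> str:
        return self.terminal_left if self.terminal_left is not None else self.terminal


GROUP_LIBRARY: dict[str, Group] = {
    "hydroxyl": Group("hydroxyl", "[OX2H]", "O", None, None),
    "amine": Group("amine", "[NX3;H2]", "N", None, None),
    "halogen": Group("halogen", "[F,Cl,Br,I]", "Cl", None, None),
    "carboxyl": Group("carboxyl", "[CX3](=[OX1])[OX2H1]", "C(=O)O", "OC(=O)", None),
    "aryl": Group("aryl", "c1ccccc1", "c1ccccc1", None, None),
    "carbonyl": Group("carbonyl", "[CX3]=[OX1]", None, None, "C(=O)"),
    "ether": Group("ether", "[OX2H0]", None, None, "O"),
}

TERMINAL_GROUPS = ("hydroxyl", "amine", "halogen", "carboxyl", "aryl")
INCHAIN_GROUPS = ("carbonyl", "ether")


def synthetic_key_set() -> KeySet:
    """SMARTS keys for the full group library, in library order."""
    return key_set_from_pairs(
        [(g.name, g.smarts) for g in GROUP_LIBRARY.values()], name="synthetic-7"
    )


def _assemble_smiles(t_left: str, inchain_order: Sequence[str],
                     t_right: str, spacers: Sequence[int]) -> str:
    """Linear scaffold: left terminal, alternating alkyl spacers and in-chain
    groups, right terminal.  ``spacers`` has len(inchain_order) + 1 entries,
    each >= 1 so neighbouring groups never fuse into a different group."""
    assert len(spacers) == len(inchain_order) + 1
    parts = [GROUP_LIBRARY[t_left].left()]
    for g, s in zip(inchain_order, spacers[:-1]):
        parts.append("C" * s)
        parts.append(GROUP_LIBRARY[g].inchain)
    parts.append("C" * spacers[-1])
    parts.append(GROUP_LIBRARY[t_right].terminal)
    return "".join(parts)


# --- datasets -------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Generated molecules plus binary labels and full provenance."""

    smiles: list[str]
    ids: list[str]
    labels: np.ndarray  # 1 = active, 0 = inactive
    generator: str
    seed: int
    rule: str
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.smiles)

    def write(self, outdir: str | Path, stem: str = "dataset") -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        data_path = outdir / f"{stem}.smi"
        lines = [f"{s}\t{i}\t{int(l)}"
                 for s, i, l in zip(self.smiles, self.ids, self.labels)]
        data_path.write_text("\n".join(lines) + "\n")
        meta_path = outdir / f"{stem}.meta.json"
        meta = {"generator": self.generator, "seed": self.seed, "rule": self.rule,
                "n_molecules": len(self.smiles),
                "n_active": int(self.labels.sum()),
                "n_inactive": int((1 - self.labels).sum()),
                **self.metadata}
        meta_path.write_text(json.dumps(meta, indent=2))
        return data_path, meta_path


def _verified_pair(rng: np.random.Generator, keys: KeySet, max_spacer: int,
                   budget: int = 200) -> tuple[str, str, dict]:
    """One connectivity-isomer pair: same group multiset, same plain FP,
    different SCFP.  Raises GenerationError when the budget is exhausted."""
    last_reason = ""
    for _ in range(budget):
        t_left, t_right = rng.choice(TERMINAL_GROUPS, size=2, replace=False)
        order_a = list(INCHAIN_GROUPS)
        order_b = list(INCHAIN_GROUPS[::-1])
        spacers_a = [int(rng.integers(1, max_spacer + 1)) for _ in range(3)]
        spacers_b = [int(rng.integers(1, max_spacer + 1)) for _ in range(3)]
        smi_a = _assemble_smiles(t_left, order_a, t_right, spacers_a)
        smi_b = _assemble_smiles(t_left, order_b, t_right, spacers_b)
        mol_a = parse_molecule(smi_a, "smiles", source_id="a")
        mol_b = parse_molecule(smi_b, "smiles", source_id="b")
        if compute_plain_fp(mol_a, keys) != compute_plain_fp(mol_b, keys):
            last_reason = f"plain FPs differ: {smi_a} vs {smi_b}"
            continue
        scfp_a = compute_scfp(mol_a, keys)
        scfp_b = compute_scfp(mol_b, keys)
        if scfp_a == scfp_b:
            last_reason = f"SCFPs identical: {smi_a} vs {smi_b}"
            continue
        case = {
            "terminals": [str(t_left), str(t_right)],
            "blocking": True,  # the reordered in-chain group severs a walk
            "atom_sharing": "carboxyl" in (t_left, t_right),
        }
        logger.debug("isomer pair %s / %s cases: %s", smi_a, smi_b, case)
        return smi_a, smi_b, case
    raise GenerationError(
        f"could not generate a conforming isomer pair in {budget} draws; "
        f"last rejection: {last_reason}"
    )


def generate_connectivity_isomers(n_pairs: int, seed: int = 0,
                                  max_spacer: int = 2
                                  ) -> tuple[SyntheticDataset, KeySet]:
    """Pairs of molecules built from the same multiset of functional groups
    in different arrangements: within each pair the plain key-based
    fingerprints are identical while the SCFP matrices differ (verified at
    generation time).

    Labels mark pair membership (first member 1, second 0) purely for
    bookkeeping; the dataset's point is the representation degeneracy.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    keys = synthetic_key_set()
    smiles, ids, labels, cases = [], [], [], []
    for p in range(n_pairs):
        smi_a, smi_b, case = _verified_pair(rng, keys, max_spacer)
        smiles += [smi_a, smi_b]
        ids += [f"pair{p:04d}_a", f"pair{p:04d}_b"]
        labels += [1, 0]
        cases.append(case)
    ds = SyntheticDataset(
        smiles=smiles, ids=ids, labels=np.array(labels, dtype=int),
        generator="connectivity_isomers", seed=seed,
        rule="pair members share plain FP, differ in SCFP",
        metadata={"n_pairs": n_pairs, "max_spacer": max_spacer, "cases": cases},
    )
    return ds, keys


# --- labeled benchmark sets -----------------------------------------------------

def _amine_carbonyl_connected(scfp: SCFPMatrix, keys: KeySet) -> bool:
    i = keys.index_of("amine")
    j = keys.index_of("carbonyl")
    return scfp[i, j] == 1


#: named labeling rules: predicate(scfp, keys) -> bool, plus a description
RULES: dict[str, tuple[Callable[[SCFPMatrix, KeySet], bool], str]] = {
    "amine_carbonyl": (_amine_carbonyl_connected,
                       "active iff the amine key is connected to the carbonyl key"),
    "tautology": (lambda scfp, keys: True, "every molecule is active (guard rule)"),
}


def _member_with_predicate(rng: np.random.Generator, keys: KeySet,
                           predicate: Callable[[SCFPMatrix, KeySet], bool],
                           want: bool, t_right: str, max_spacer: int,
                           budget: int = 400) -> str:
    """A molecule containing amine + carbonyl, ending in ``t_right``, whose
    predicate value is ``want``."""
    for _ in range(budget):
        # carbonyl adjacent to the amine end vs. ether interposed
        order = ["carbonyl", "ether"] if want else ["ether", "carbonyl"]
        spacers = [int(rng.integers(1, max_spacer + 1)) for _ in range(3)]
        smi = _assemble_smiles("amine", order, t_right, spacers)
        mol = parse_molecule(smi, "smiles")
        if predicate(compute_scfp(mol, keys), keys) == want:
            return smi
    raise GenerationError(
        f"rule unsatisfiable: no molecule with predicate={want} found in "
        f"{budget} draws (single-class dataset)"
    )


def generate_benchmark_set(n_active: int, n_inactive: int,
                           rule: str = "amine_carbonyl", seed: int = 0,
                           max_spacer: int = 2) -> SyntheticDataset:
    """Labeled benchmark set where the label is a connectivity predicate.

    Actives and inactives are drawn as matched arrangement pairs over the
    same group multiset (same terminal group, same functional groups), so
    the two classes realize the same plain-fingerprint multiset — the plain
    FP carries no label signal — while the SCFP separates them by
    construction.  Class counts are honored exactly; imbalance is configured
    by the two counts.
    """
    if n_active < 10 or n_inactive < 10:
        raise ValueError("need at least 10 molecules per class")
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; available: {sorted(RULES)}")
    predicate, rule_desc = RULES[rule]
    rng = np.random.default_rng(seed)
    keys = synthetic_key_set()
    smiles, ids, labels = [], [], []
    n_pairs = max(n_active, n_inactive)
    terminals = [t for t in TERMINAL_GROUPS if t != "amine"]
    for p in range(n_pairs):
        # same terminal for both members keeps the plain-FP multisets matched
        t_right = terminals[p % len(terminals)]
        if sum(labels) < n_active:
            smi = _member_with_predicate(rng, keys, predicate, True,
                                         t_right, max_spacer)
            smiles.append(smi)
            ids.append(f"act{p:04d}")
            labels.append(1)
        if len(labels) - sum(labels) < n_inactive:
            smi = _member_with_predicate(rng, keys, predicate, False,
                                         t_right, max_spacer)
            smiles.append(smi)
            ids.append(f"ina{p:04d}")
            labels.append(0)
    labels_arr = np.array(labels, dtype=int)
    if labels_arr.sum() == 0 or (1 - labels_arr).sum() == 0:  # pragma: no cover
        raise GenerationError("generated a single-class dataset")
    return SyntheticDataset(
        smiles=smiles, ids=ids, labels=labels_arr,
        generator="benchmark_set", seed=seed, rule=rule_desc,
        metadata={"rule_name": rule, "max_spacer": max_spacer},
    )


def fingerprint_dataset(ds: SyntheticDataset,
                        keys: KeySet | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compute (plain FP matrix, SCFP-linear matrix, labels) for a dataset."""
    keys = keys or synthetic_key_set()
    plain, linear = [], []
    for smi, mol_id in zip(ds.smiles, ds.ids):
        mol = parse_molecule(smi, "smiles", source_id=mol_id)
        plain.append(compute_plain_fp(mol, keys).bits)
        linear.append(compute_scfp(mol, keys).to_linear().bits)
    return np.array(plain), np.array(linear), ds.labels.copy()
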