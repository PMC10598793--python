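"""Deterministic synthetic compound libraries with known ground truth.

Molecules are assembled by attaching acyclic substituents to fully
cyclic ring scaffolds through single bonds at hydrogen-bearing ring
positions.  Because assembly only ever forms single bonds between a
ring atom and the head atom of an acyclic substituent, the ring/acyclic
decomposition of every generated molecule is known by construction:

* the molecule's single RF is the scaffold plus one copy of each
  substituent's head atom;
* its AFs are exactly the substituents used.

A *bridge* mode instead joins two scaffolds through one acyclic linker
(head atom to one scaffold, tail atom to the other), producing two ring
systems with known truth; a single-atom linker is then adjacent to both
systems and must appear in both RFs, exercising the duplication rule.

The generator emulates the occurrence structure of real compound
collections (shared frequent fragments, rarer combinations, planted
active/inactive enrichment) but not realistic medicinal-chemistry
property distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import canonical_key, parse_molecule
from .errors import ConfigurationError
from .fragment import fragment_molecule


@dataclass(frozen=True)
class LibrarySpec:
    n_molecules: int
    rf_alphabet: tuple[str, ...]
    af_alphabet: tuple[str, ...]
    max_substituents: int = 2
    bridge_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ConfigurationError("n_molecules must be at least 1")
        if not self.rf_alphabet or not self.af_alphabet:
            raise ConfigurationError("scaffold and substituent alphabets must be non-empty")
        if not (0.0 <= self.bridge_fraction <= 1.0):
            raise ConfigurationError("bridge_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class EnrichmentSpec:
    planted_fragment: str
    target_ratio: float
    n_active: int
    n_inactive: int
    seed: int = 0

    def __post_init__(self):
        if self.target_ratio <= 0:
            raise ConfigurationError("target_ratio must be positive")
        if self.n_active < 1 or self.n_inactive < 1:
            raise ConfigurationError("both subset sizes must be at least 1")


@dataclass
class LibraryResult:
    smiles: list[str]
    truth: pd.DataFrame  # molecule_index, molecule_smiles, kind, fragment_smiles
    n_resampled: int = 0

    def truth_fragments(self, index: int, kind: str) -> list[str]:
        t = self.truth
        rows = t[(t.molecule_index == index) & (t.kind == kind)]
        return list(rows.fragment_smiles)


def _validated_scaffold(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ConfigurationError(f"unparsable scaffold SMILES: {smiles!r}")
    if not all(a.IsInRing() for a in m.GetAtoms()):
        raise ConfigurationError(f"scaffold must be fully cyclic: {smiles!r}")
    return m


def _validated_substituent(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ConfigurationError(f"unparsable substituent SMILES: {smiles!r}")
    if any(a.IsInRing() for a in m.GetAtoms()):
        raise ConfigurationError(f"substituent must be acyclic: {smiles!r}")
    if m.GetAtomWithIdx(0).GetTotalNumHs() < 1:
        raise ConfigurationError(
            f"substituent head atom must bear a hydrogen: {smiles!r}"
        )
    return m


def _open_positions(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def _attach(base: Chem.Mol, attachments: Sequence[tuple[int, Chem.Mol, int]]) -> str:
    """Join each (base position, group mol, group atom) pair by a single
    bond and return the canonical SMILES; raises on valence failure."""
    combo = Chem.RWMol(base)
    for pos, group, group_atom in attachments:
        offset = combo.GetNumAtoms()
        combo.InsertMol(group)
        combo.AddBond(pos, offset + group_atom, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _head_atom_mol(group: Chem.Mol, atom_idx: int) -> Chem.Mol:
    """A one-atom molecule copying element and charge of a group atom."""
    atom = group.GetAtomWithIdx(atom_idx)
    rw = Chem.RWMol()
    a = Chem.Atom(atom.GetSymbol())
    a.SetFormalCharge(atom.GetFormalCharge())
    rw.AddAtom(a)
    m = rw.GetMol()
    Chem.SanitizeMol(m)
    return m


def generate_library(spec: LibrarySpec) -> LibraryResult:
    """Generate molecules with a per-molecule ground-truth fragment
    table.  Deterministic for a fixed seed; chemically invalid
    combinations are rejected and resampled (tallied)."""
    rng = np.random.default_rng(spec.seed)
    scaffolds = [_validated_scaffold(s) for s in spec.rf_alphabet]
    substituents = [_validated_substituent(s) for s in spec.af_alphabet]
    sub_keys = [canonical_key(s) for s in spec.af_alphabet]

    smiles_out: list[str] = []
    truth_rows: list[tuple[int, str, str, str]] = []
    n_resampled = 0

    for mol_idx in range(spec.n_molecules):
        for _attempt in range(100):
            try:
                if rng.random() < spec.bridge_fraction:
                    record = _build_bridge(rng, scaffolds, substituents, sub_keys)
                else:
                    record = _build_decorated(rng, scaffolds, substituents, sub_keys, spec)
                break
            except (Chem.rdchem.MolSanitizeException, Chem.rdchem.KekulizeException):
                n_resampled += 1
        else:  # pragma: no cover - alphabets would have to be pathological
            raise ConfigurationError(
                "could not assemble a valid molecule after 100 attempts"
            )
        mol_smiles, rfs, afs = record
        smiles_out.append(mol_smiles)
        for rf in rfs:
            truth_rows.append((mol_idx, mol_smiles, "RF", rf))
        for af in afs:
            truth_rows.append((mol_idx, mol_smiles, "AF", af))

    truth = pd.DataFrame(
        truth_rows,
        columns=["molecule_index", "molecule_smiles", "kind", "fragment_smiles"],
    )
    return LibraryResult(smiles=smiles_out, truth=truth, n_resampled=n_resampled)


def _build_decorated(rng, scaffolds, substituents, sub_keys, spec):
    s_idx = int(rng.integers(len(scaffolds)))
    scaffold = scaffolds[s_idx]
    positions = _open_positions(scaffold)
    k = int(rng.integers(0, spec.max_substituents + 1))
    k = min(k, len(positions))
    chosen_pos = [int(p) for p in rng.choice(positions, size=k, replace=False)]
    chosen_sub = [int(i) for i in rng.integers(len(substituents), size=k)]

    mol_smiles = _attach(
        scaffold, [(p, substituents[i], 0) for p, i in zip(chosen_pos, chosen_sub)]
    )
    rf_smiles = _attach(
        scaffold,
        [(p, _head_atom_mol(substituents[i], 0), 0) for p, i in zip(chosen_pos, chosen_sub)],
    )
    afs = [sub_keys[i] for i in chosen_sub]
    return mol_smiles, [rf_smiles], afs


def _build_bridge(rng, scaffolds, substituents, sub_keys):
    ia, ib = (int(i) for i in rng.integers(len(scaffolds), size=2))
    scaf_a, scaf_b = scaffolds[ia], scaffolds[ib]
    li = int(rng.integers(len(substituents)))
    linker = substituents[li]
    head = 0
    tail = linker.GetNumAtoms() - 1
    if head == tail and linker.GetAtomWithIdx(head).GetTotalNumHs() < 2:
        raise Chem.rdchem.MolSanitizeException("single-atom linker needs two hydrogens")
    pos_a = int(rng.choice(_open_positions(scaf_a)))
    pos_b = int(rng.choice(_open_positions(scaf_b)))

    combo = Chem.RWMol(scaf_a)
    off_l = combo.GetNumAtoms()
    combo.InsertMol(linker)
    off_b = combo.GetNumAtoms()
    combo.InsertMol(scaf_b)
    combo.AddBond(pos_a, off_l + head, Chem.BondType.SINGLE)
    combo.AddBond(off_b + pos_b, off_l + tail, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    mol_smiles = Chem.MolToSmiles(mol)

    rf_a = _attach(scaf_a, [(pos_a, _head_atom_mol(linker, head), 0)])
    rf_b = _attach(scaf_b, [(pos_b, _head_atom_mol(linker, tail), 0)])
    return mol_smiles, [rf_a, rf_b], [sub_keys[li]]


def generate_activity_split(
    library: Union[LibraryResult, Sequence[str]], spec: EnrichmentSpec
) -> tuple[list[str], list[str]]:
    """Split a library into active/inactive subsets so that the planted
    fragment's expected measured R_bioactive equals ``target_ratio``.

    Molecules containing the planted fragment are assigned active with
    probability p = rho*N_a / (rho*N_a + N_i), which makes the ratio of
    expected relative occurrences equal rho; the remaining slots are
    filled from the other molecules at random.  Deterministic per seed.
    """
    planted = canonical_key(spec.planted_fragment)
    if isinstance(library, LibraryResult):
        smiles = library.smiles
        truth = library.truth
        containing = set(
            truth.loc[truth.fragment_smiles == planted, "molecule_index"].astype(int)
        )
    else:
        smiles = list(library)
        containing = set()
        for i, smi in enumerate(smiles):
            rfs, afs = fragment_molecule(parse_molecule(smi))
            if any(f.canonical_smiles == planted for f in rfs + afs):
                containing.add(i)
    if not containing:
        raise ConfigurationError(
            f"planted fragment {spec.planted_fragment!r} does not occur in the library"
        )
    n_a, n_i = spec.n_active, spec.n_inactive
    if n_a + n_i > len(smiles):
        raise ConfigurationError(
            f"library has {len(smiles)} molecules but the split needs {n_a + n_i}"
        )
    rng = np.random.default_rng(spec.seed)
    p_active = spec.target_ratio * n_a / (spec.target_ratio * n_a + n_i)

    active_idx: list[int] = []
    inactive_idx: list[int] = []
    for i in sorted(containing):
        (active_idx if rng.random() < p_active else inactive_idx).append(i)
    if len(active_idx) > n_a or len(inactive_idx) > n_i:
        raise ConfigurationError(
            "target ratio unattainable: planted molecules overflow a subset"
        )
    rest = [i for i in range(len(smiles)) if i not in containing]
    rest = [int(i) for i in rng.permutation(rest)]
    need_a = n_a - len(active_idx)
    need_i = n_i - len(inactive_idx)
    if need_a + need_i > len(rest):
        raise ConfigurationError("not enough molecules outside the planted set")
    active_idx += rest[:need_a]
    inactive_idx += rest[need_a : need_a + need_i]
    return [smiles[i] for i in active_idx], [smiles[i] for i in inactive_idx]
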