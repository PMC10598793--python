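"""Molecule parsing, normalization and canonical identity.

Every other module works on :class:`Molecule` and :class:`Fragment`
objects produced here.  Normalization policy:

* the largest component of a multi-component record is kept (salts and
  counter-ions would otherwise pollute acyclic-fragment counts); ties
  are broken by lexicographic order of the component canonical SMILES;
* stereochemistry descriptors and isotope labels are stripped before
  the canonical key is computed, so stereoisomers collapse to one
  fragment identity;
* formal charges are preserved as written — no neutralization pass;
* aromaticity perception is RDKit's default model, so dearomatized
  (Kekulé) input normalizes to the same canonical key as aromatic
  input.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Union

from rdkit import Chem
from rdkit import RDLogger

from .errors import SmilesParseError

RDLogger.DisableLog("rdApp.error")

RF = "RF"
AF = "AF"


class AtomRecord(NamedTuple):
    symbol: str
    charge: int
    aromatic: bool
    in_ring: bool
    heavy_degree: int


class BondRecord(NamedTuple):
    i: int
    j: int
    order: float
    in_ring: bool


@dataclass(frozen=True)
class Molecule:
    """A normalized small molecule with ring-membership annotation.

    ``atoms``/``bonds`` describe the canonical form (atom indices refer
    to the canonical RDKit mol held in ``rdmol``), not the input order.
    """

    source_smiles: str
    canonical_smiles: str
    hac: int
    atoms: tuple[AtomRecord, ...]
    bonds: tuple[BondRecord, ...]
    rdmol: Chem.Mol = field(repr=False, compare=False)


@dataclass(frozen=True)
class Fragment:
    """A ring fragment (RF) or acyclic fragment (AF).

    ``parent_atoms`` holds the atom indices of the parent molecule's
    canonical mol that the fragment was cut from, when known.
    """

    kind: str  # RF or AF
    canonical_smiles: str
    hac: int
    parent_atoms: tuple[int, ...] | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.kind not in (RF, AF):
            raise ValueError(f"fragment kind must be RF or AF, got {self.kind!r}")
        if self.hac < 1:
            raise ValueError("fragment must have at least one heavy atom")


def _strip_identity_annotations(mol: Chem.Mol) -> Chem.Mol:
    """Remove stereo descriptors and isotope labels in place."""
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    return mol


def _largest_component(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return frags[0]
    # largest heavy atom count wins; ties broken by canonical SMILES order
    return min(frags, key=lambda m: (-m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))


def parse_molecule(smiles: str) -> Molecule:
    """Parse a SMILES string into a normalized :class:`Molecule`.

    Raises
    ------
    ValueError
        if ``smiles`` is empty or whitespace (blank input is a skip
        condition for line readers, not a parse failure).
    SmilesParseError
        if RDKit cannot parse or sanitize the input.
    """
    if not smiles or not smiles.strip():
        raise ValueError("empty SMILES: blank lines should be skipped upstream")
    source = smiles.strip()
    mol = Chem.MolFromSmiles(source)
    if mol is None:
        raise SmilesParseError(source)
    mol = _largest_component(mol)
    _strip_identity_annotations(mol)
    canonical = Chem.MolToSmiles(mol)
    # round-trip through the canonical string so stored atom indices refer
    # to the canonical atom order
    canon_mol = Chem.MolFromSmiles(canonical)
    if canon_mol is None:  # pragma: no cover - canonical output must reparse
        raise SmilesParseError(source, "canonical form failed to reparse")
    atoms = tuple(
        AtomRecord(
            a.GetSymbol(),
            a.GetFormalCharge(),
            a.GetIsAromatic(),
            a.IsInRing(),
            sum(1 for _ in a.GetNeighbors()),
        )
        for a in canon_mol.GetAtoms()
    )
    bonds = tuple(
        BondRecord(
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            b.GetBondTypeAsDouble(),
            b.IsInRing(),
        )
        for b in canon_mol.GetBonds()
    )
    return Molecule(
        source_smiles=source,
        canonical_smiles=canonical,
        hac=canon_mol.GetNumHeavyAtoms(),
        atoms=atoms,
        bonds=bonds,
        rdmol=canon_mol,
    )


def canonical_key(obj: Union[str, Molecule, Fragment]) -> str:
    """Deterministic canonical-SMILES dictionary key for a structure.

    Two inputs describing the same molecular graph yield identical keys
    regardless of atom order, Kekulé vs aromatic notation, stereo or
    isotope annotation.
    """
    if isinstance(obj, Molecule):
        return obj.canonical_smiles
    if isinstance(obj, Fragment):
        return obj.canonical_smiles
    return parse_molecule(obj).canonical_smiles


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms of the largest component."""
    return parse_molecule(smiles).hac


def as_molecule(obj: Union[str, Molecule]) -> Molecule:
    return obj if isinstance(obj, Molecule) else parse_molecule(obj)


def read_smiles_lines(lines: Iterable[str]) -> Iterator[tuple[str, str]]:
    """Yield ``(smiles, identifier)`` pairs from SMILES line records.

    Format: ``SMILES`` or ``SMILES<TAB>ID``.  Blank lines and lines
    starting with ``#`` are skipped.  Identifiers default to the
    1-based line number.
    """
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        ident = parts[1].strip() if len(parts) > 1 and parts[1].strip() else str(lineno)
        yield smiles, ident


def open_text(path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def read_smiles_file(path) -> Iterator[tuple[str, str]]:
    """Stream ``(smiles, id)`` records from a .smi/.smi.gz file."""
    with open_text(path) as fh:
        yield from read_smiles_lines(fh)
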