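"""Decomposition of molecules into ring fragments and acyclic fragments.

A *ring system* is a connected component of the subgraph induced by the
ring atoms, so fused and spiro rings (sharing at least one atom) merge
into a single system, and two rings joined by a direct ring-ring bond
(biphenyl) also form a single system: only bonds between two acyclic
atoms are ever broken when building ring fragments.

* RF (ring fragment): one per ring system — all ring atoms of the
  system plus every acyclic atom directly bonded to a ring atom of the
  system, original bond orders kept, cut valences hydrogen-saturated.
  An acyclic atom bonded to ring atoms of k distinct systems appears in
  k RFs.
* AF (acyclic fragment): the connected components of the subgraph
  induced by the acyclic atoms, cut valences hydrogen-saturated.  An
  exocyclic double-bonded oxygen therefore yields the water-like
  fragment ``O``.

Fragment identity is the hydrogen-saturated heavy-atom graph: the
``N`` cut from a secondary and from a tertiary amine are the same AF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

from rdkit import Chem

from .chem import AF, RF, Fragment, Molecule, as_molecule
from .errors import KindMismatchError, ScoringUnavailableError


def ring_systems(mol: Union[str, Molecule]) -> list[tuple[int, ...]]:
    """Atom-index sets of the ring systems of a molecule.

    Connected components of the subgraph induced by ring atoms; ordered
    by smallest member index for determinism.
    """
    m = as_molecule(mol).rdmol
    ring_atoms = {a.GetIdx() for a in m.GetAtoms() if a.IsInRing()}
    seen: set[int] = set()
    systems: list[tuple[int, ...]] = []
    for start in sorted(ring_atoms):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            for nb in m.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in ring_atoms and j not in comp:
                    stack.append(j)
        seen |= comp
        systems.append(tuple(sorted(comp)))
    return systems


def _submol_smiles(parent: Chem.Mol, keep: Iterable[int]) -> str:
    """Canonical SMILES of the sub-molecule on ``keep`` atoms.

    Atoms outside ``keep`` are deleted from an editable copy; RDKit
    re-derives implicit hydrogens on sanitization, which realizes the
    hydrogen saturation of cut valences.
    """
    keep = set(keep)
    keep_sorted = sorted(keep)
    # atoms that lose a neighbor must accept implicit hydrogens again,
    # even if they were written as bracket atoms (noImplicit) in the input
    cut = [
        a
        for a in keep_sorted
        if any(nb.GetIdx() not in keep for nb in parent.GetAtomWithIdx(a).GetNeighbors())
    ]
    rw = Chem.RWMol(parent)
    for idx in sorted(range(parent.GetNumAtoms()), reverse=True):
        if idx not in keep:
            rw.RemoveAtom(idx)
    for a in cut:
        rw.GetAtomWithIdx(keep_sorted.index(a)).SetNoImplicit(False)
    sub = rw.GetMol()
    Chem.SanitizeMol(sub)
    return Chem.MolToSmiles(sub)


def extract_ring_fragments(mol: Union[str, Molecule]) -> list[Fragment]:
    """One RF per ring system; empty list for acyclic molecules."""
    molecule = as_molecule(mol)
    m = molecule.rdmol
    fragments = []
    for system in ring_systems(molecule):
        keep = set(system)
        for i in system:
            for nb in m.GetAtomWithIdx(i).GetNeighbors():
                if not nb.IsInRing():
                    keep.add(nb.GetIdx())
        fragments.append(
            Fragment(
                kind=RF,
                canonical_smiles=_submol_smiles(m, keep),
                hac=len(keep),
                parent_atoms=tuple(sorted(keep)),
            )
        )
    return fragments


def extract_acyclic_fragments(mol: Union[str, Molecule]) -> list[Fragment]:
    """Connected acyclic components as AFs; a multiset, duplicates kept."""
    molecule = as_molecule(mol)
    m = molecule.rdmol
    acyclic = {a.GetIdx() for a in m.GetAtoms() if not a.IsInRing()}
    seen: set[int] = set()
    fragments = []
    for start in sorted(acyclic):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            for nb in m.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in acyclic and j not in comp:
                    stack.append(j)
        seen |= comp
        fragments.append(
            Fragment(
                kind=AF,
                canonical_smiles=_submol_smiles(m, comp),
                hac=len(comp),
                parent_atoms=tuple(sorted(comp)),
            )
        )
    return fragments


def fragment_molecule(
    mol: Union[str, Molecule]
) -> tuple[list[Fragment], list[Fragment]]:
    """RFs and AFs of a molecule, as ``(rf_list, af_list)``."""
    molecule = as_molecule(mol)
    return extract_ring_fragments(molecule), extract_acyclic_fragments(molecule)


# ---------------------------------------------------------------------------
# structural profiles


@dataclass(frozen=True)
class RFProfile:
    """Structural descriptors of a ring fragment.

    ``n_rings`` is the cyclomatic number (bonds − atoms + 1 of the
    connected fragment), ``largest_ring_size`` the maximum SSSR ring
    size, ``n_acyclic_atoms`` the retained ring-adjacent atoms, and
    ``n_heteroatoms`` the non-carbon heavy atoms.  SA/NP scores are
    filled only when requested (loading the scorer models is costly).
    """

    n_rings: int
    largest_ring_size: int
    n_acyclic_atoms: int
    n_heteroatoms: int
    sa_score: Optional[float] = None
    np_score: Optional[float] = None


@dataclass(frozen=True)
class AFProfile:
    """Structural descriptors of an acyclic fragment.

    A quaternary center is a carbon with exactly four heavy-atom
    neighbors; a terminal atom is a heavy atom with at most one heavy
    neighbor (an isolated atom counts as one terminal atom).
    """

    n_quaternary: int
    n_triple_bonds: int
    n_heteroatoms: int
    n_terminal_atoms: int
    sa_score: Optional[float] = None
    np_score: Optional[float] = None


def _fragment_mol(fragment: Fragment) -> Chem.Mol:
    m = Chem.MolFromSmiles(fragment.canonical_smiles)
    if m is None:  # pragma: no cover - fragments carry valid canonical SMILES
        raise ValueError(f"fragment SMILES failed to parse: {fragment.canonical_smiles}")
    return m


def rf_profile(fragment: Fragment, with_scores: bool = False) -> RFProfile:
    if fragment.kind != RF:
        raise KindMismatchError("rf_profile requires a ring fragment")
    m = _fragment_mol(fragment)
    n_rings = m.GetNumBonds() - m.GetNumAtoms() + 1
    ring_sizes = [len(r) for r in m.GetRingInfo().AtomRings()]
    sa = np_ = None
    if with_scores:
        sa, np_ = score_fragment(fragment)
    return RFProfile(
        n_rings=n_rings,
        largest_ring_size=max(ring_sizes) if ring_sizes else 0,
        n_acyclic_atoms=sum(1 for a in m.GetAtoms() if not a.IsInRing()),
        n_heteroatoms=sum(1 for a in m.GetAtoms() if a.GetSymbol() != "C"),
        sa_score=sa,
        np_score=np_,
    )


def af_profile(fragment: Fragment, with_scores: bool = False) -> AFProfile:
    if fragment.kind != AF:
        raise KindMismatchError("af_profile requires an acyclic fragment")
    m = _fragment_mol(fragment)
    n_quat = sum(
        1
        for a in m.GetAtoms()
        if a.GetSymbol() == "C" and sum(1 for _ in a.GetNeighbors()) == 4
    )
    n_triple = sum(1 for b in m.GetBonds() if b.GetBondType() == Chem.BondType.TRIPLE)
    sa = np_ = None
    if with_scores:
        sa, np_ = score_fragment(fragment)
    return AFProfile(
        n_quaternary=n_quat,
        n_triple_bonds=n_triple,
        n_heteroatoms=sum(1 for a in m.GetAtoms() if a.GetSymbol() != "C"),
        n_terminal_atoms=sum(
            1 for a in m.GetAtoms() if sum(1 for _ in a.GetNeighbors()) <= 1
        ),
        sa_score=sa,
        np_score=np_,
    )


# ---------------------------------------------------------------------------
# synthetic accessibility / natural-product likeness

_SCORERS: dict = {}


def _load_scorers():
    """Import the published SAscore/NPscore implementations from the
    RDKit Contrib tree and cache their models."""
    if _SCORERS:
        return _SCORERS
    import os
    import sys

    from rdkit import RDConfig

    sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
    np_dir = os.path.join(RDConfig.RDContribDir, "NP_Score")
    if not (
        os.path.exists(os.path.join(sa_dir, "sascorer.py"))
        and os.path.exists(os.path.join(np_dir, "npscorer.py"))
    ):
        raise ScoringUnavailableError(
            "SAscore/NPscore contribution data not found in the RDKit "
            f"Contrib directory ({RDConfig.RDContribDir})"
        )
    for d in (sa_dir, np_dir):
        if d not in sys.path:
            sys.path.append(d)
    import npscorer  # type: ignore
    import sascorer  # type: ignore

    _SCORERS["sa"] = sascorer
    _SCORERS["np"] = npscorer
    _SCORERS["np_model"] = npscorer.readNPModel()
    return _SCORERS


def score_fragment(fragment: Union[Fragment, str]) -> tuple[float, float]:
    """``(sa_score, np_score)`` of a fragment.

    SAscore lies in [1, 10], lower meaning easier synthesis; NPscore is
    higher for more natural-product-like structures (typically within
    [−5, 5]).  Both use the published fragment-contribution data; a
    missing data installation raises :class:`ScoringUnavailableError`.
    """
    scorers = _load_scorers()
    smiles = fragment.canonical_smiles if isinstance(fragment, Fragment) else fragment
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"cannot score unparsable SMILES: {smiles!r}")
    sa = float(scorers["sa"].calculateScore(m))
    np_ = float(scorers["np"].scoreMol(m, scorers["np_model"]))
    return sa, np_
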