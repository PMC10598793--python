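"""Independent brute-force reference implementations used as oracles.

The fragmentation oracle classifies atoms by ring membership with a
networkx cycle basis (DFS-based), groups ring systems and acyclic
components with networkx connected components, and rebuilds each
fragment as a fresh molecular graph atom by atom.  It shares no graph
logic with fragspace.fragment, which perceives rings through RDKit and
cuts fragments by deleting atoms from an editable copy of the parent.
"""

from __future__ import annotations

import networkx as nx
from rdkit import Chem

from fragspace.chem import Molecule


def _bond_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    g.add_edges_from(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    )
    return g


def ring_atoms_brute_force(mol: Chem.Mol) -> set[int]:
    """Atoms lying on at least one cycle: union of a DFS cycle basis
    (every edge on a cycle appears in some basis cycle, hence so does
    every atom on a cycle)."""
    g = _bond_graph(mol)
    atoms: set[int] = set()
    for cycle in nx.cycle_basis(g):
        atoms.update(cycle)
    return atoms


def _rebuild_smiles(mol: Chem.Mol, atom_ids: set[int]) -> str:
    """Canonical SMILES of the fragment on ``atom_ids``, rebuilt as a
    fresh graph; open valences fill with implicit hydrogens on
    sanitization."""
    order = sorted(atom_ids)
    remap = {a: i for i, a in enumerate(order)}
    rw = Chem.RWMol()
    for a in order:
        src = mol.GetAtomWithIdx(a)
        atom = Chem.Atom(src.GetSymbol())
        atom.SetFormalCharge(src.GetFormalCharge())
        atom.SetIsAromatic(src.GetIsAromatic())
        atom.SetNumExplicitHs(src.GetNumExplicitHs())
        rw.AddAtom(atom)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in atom_ids and j in atom_ids:
            rw.AddBond(remap[i], remap[j], b.GetBondType())
    frag = rw.GetMol()
    Chem.SanitizeMol(frag)
    return Chem.MolToSmiles(frag)


def brute_force_fragments(molecule: Molecule) -> tuple[list[str], list[str]]:
    """(RF SMILES list, AF SMILES list) computed by direct graph
    analysis on the normalized molecule."""
    mol = molecule.rdmol
    g = _bond_graph(mol)
    ring = ring_atoms_brute_force(mol)
    acyclic = set(g.nodes) - ring

    rf_smiles = []
    for system in nx.connected_components(g.subgraph(ring)):
        keep = set(system)
        for atom in system:
            keep.update(nb for nb in g.neighbors(atom) if nb in acyclic)
        rf_smiles.append(_rebuild_smiles(mol, keep))

    af_smiles = [
        _rebuild_smiles(mol, set(comp))
        for comp in nx.connected_components(g.subgraph(acyclic))
    ]
    return sorted(rf_smiles), sorted(af_smiles)
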