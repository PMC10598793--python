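"""Curated + generated molecule fixture for oracle-equivalence checks.

The set combines hand-picked topologies (fused, spiro, bridged rings,
biphenyl-type direct ring-ring bonds, exocyclic double bonds,
ring-bridging acyclic atoms, charged atoms, single-atom substituents,
salts) with molecules from the synthetic library generator, restricted
to at most 12 heavy atoms and deduplicated by canonical key.
"""

from __future__ import annotations

from fragspace import LibrarySpec, generate_library, parse_molecule

CURATED_SMILES = [
    # acyclic only
    "C", "CC", "CCC", "CCO", "NCCO", "C#N", "CC(C)(C)C", "C=CC=C",
    "CC(=O)O", "COC", "CS", "CCl", "FC(F)F", "N#CC#N", "OCC(O)CO",
    "CNC", "C=O", "CSSC", "CC(C)CC(C)C",
    # monocycles
    "c1ccccc1", "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCCCCC1",
    "C1CCCCCCC1", "c1ccncc1", "c1cc[nH]c1", "c1ccsc1", "c1ccoc1",
    "C1CCNCC1", "C1CCOC1", "C1CCOCC1", "C1CCSCC1",
    # substituted rings (single-atom and chain substituents)
    "Cc1ccccc1", "CCc1ccccc1", "COc1ccccc1", "Oc1ccccc1", "Nc1ccccc1",
    "Clc1ccccc1", "Fc1ccccc1", "Cc1ccc(C)cc1", "Cc1ccccc1C",
    "N#Cc1ccccc1", "O=Cc1ccccc1", "CC(=O)C1CC1", "OC1CCCCC1",
    "CC1(C)CCCCC1", "CC1CCCCC1", "CN1CCOCC1", "ClC1CCCCC1",
    # exocyclic double bonds
    "O=C1CCCCC1", "C=C1CCCCC1", "S=C1CCCC1", "O=S1(=O)CCCC1",
    "O=C1CCC(=O)N1", "C=C1CC1",
    # fused / bridged / spiro ring systems
    "c1ccc2ccccc2c1", "C1CCC2CCCCC2C1", "c1ccc2[nH]ccc2c1",
    "c1ccc2ncccc2c1", "C1CC2CCC1C2", "C1CC2CCC1CC2", "C1CC12CC2",
    "C1CCC2(CC1)CCCC2", "c1ccc2c(c1)CCCC2", "C1CC2(C1)CCC2",
    # two ring systems: direct ring-ring bond and acyclic bridges
    "c1ccc(-c2ccccc2)cc1", "C1CC1C1CC1", "C1CC1CC1CC1",
    "c1ccccc1Cc1ccco1", "C1CC1CCC1CC1", "C1CC1OC1CC1", "C1CC1C(=O)C1CC1",
    "C1CC1N(C1CC1)C1CC1",
    # charged species
    "C[N+](C)(C)C", "CC(=O)[O-]", "c1cc[nH+]cc1", "[NH3+]CC(=O)[O-]",
    "C[NH2+]C1CC1",
    # multi-component records (largest component kept)
    "C1CC1.Cl", "c1ccccc1.[Na+]",
]


def build_oracle_fixture(seed: int = 20240917) -> list:
    """>=500 normalized molecules of <=12 heavy atoms."""
    spec = LibrarySpec(
        n_molecules=1500,
        rf_alphabet=(
            "C1CC1", "C1CCC1", "C1CCCC1", "c1ccccc1", "c1ccncc1",
            "C1CCOC1", "C1CCNCC1", "c1ccsc1", "C1CC2CCC1C2", "C1CC2(C1)CC2",
        ),
        af_alphabet=("C", "O", "N", "F", "Cl", "S", "CO", "CC", "OC", "CN", "C#N", "C=O"),
        max_substituents=2,
        bridge_fraction=0.25,
        seed=seed,
    )
    library = generate_library(spec)
    molecules = []
    seen = set()
    for smi in CURATED_SMILES + library.smiles:
        mol = parse_molecule(smi)
        if mol.hac > 12 or mol.canonical_smiles in seen:
            continue
        seen.add(mol.canonical_smiles)
        molecules.append(mol)
    return molecules
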