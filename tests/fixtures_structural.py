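"""Hand-labeled fixture for the structural selection filters.

Each entry is ``(smiles, kind, keep)`` where ``keep`` records whether
the fragment passes the default structural bounds (exclusivity not
considered), derived by inspection of the structure:

* RF bounds: at most 2 rings (cyclomatic), largest ring size at most 7,
  at most 3 heteroatoms, at most 3 acyclic atoms;
* AF bounds: no quaternary center, at most 1 triple bond, at most 4
  heteroatoms, at most 4 terminal atoms.
"""

STRUCTURAL_FIXTURE = [
    # --- ring fragments -------------------------------------------------
    ("c1ccccc1", "RF", True),            # 1 ring, size 6
    ("C1CC1", "RF", True),               # cyclopropane
    ("C1CCCCCCC1", "RF", False),         # 8-membered ring > 7
    ("c1ccc2ccccc2c1", "RF", True),      # naphthalene: 2 rings, size 6
    ("c1ccc2cc3ccccc3cc2c1", "RF", False),  # anthracene: 3 rings
    ("Cc1ccccc1", "RF", True),           # 1 acyclic atom
    ("Cc1cc(C)c(C)cc1C", "RF", False),   # 4 acyclic atoms
    ("Oc1ccccc1", "RF", True),           # 1 het, 1 acyclic
    ("OC1CCC(O)CC1", "RF", True),        # 2 het, 2 acyclic
    ("NC1CCC(O)C(S)C1", "RF", True),     # 3 het, 3 acyclic (boundary)
    ("NC1CCC(O)C(S)C1N", "RF", False),   # 4 het, 4 acyclic
    ("C1CCC2(CC1)CCCC2", "RF", True),    # spiro[4.5]: 2 rings, size 6
    ("C1CC2CCC1C2", "RF", True),         # norbornane: 2 SSSR rings of 5
    ("C1CCC(CC1)C1CCCCC1", "RF", True),  # bicyclohexyl: 2 rings, size 6
    ("C1CCCCCCCC1", "RF", False),        # 9-membered ring
    ("c1ccncc1", "RF", True),            # pyridine: 1 het
    ("O=C1CCCCC1", "RF", True),          # cyclohexanone: 1 het, 1 acyclic
    ("O=S1(=O)CCCC1", "RF", True),       # sulfolane: 3 het, 2 acyclic
    ("FC1(F)C(F)C1F", "RF", False),      # 4 heteroatoms
    ("C1C2CC3CC1CC(C2)C3", "RF", False), # adamantane: 3 rings
    ("CC1CCCCC1C", "RF", True),          # 2 acyclic atoms
    ("ClC1CCC(Cl)CC1", "RF", True),      # 2 het, 2 acyclic
    ("C1CCC2CCCCC2C1", "RF", True),      # decalin: 2 rings, size 6
    ("c1ccc2c(c1)CCCC2", "RF", True),    # tetralin: 2 rings, size 6
    ("CN1CCOCC1", "RF", True),           # N-methylmorpholine: 2 het, 1 acyclic
    # --- acyclic fragments ----------------------------------------------
    ("C", "AF", True),                   # methane: 1 terminal atom
    ("CC(C)(C)C", "AF", False),          # neopentane: quaternary center
    ("C#N", "AF", True),                 # 1 triple bond (boundary)
    ("C#CC#C", "AF", False),             # 2 triple bonds
    ("OCCO", "AF", True),                # 2 het, 2 terminal
    ("NCCO", "AF", True),
    ("CCCCC", "AF", True),               # 2 terminal atoms
    ("CC(C)C", "AF", True),              # 3 terminal atoms
    ("CCC(C)(C)C", "AF", False),         # quaternary center
    ("OCC(O)CO", "AF", True),            # 3 het, 3 terminal
    ("FC(F)(F)F", "AF", False),          # quaternary carbon (4 heavy neighbors)
    ("FC(F)F", "AF", True),              # 3 het, 3 terminal
    ("NC(=O)CO", "AF", True),            # 3 het, 3 terminal
    ("CC(C)OCC", "AF", True),            # 1 het, 3 terminal
    ("N#CCC#N", "AF", False),            # 2 triple bonds
    ("CSSC", "AF", True),                # 2 het, 2 terminal
    ("NCCCCN", "AF", True),
    ("OCC(CO)(CO)CO", "AF", False),      # quaternary center
    ("NC(N)N", "AF", True),              # 3 het, 3 terminal
    ("NCC(O)C(S)CO", "AF", True),        # 4 het, 4 terminal (boundary)
    ("NCC(O)C(S)C(F)CO", "AF", False),   # 5 heteroatoms
    ("C=CC=C", "AF", True),              # butadiene
    ("CC(C)(C)C#N", "AF", False),        # quaternary center
    ("CC(C)CC(C)C", "AF", True),         # 4 terminal atoms (boundary)
    ("CC(C)C(C)C", "AF", True),          # 4 terminal atoms (boundary)
]

assert len(STRUCTURAL_FIXTURE) == 50
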