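"""Shared fixtures: curated molecules and extracted fragment pools."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fixture_molecules import build_oracle_fixture  # noqa: E402


@pytest.fixture(scope="session")
def oracle_fixture():
    molecules = build_oracle_fixture()
    assert len(molecules) >= 500
    return molecules


@pytest.fixture(scope="session")
def fragment_pool(oracle_fixture):
    """Unique RFs and AFs extracted from the oracle fixture set."""
    from fragspace import fragment_molecule

    rfs, afs = {}, {}
    for mol in oracle_fixture:
        rf_list, af_list = fragment_molecule(mol)
        for f in rf_list:
            rfs.setdefault(f.canonical_smiles, f)
        for f in af_list:
            afs.setdefault(f.canonical_smiles, f)
    return sorted(rfs.values(), key=lambda f: f.canonical_smiles), sorted(
        afs.values(), key=lambda f: f.canonical_smiles
    )
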