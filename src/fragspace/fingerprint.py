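"""MinHashed atom-pair fingerprints and Jaccard-distance screening.

The shingle set of a molecule follows the MinHashed atom-pair design:
for every unordered heavy-atom pair and every environment radius
(default radii 1 and 2, i.e. circular environments up to a diameter of
four bonds) one token

    ``envA|d|envB``

is emitted, where ``envA``/``envB`` are canonical SMILES of the two
atoms' circular environments (lexicographically ordered within the
token) and ``d`` is the topological bond-count distance between the
two centers.  Atoms whose neighborhood does not extend to the full
radius contribute their largest available environment, and a lone atom
emits self-pair tokens at distance 0, so every fragment with at least
one heavy atom — including the very common single-atom AFs ``O``,
``N``, ``F``, ``Cl`` — is fingerprintable.

Signatures are classic MinHash: each token is hashed to 64 bits with
BLAKE2b, then 256 seeded multiply-shift permutations
(``a*x + b mod 2^64`` with odd ``a``) take position-wise minima.  The
fraction of matching signature positions estimates Jaccard similarity;
the hash family and seed are recorded so signatures are comparable
only when computed under the same configuration.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
from rdkit import Chem

from .chem import Fragment, Molecule
from .errors import ConfigurationError, FragspaceError


@dataclass(frozen=True)
class SimilarityConfig:
    d_max: float = 0.6
    dimensions: int = 256
    radii: tuple[int, ...] = (1, 2)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.d_max <= 1):
            raise ConfigurationError("d_max must lie in (0, 1]")
        if self.dimensions < 1:
            raise ConfigurationError("dimensions must be positive")


@dataclass(frozen=True)
class MinHashSignature:
    values: np.ndarray = field(compare=False)  # uint64, length = dimensions
    seed: int = 0
    dimensions: int = 256

    def __eq__(self, other):
        return (
            isinstance(other, MinHashSignature)
            and self.seed == other.seed
            and self.dimensions == other.dimensions
            and bool(np.array_equal(self.values, other.values))
        )


def _as_rdmol(obj: Union[str, Molecule, Fragment]) -> Chem.Mol:
    if isinstance(obj, Molecule):
        return obj.rdmol
    smiles = obj.canonical_smiles if isinstance(obj, Fragment) else obj
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise FragspaceError(f"cannot fingerprint unparsable SMILES: {smiles!r}")
    return m


def _environment_smiles(mol: Chem.Mol, atom_idx: int, radius: int) -> str:
    """Canonical SMILES of the circular environment of an atom, falling
    back to the largest radius the molecule supports."""
    for r in range(radius, 0, -1):
        bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, r, atom_idx)
        if bonds:
            amap: dict[int, int] = {}
            sub = Chem.PathToSubmol(mol, bonds, atomMap=amap)
            return Chem.MolToSmiles(sub, rootedAtAtom=amap[atom_idx], canonical=True)
    return Chem.MolFragmentToSmiles(mol, atomsToUse=[atom_idx])


def atom_pair_shingles(
    obj: Union[str, Molecule, Fragment], radii: Sequence[int] = (1, 2)
) -> frozenset[str]:
    """Atom-pair shingle set of a molecule or fragment."""
    mol = _as_rdmol(obj)
    n = mol.GetNumAtoms()
    if n == 0:
        raise FragspaceError("cannot fingerprint an empty molecule")
    envs = {
        (i, r): _environment_smiles(mol, i, r) for i in range(n) for r in set(radii)
    }
    if n == 1:
        return frozenset(f"{envs[(0, r)]}|0|{envs[(0, r)]}" for r in set(radii))
    dist = Chem.GetDistanceMatrix(mol)
    tokens = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = int(dist[i, j])
            for r in set(radii):
                a, b = sorted((envs[(i, r)], envs[(j, r)]))
                tokens.add(f"{a}|{d}|{b}")
    return frozenset(tokens)


def _token_hash64(token: str) -> int:
    return int.from_bytes(
        hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest(), "little"
    )


def _permutation_params(config: SimilarityConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    a = rng.integers(0, 2**63, size=config.dimensions, dtype=np.uint64) * 2 + 1
    b = rng.integers(0, 2**64, size=config.dimensions, dtype=np.uint64)
    return a, b


def minhash(
    shingles: Iterable[str], config: SimilarityConfig = SimilarityConfig()
) -> MinHashSignature:
    """MinHash signature of a shingle set under a fixed configuration."""
    tokens = sorted(set(shingles))
    if not tokens:
        raise ConfigurationError("cannot MinHash an empty shingle set")
    a, b = _permutation_params(config)
    x = np.array([_token_hash64(t) for t in tokens], dtype=np.uint64)
    # multiply-shift permutations with natural mod-2^64 wraparound
    hashed = x[:, None] * a[None, :] + b[None, :]
    return MinHashSignature(
        values=hashed.min(axis=0), seed=config.seed, dimensions=config.dimensions
    )


def jaccard_distance(a: MinHashSignature, b: MinHashSignature) -> float:
    """Estimated Jaccard distance: 1 − (matching positions)/dimensions."""
    if a.seed != b.seed or a.dimensions != b.dimensions:
        raise ConfigurationError(
            "signatures are comparable only under identical seed and dimensions"
        )
    return 1.0 - float(np.count_nonzero(a.values == b.values)) / a.dimensions


def exact_jaccard_distance(a: Iterable[str], b: Iterable[str]) -> float:
    """Exact Jaccard distance between two shingle sets."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ConfigurationError("exact Jaccard requires non-empty shingle sets")
    return 1.0 - len(sa & sb) / len(sa | sb)


@dataclass(frozen=True)
class ScreenHit:
    candidate: str
    min_distance: float
    nearest_reference: str


def screen_report(
    candidates: Sequence[Union[str, Fragment]],
    references: Sequence[Union[str, Fragment]],
    config: SimilarityConfig = SimilarityConfig(),
) -> list[ScreenHit]:
    """Linear-scan nearest-reference distances for every candidate."""
    if not references:
        raise ConfigurationError("reference set must be non-empty")

    def key_of(obj):
        return obj.canonical_smiles if isinstance(obj, Fragment) else obj

    ref_sigs = [
        (key_of(r), minhash(atom_pair_shingles(r, config.radii), config))
        for r in references
    ]
    hits = []
    for cand in candidates:
        sig = minhash(atom_pair_shingles(cand, config.radii), config)
        best_d, best_ref = min(
            ((jaccard_distance(sig, rs), rk) for rk, rs in ref_sigs),
            key=lambda t: t[0],
        )
        hits.append(ScreenHit(key_of(cand), best_d, best_ref))
    return hits


def screen_within(
    candidates: Sequence[Union[str, Fragment]],
    references: Sequence[Union[str, Fragment]],
    config: SimilarityConfig = SimilarityConfig(),
) -> list[Union[str, Fragment]]:
    """Candidates within ``config.d_max`` of at least one reference,
    in input order.  Deterministic for a fixed seed."""
    hits = screen_report(candidates, references, config)
    return [c for c, h in zip(candidates, hits) if h.min_distance <= config.d_max]
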