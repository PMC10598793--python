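"""Fragment occurrence indexing and collection-level statistics.

A :class:`FragmentIndex` maps each fragment canonical key to the number
of *distinct* molecules of a collection containing it (within-molecule
duplicates count once).  Indexes over disjoint molecule sets add
key-wise, so large collections can be processed in shards and merged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .chem import AF, RF, Molecule, as_molecule, open_text
from .errors import ConfigurationError, KindMismatchError, SmilesParseError
from .fragment import extract_acyclic_fragments, extract_ring_fragments


@dataclass
class FragmentIndex:
    collection_name: str
    kind: str  # RF or AF
    counts: dict[str, int] = field(default_factory=dict)
    n_molecules: int = 0
    n_skipped: int = 0

    def __post_init__(self):
        if self.kind not in (RF, AF):
            raise ValueError(f"index kind must be RF or AF, got {self.kind!r}")

    def merge(self, other: "FragmentIndex") -> "FragmentIndex":
        """Key-wise sum of two indexes over disjoint molecule sets."""
        if other.kind != self.kind:
            raise KindMismatchError("cannot merge indexes of different kinds")
        merged = Counter(self.counts)
        merged.update(other.counts)
        return FragmentIndex(
            collection_name=self.collection_name or other.collection_name,
            kind=self.kind,
            counts=dict(merged),
            n_molecules=self.n_molecules + other.n_molecules,
            n_skipped=self.n_skipped + other.n_skipped,
        )


def _fragments_of_kind(molecule: Molecule, kind: str):
    if kind == RF:
        return extract_ring_fragments(molecule)
    if kind == AF:
        return extract_acyclic_fragments(molecule)
    raise ValueError(f"unknown fragment kind {kind!r}")


def build_index(
    molecules: Iterable[Union[str, Molecule]],
    kind: str,
    collection_name: str = "",
    dedupe_molecules: bool = False,
) -> FragmentIndex:
    """Index fragment occurrence over a molecule stream.

    Unparsable records are skipped and tallied in ``n_skipped``.  The
    stream is assumed pre-deduplicated at the molecule level unless
    ``dedupe_molecules`` applies canonical-key deduplication.
    """
    index = FragmentIndex(collection_name=collection_name, kind=kind)
    counts: Counter[str] = Counter()
    seen_molecules: set[str] = set()
    for item in molecules:
        try:
            molecule = as_molecule(item)
        except (SmilesParseError, ValueError):
            index.n_skipped += 1
            continue
        if dedupe_molecules:
            if molecule.canonical_smiles in seen_molecules:
                continue
            seen_molecules.add(molecule.canonical_smiles)
        index.n_molecules += 1
        keys = {f.canonical_smiles for f in _fragments_of_kind(molecule, kind)}
        counts.update(keys)
    index.counts = dict(counts)
    return index


def singletons(index: FragmentIndex) -> set[str]:
    """Fragments occurring in exactly one molecule of the collection."""
    return {k for k, c in index.counts.items() if c == 1}


def exclusives(target: FragmentIndex, others: Iterable[FragmentIndex]) -> set[str]:
    """Fragments of ``target`` absent from every comparison index."""
    others = list(others)
    for other in others:
        if other.kind != target.kind:
            raise KindMismatchError("exclusives requires indexes of one kind")
    keys = set(target.counts)
    for other in others:
        keys.difference_update(other.counts)
    return keys


def coverage(
    molecules: Iterable[Union[str, Molecule]],
    kind_filter: str = "both",
    max_hac: int = 13,
) -> float:
    """Fraction of molecules all of whose fragments of the selected
    kind(s) have at most ``max_hac`` heavy atoms.

    A molecule with no fragments of the selected kind is covered
    (vacuous truth).  Unparsable records are excluded from the
    denominator; an empty stream yields 0.0.
    """
    if kind_filter not in (RF, AF, "both"):
        raise ValueError(f"kind_filter must be RF, AF or 'both', got {kind_filter!r}")
    n_total = 0
    n_covered = 0
    for item in molecules:
        try:
            molecule = as_molecule(item)
        except (SmilesParseError, ValueError):
            continue
        n_total += 1
        fragments = []
        if kind_filter in (RF, "both"):
            fragments += extract_ring_fragments(molecule)
        if kind_filter in (AF, "both"):
            fragments += extract_acyclic_fragments(molecule)
        if all(f.hac <= max_hac for f in fragments):
            n_covered += 1
    return n_covered / n_total if n_total else 0.0


def frequency_distribution(index: FragmentIndex) -> list[tuple[int, int]]:
    """Histogram of occurrence values: ``[(occurrence, n_fragments)]``,
    sorted by occurrence.  Entry counts sum to the number of keys."""
    hist = Counter(index.counts.values())
    return sorted(hist.items())


def top_n(index: FragmentIndex, n: int) -> list[str]:
    """The ``n`` most frequent fragments; ties broken by canonical key
    lexicographic order so the ranking is deterministic."""
    if n < 0:
        raise ValueError("n must be non-negative")
    ranked = sorted(index.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in ranked[:n]]


@dataclass
class SizeHistograms:
    """Per-HAC counts of compounds and of distinct fragments.

    ``erf``/``eaf`` (exclusive fragments, absent from the comparison
    indexes) are filled only when comparison indexes are supplied.
    """

    compounds: dict[int, int] = field(default_factory=dict)
    rf: dict[int, int] = field(default_factory=dict)
    erf: dict[int, int] = field(default_factory=dict)
    af: dict[int, int] = field(default_factory=dict)
    eaf: dict[int, int] = field(default_factory=dict)


def size_histograms(
    molecules: Iterable[Union[str, Molecule]],
    other_rf_indexes: Iterable[FragmentIndex] = (),
    other_af_indexes: Iterable[FragmentIndex] = (),
) -> SizeHistograms:
    """Heavy-atom-count histograms of compounds, distinct RFs/AFs, and
    (when comparison indexes are given) exclusive RFs/AFs."""
    other_rf_keys: set[str] = set()
    for idx in other_rf_indexes:
        other_rf_keys |= set(idx.counts)
    other_af_keys: set[str] = set()
    for idx in other_af_indexes:
        other_af_keys |= set(idx.counts)

    hist = SizeHistograms()
    rf_seen: dict[str, int] = {}
    af_seen: dict[str, int] = {}
    for item in molecules:
        try:
            molecule = as_molecule(item)
        except (SmilesParseError, ValueError):
            continue
        hist.compounds[molecule.hac] = hist.compounds.get(molecule.hac, 0) + 1
        for f in extract_ring_fragments(molecule):
            rf_seen.setdefault(f.canonical_smiles, f.hac)
        for f in extract_acyclic_fragments(molecule):
            af_seen.setdefault(f.canonical_smiles, f.hac)
    for key, hac in rf_seen.items():
        hist.rf[hac] = hist.rf.get(hac, 0) + 1
        if key not in other_rf_keys:
            hist.erf[hac] = hist.erf.get(hac, 0) + 1
    for key, hac in af_seen.items():
        hist.af[hac] = hist.af.get(hac, 0) + 1
        if key not in other_af_keys:
            hist.eaf[hac] = hist.eaf.get(hac, 0) + 1
    if not other_rf_keys:
        hist.erf = {}
    if not other_af_keys:
        hist.eaf = {}
    return hist


# ---------------------------------------------------------------------------
# serialization: two-column TSV with a metadata header line


def write_index(index: FragmentIndex, path) -> None:
    with open_text(path, "wt") as fh:
        fh.write(
            f"#collection={index.collection_name}\tkind={index.kind}"
            f"\tn_molecules={index.n_molecules}\n"
        )
        fh.write("fragment_smiles\tcount\n")
        for key in sorted(index.counts, key=lambda k: (-index.counts[k], k)):
            fh.write(f"{key}\t{index.counts[key]}\n")


def read_index(path) -> FragmentIndex:
    with open_text(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ConfigurationError(f"{path}: missing index metadata header")
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("#").split("\t") if "=" in kv
        )
        columns = fh.readline()
        if not columns.startswith("fragment_smiles"):
            raise ConfigurationError(f"{path}: missing column header line")
        counts: dict[str, int] = {}
        for line in fh:
            if not line.strip():
                continue
            key, count = line.rstrip("\n").split("\t")
            counts[key] = int(count)
    return FragmentIndex(
        collection_name=meta.get("collection", ""),
        kind=meta.get("kind", RF),
        counts=counts,
        n_molecules=int(meta.get("n_molecules", 0)),
    )
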