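"""Fragment selection: structural-constraint filtering and
bioactive-like similarity selection.

Two complementary routes mirror the two selection stages used to pick
novel fragments from an enumerated chemical space:

* :func:`filter_structural` keeps fragments within explicit structural
  bounds (ring count, ring size, heteroatoms, ... — the RFset1/AFset1
  style criteria), optionally restricted to fragments exclusive to the
  source collection;
* :func:`select_bioactive_like` keeps candidates within Jaccard
  distance ``d_max`` of at least one bioactivity-enriched reference
  fragment and then removes every candidate within ``d_max`` of any
  inactive-enriched reference (removal takes precedence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set, Union

from .chem import AF, RF, Fragment
from .errors import ConfigurationError, KindMismatchError
from .fingerprint import SimilarityConfig, screen_within
from .fragment import af_profile, rf_profile
from .store import FragmentIndex


@dataclass(frozen=True)
class RFset1Criteria:
    """Structural bounds for ring fragments (defaults: up to two rings,
    ring size up to seven, up to three heteroatoms and three acyclic
    atoms, fragment exclusive to the source collection)."""

    max_rings: int = 2
    max_ring_size: int = 7
    max_heteroatoms: int = 3
    max_acyclic_atoms: int = 3
    require_exclusive: bool = True

    kind = RF

    def admits(self, fragment: Fragment) -> bool:
        p = rf_profile(fragment)
        return (
            p.n_rings <= self.max_rings
            and p.largest_ring_size <= self.max_ring_size
            and p.n_heteroatoms <= self.max_heteroatoms
            and p.n_acyclic_atoms <= self.max_acyclic_atoms
        )


@dataclass(frozen=True)
class AFset1Criteria:
    """Structural bounds for acyclic fragments (defaults: no quaternary
    center, up to one triple bond, up to four heteroatoms and four
    terminal atoms, fragment exclusive to the source collection)."""

    max_quaternary: int = 0
    max_triple_bonds: int = 1
    max_heteroatoms: int = 4
    max_terminal_atoms: int = 4
    require_exclusive: bool = True

    kind = AF

    def admits(self, fragment: Fragment) -> bool:
        p = af_profile(fragment)
        return (
            p.n_quaternary <= self.max_quaternary
            and p.n_triple_bonds <= self.max_triple_bonds
            and p.n_heteroatoms <= self.max_heteroatoms
            and p.n_terminal_atoms <= self.max_terminal_atoms
        )


Criteria = Union[RFset1Criteria, AFset1Criteria]


def filter_structural(
    fragments: Iterable[Fragment],
    criteria: Criteria,
    exclusive_set: Optional[Set[str]] = None,
) -> list[Fragment]:
    """Fragments passing every structural bound of ``criteria`` and,
    when ``require_exclusive`` is set, whose canonical key belongs to
    ``exclusive_set``."""
    if criteria.require_exclusive and exclusive_set is None:
        raise ConfigurationError(
            "criteria require exclusivity but no exclusive_set was provided"
        )
    selected = []
    for fragment in fragments:
        if fragment.kind != criteria.kind:
            raise KindMismatchError(
                f"{type(criteria).__name__} cannot filter {fragment.kind} fragments"
            )
        if criteria.require_exclusive and fragment.canonical_smiles not in exclusive_set:
            continue
        if criteria.admits(fragment):
            selected.append(fragment)
    return selected


def select_bioactive_like(
    candidates: Sequence[Union[str, Fragment]],
    active_refs: Sequence[Union[str, Fragment]],
    inactive_refs: Sequence[Union[str, Fragment]],
    config: SimilarityConfig = SimilarityConfig(),
) -> list[Union[str, Fragment]]:
    """Candidates near an active reference and away from all inactive
    references; a candidate near both is dropped."""
    if not active_refs or not inactive_refs:
        raise ConfigurationError("active and inactive reference sets must be non-empty")
    near_active = screen_within(candidates, active_refs, config)
    near_inactive = {
        _key(c) for c in screen_within(candidates, inactive_refs, config)
    }
    return [c for c in near_active if _key(c) not in near_inactive]


def _key(obj: Union[str, Fragment]) -> str:
    return obj.canonical_smiles if isinstance(obj, Fragment) else obj


def annotate_exclusivity(
    selected: Iterable[Fragment],
    other_collection_indexes: Iterable[FragmentIndex],
) -> list[tuple[Fragment, bool]]:
    """Flag each fragment as exclusive (absent from every comparison
    collection index)."""
    other_keys: set[str] = set()
    for idx in other_collection_indexes:
        other_keys |= set(idx.counts)
    return [(f, f.canonical_smiles not in other_keys) for f in selected]
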