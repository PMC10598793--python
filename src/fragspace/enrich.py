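"""Bioactivity enrichment of fragments.

For a fragment present in an active and an inactive molecule subset,
the activity ratio is

    R_bioactive = (% active) / (% inactive)

where % active = 100 * n_active / N_active is the fragment's relative
occurrence among the N_active active molecules (and likewise for the
inactives).  No pseudocounts are applied: a fragment occurring only in
actives has R = +inf and only in inactives R = 0, so exclusive
fragments land in the extreme classes by construction.  Fragments are
labeled ``active`` when R >= 4, ``inactive`` when R <= 0.25 and
``nonpreferential`` in between (both bounds inclusive, thresholds
configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .chem import open_text
from .errors import ConfigurationError, KindMismatchError
from .store import FragmentIndex

ACTIVE = "active"
INACTIVE = "inactive"
NONPREFERENTIAL = "nonpreferential"

#: x-axis sentinels for fragments exclusive to one subset (volcano plot)
LEFT_SENTINEL = float("-inf")
RIGHT_SENTINEL = float("inf")


@dataclass(frozen=True)
class EnrichmentConfig:
    hi_threshold: float = 4.0
    lo_threshold: float = 0.25

    def __post_init__(self):
        if not (0 < self.lo_threshold < 1 < self.hi_threshold):
            raise ConfigurationError(
                "thresholds must satisfy 0 < lo < 1 < hi, got "
                f"lo={self.lo_threshold}, hi={self.hi_threshold}"
            )


@dataclass(frozen=True)
class EnrichmentRecord:
    fragment: str
    kind: str
    n_active: int
    n_inactive: int
    pct_active: float
    pct_inactive: float
    r_bioactive: float  # in [0, +inf]
    total_occurrence: int
    label: str


def _ratio(pct_active: float, pct_inactive: float) -> float:
    if pct_inactive == 0.0:
        return float("inf")  # pct_active > 0 guaranteed: record exists
    return pct_active / pct_inactive


def classify(r: float, config: EnrichmentConfig = EnrichmentConfig()) -> str:
    if r >= config.hi_threshold:
        return ACTIVE
    if r <= config.lo_threshold:
        return INACTIVE
    return NONPREFERENTIAL


def compute_enrichment(
    active_index: FragmentIndex,
    inactive_index: FragmentIndex,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[EnrichmentRecord]:
    """One record per fragment present in either subset, sorted by key."""
    if active_index.kind != inactive_index.kind:
        raise KindMismatchError("active and inactive indexes must share a kind")
    if active_index.n_molecules == 0 or inactive_index.n_molecules == 0:
        raise ConfigurationError(
            "both the active and the inactive subset must be non-empty"
        )
    n_act_total = active_index.n_molecules
    n_inact_total = inactive_index.n_molecules
    records = []
    for key in sorted(set(active_index.counts) | set(inactive_index.counts)):
        n_a = active_index.counts.get(key, 0)
        n_i = inactive_index.counts.get(key, 0)
        pct_a = 100.0 * n_a / n_act_total
        pct_i = 100.0 * n_i / n_inact_total
        r = _ratio(pct_a, pct_i)
        records.append(
            EnrichmentRecord(
                fragment=key,
                kind=active_index.kind,
                n_active=n_a,
                n_inactive=n_i,
                pct_active=pct_a,
                pct_inactive=pct_i,
                r_bioactive=r,
                total_occurrence=n_a + n_i,
                label=classify(r, config),
            )
        )
    return records


def partition(
    records: Iterable[EnrichmentRecord],
    config: EnrichmentConfig = EnrichmentConfig(),
) -> tuple[set[str], set[str], set[str]]:
    """Disjoint, exhaustive split of fragment keys into
    (active, nonpreferential, inactive) sets at the config thresholds."""
    active, nonpref, inactive = set(), set(), set()
    for rec in records:
        label = classify(rec.r_bioactive, config)
        if label == ACTIVE:
            active.add(rec.fragment)
        elif label == INACTIVE:
            inactive.add(rec.fragment)
        else:
            nonpref.add(rec.fragment)
    return active, nonpref, inactive


def volcano_data(
    records: Iterable[EnrichmentRecord],
) -> list[tuple[float, int]]:
    """``(x, y)`` pairs for a volcano plot: x = log2(R_bioactive), y =
    total occurrence.  Fragments exclusive to the inactives map to the
    left sentinel (−inf) and fragments exclusive to the actives to the
    right sentinel (+inf), mirroring the vertical edge lines of the
    plot."""
    points = []
    for rec in records:
        if rec.pct_active == 0.0:
            x = LEFT_SENTINEL
        elif rec.pct_inactive == 0.0:
            x = RIGHT_SENTINEL
        else:
            x = math.log2(rec.r_bioactive)
        points.append((x, rec.total_occurrence))
    return points


def write_enrichment(records: Iterable[EnrichmentRecord], path) -> None:
    """TSV export; r_bioactive uses the literals ``inf`` and ``0`` at
    the extremes."""
    with open_text(path, "wt") as fh:
        fh.write(
            "fragment_smiles\tkind\tn_active\tn_inactive\tpct_active"
            "\tpct_inactive\tr_bioactive\tlabel\n"
        )
        for rec in records:
            r = "inf" if math.isinf(rec.r_bioactive) else repr(rec.r_bioactive)
            fh.write(
                f"{rec.fragment}\t{rec.kind}\t{rec.n_active}\t{rec.n_inactive}"
                f"\t{rec.pct_active:.6g}\t{rec.pct_inactive:.6g}\t{r}\t{rec.label}\n"
            )
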