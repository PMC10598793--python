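"""Occurrence indexing and collection statistics."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragspace import (
    FragmentIndex,
    KindMismatchError,
    build_index,
    canonical_key,
    coverage,
    exclusives,
    fragment_molecule,
    frequency_distribution,
    singletons,
    size_histograms,
    top_n,
)
from fragspace.store import read_index, write_index


def make_index(counts, kind="RF", n_molecules=None):
    return FragmentIndex(
        collection_name="t",
        kind=kind,
        counts=dict(counts),
        n_molecules=n_molecules if n_molecules is not None else max(counts.values(), default=0),
    )


class TestBuildIndex:
    def test_within_molecule_duplicates_count_once(self):
        index = build_index(["Cc1ccc(C)cc1"], kind="AF")
        assert index.counts == {"C": 1}
        assert index.n_molecules == 1

    def test_rf_counts_from_examples(self):
        index = build_index(["Cc1ccccc1", "COc1ccccc1"], kind="RF")
        assert index.counts == {
            canonical_key("Cc1ccccc1"): 1,
            canonical_key("Oc1ccccc1"): 1,
        }

    def test_empty_stream(self):
        index = build_index([], kind="RF")
        assert index.counts == {} and index.n_molecules == 0

    def test_unparsable_records_skipped_and_counted(self):
        index = build_index(["CCO", "not-a-smiles", "C1CC"], kind="AF")
        assert index.n_molecules == 1
        assert index.n_skipped == 2

    def test_molecule_dedup_flag(self):
        mols = ["Cc1ccccc1", "Cc1ccccc1", "C1=CC=CC=C1C"]  # all toluene
        assert build_index(mols, "RF").counts[canonical_key("Cc1ccccc1")] == 3
        assert (
            build_index(mols, "RF", dedupe_molecules=True).counts[
                canonical_key("Cc1ccccc1")
            ]
            == 1
        )

    @settings(derandomize=True, max_examples=20)
    @given(split=st.lists(st.booleans(), min_size=40, max_size=40))
    def test_merge_additivity_over_disjoint_shards(self, split, oracle_fixture):
        molecules = oracle_fixture[:40]
        left = [m for m, s in zip(molecules, split) if s]
        right = [m for m, s in zip(molecules, split) if not s]
        merged = build_index(left, "RF").merge(build_index(right, "RF"))
        whole = build_index(molecules, "RF")
        assert merged.counts == whole.counts
        assert merged.n_molecules == whole.n_molecules


class TestSingletonsExclusives:
    def test_singletons_simple(self):
        assert singletons(make_index({"A": 1, "B": 5})) == {"A"}
        assert singletons(make_index({})) == set()

    def test_singletons_match_brute_force_scan(self, oracle_fixture):
        molecules = oracle_fixture[:50]
        index = build_index(molecules, "AF")
        scan = Counter()
        for mol in molecules:
            scan.update({f.canonical_smiles for f in fragment_molecule(mol)[1]})
        assert singletons(index) == {k for k, c in scan.items() if c == 1}
        # singletons and non-singletons partition the key set
        assert singletons(index) | {
            k for k in index.counts if index.counts[k] > 1
        } == set(index.counts)

    def test_exclusives_set_algebra(self):
        target = make_index({"A": 1, "B": 2, "C": 3})
        assert exclusives(target, [make_index({"X": 1})]) == {"A", "B", "C"}
        assert exclusives(target, [make_index({"A": 1, "B": 1, "C": 9, "X": 1})]) == set()
        assert exclusives(
            target, [make_index({"A": 1}), make_index({"C": 2})]
        ) == {"B"}

    def test_exclusives_kind_mismatch(self):
        with pytest.raises(KindMismatchError):
            exclusives(make_index({"A": 1}, kind="RF"), [make_index({}, kind="AF")])


class TestCoverage:
    def test_vacuous_molecule_is_covered(self):
        assert coverage(["CCC"], kind_filter="RF") == 1.0

    def test_half_covered(self):
        mols = ["C1CCCCCCCCCCCCC1", "c1ccccc1"]  # RF HAC 14 vs 6
        assert coverage(mols, kind_filter="RF", max_hac=13) == 0.5

    def test_small_molecule_library_fully_covered(self, oracle_fixture):
        assert coverage(oracle_fixture[:60], kind_filter="both", max_hac=13) == 1.0

    def test_monotone_in_max_hac(self):
        mols = ["C1CCCCCCCCCCCCC1", "c1ccccc1", "Cc1ccccc1", "CCCCCCCCCCCCCC"]
        values = [coverage(mols, "both", h) for h in range(2, 16)]
        assert values == sorted(values)


class TestDistributions:
    def test_frequency_distribution(self):
        assert frequency_distribution(make_index({"A": 1, "B": 1, "C": 3})) == [
            (1, 2),
            (3, 1),
        ]
        assert frequency_distribution(make_index({})) == []

    def test_histogram_sums_to_key_count(self, oracle_fixture):
        index = build_index(oracle_fixture[:80], "RF")
        hist = frequency_distribution(index)
        assert sum(n for _, n in hist) == len(index.counts)

    def test_top_n(self):
        index = make_index({"A": 2, "B": 9})
        assert top_n(index, 1) == ["B"]
        assert top_n(index, 0) == []
        # ties broken lexicographically, deterministic full ordering
        tied = make_index({"Z": 5, "A": 5, "M": 7})
        assert top_n(tied, 3) == ["M", "A", "Z"]

    def test_top_n_agrees_with_full_sort(self, oracle_fixture):
        index = build_index(oracle_fixture[:80], "AF")
        full = sorted(index.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        assert top_n(index, 5) == [k for k, _ in full[:5]]


class TestSizeHistograms:
    def test_single_benzene(self):
        hist = size_histograms(["c1ccccc1"])
        assert hist.compounds == {6: 1}
        assert hist.rf == {6: 1}
        assert hist.af == {}

    def test_empty(self):
        hist = size_histograms([])
        assert hist.compounds == {} and hist.rf == {} and hist.af == {}

    def test_totals_match_direct_count(self, oracle_fixture):
        molecules = oracle_fixture[:50]
        hist = size_histograms(molecules)
        assert sum(hist.compounds.values()) == len(molecules)
        rf_keys, af_keys = set(), set()
        for mol in molecules:
            rfs, afs = fragment_molecule(mol)
            rf_keys |= {f.canonical_smiles for f in rfs}
            af_keys |= {f.canonical_smiles for f in afs}
        assert sum(hist.rf.values()) == len(rf_keys)
        assert sum(hist.af.values()) == len(af_keys)

    def test_exclusive_histograms_with_comparison(self, oracle_fixture):
        first, second = oracle_fixture[:30], oracle_fixture[30:60]
        other = build_index(second, "RF")
        hist = size_histograms(first, other_rf_indexes=[other])
        assert sum(hist.erf.values()) == len(
            exclusives(build_index(first, "RF"), [other])
        )


def test_index_serialization_round_trip(tmp_path, oracle_fixture):
    index = build_index(oracle_fixture[:30], "RF", collection_name="toy")
    for name in ("idx.tsv", "idx.tsv.gz"):
        path = tmp_path / name
        write_index(index, path)
        loaded = read_index(path)
        assert loaded.counts == index.counts
        assert loaded.kind == "RF"
        assert loaded.collection_name == "toy"
        assert loaded.n_molecules == index.n_molecules
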