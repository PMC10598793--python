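# Methods

## Molecule normalization and fragment identity

Input SMILES are parsed with RDKit. Multi-component records (salts)
are reduced to the component with the most heavy atoms, ties broken by
lexicographic order of the component canonical SMILES, because
fragment statistics are per molecule and counter-ions would otherwise
pollute the acyclic-fragment counts. Stereo descriptors and isotope
labels are stripped before the canonical key is computed, so
stereoisomeric fragments collapse to one identity and counts are
reproducible across differently annotated sources; formal charges are
preserved as written, with no neutralization pass, to avoid inventing
chemistry the inputs do not contain. Aromaticity perception is
RDKit's default model, so Kekulé (dearomatized) input normalizes to
the same canonical key as aromatic input.

## Fragmentation rules

A *ring system* is a connected component of the subgraph induced by
ring atoms. This merges fused and spiro rings (which share an atom)
and also keeps two rings joined by a direct ring–ring bond (biphenyl)
in a single system: only bonds between two acyclic atoms are ever
broken during RF construction, never ring–ring bonds. This is a
deliberate reading of the breakdown rules and is stated prominently
because directly bonded ring systems are an easy point of divergence
between implementations.

* **RF extraction** — one fragment per ring system: the system's ring
  atoms plus every acyclic atom directly bonded to one of them, with
  original bond orders. An acyclic atom bonded to ring atoms of *k*
  distinct systems (an acyclic bridge) is duplicated into all *k* RFs.
  Two retained acyclic atoms can never be bonded to each other inside
  one RF — such a bond would either close a ring (same system) or is
  an acyclic–acyclic bond that the rules break (different systems).
* **AF extraction** — the connected components of the subgraph induced
  by acyclic atoms, a multiset (deduplication is the counting layer's
  job, since occurrence counts distinct molecules).

Cut valences are re-saturated with implicit hydrogens, including on
atoms that were written as bracket atoms (for example a cut
`[NH2+]` becomes `[NH3+]`): fragment identity is the
hydrogen-saturated heavy-atom graph, so the `N` cut from a secondary
and from a tertiary amine are the same AF. An exocyclic double bond is
kept in the RF (the doubly bonded acyclic atom is ring-adjacent) and
severed for the AF, so a ketone oxygen yields the water-like fragment
`O`.

Implementation: fragments are cut by deleting atoms from an editable
copy of the parent and re-sanitizing. The test suite holds an
independent brute-force implementation that classifies ring atoms with
a networkx cycle basis, groups systems and components with networkx
connected components, and rebuilds each fragment atom by atom; the two
routes are compared exactly on >500 fixture molecules covering fused,
spiro and bridged rings, exocyclic double bonds, acyclic bridges,
charged atoms and single-atom substituents.

## Structural profiles and scores

RF profiles report the cyclomatic ring count (bonds − atoms + 1 of the
connected fragment), the largest SSSR ring size, the number of
retained acyclic atoms, and the number of non-carbon heavy atoms. AF
profiles report quaternary centers (carbon with exactly four
heavy-atom neighbors, neighbors of any element), triple bonds,
heteroatoms and terminal atoms (heavy atoms with at most one heavy
neighbor; an isolated atom counts as one terminal atom).

Synthetic accessibility (SAscore, 1 easy to 10 hard) and natural
product likeness (NPscore, higher = more natural-product-like) are
delegated to the published reference implementations shipped in
RDKit's Contrib tree, with their published fragment-contribution
tables; a missing data installation raises an explicit error rather
than returning silent zeros. Because loading the NPscore model is
costly, profiles fill the score fields only on request
(`with_scores=True`); the structural filters never need them.

## Occurrence statistics

A fragment index maps canonical keys to the number of *distinct*
molecules containing the fragment (within-molecule duplicates count
once). Indexes over disjoint molecule sets merge additively, so
collections can be processed in shards out of core; all tests run in
memory. Input collections are assumed pre-deduplicated at the
molecule level; an optional flag applies canonical-key deduplication.
*Coverage* at `max_hac` is the fraction of molecules all of whose
fragments of the selected kind(s) have at most `max_hac` heavy atoms;
a molecule with no fragments of that kind counts as covered (vacuous
truth) — the reading under which a fully enumerated ≤13-atom space
covers itself at 100%. Top-N rankings break count ties by canonical
key so output is deterministic.

## Enrichment

`R_bioactive = (% active)/(% inactive)` with percentages relative to
the total sizes of the two subsets. No pseudocounts: fragments
exclusive to one subset get `R = +∞` or `R = 0`, which places all
exclusive fragments (including singletons) in the extreme classes by
construction. Both class bounds are inclusive (`R ≥ 4` active,
`R ≤ 0.25` inactive); the nonpreferential class is exactly the open
complement interval. The ratio is scale-invariant, and swapping the
subsets maps every finite `R` to `1/R` and exchanges the labels — both
properties are tested. Volcano-plot data report `log2 R` with `±∞`
sentinels for one-sided fragments, mirroring the vertical edge columns
of such plots.

## MinHash atom-pair fingerprints

Shingles are `envA|d|envB` tokens over all unordered heavy-atom pairs:
`env` is the canonical SMILES of the atom's circular environment at
radius 1 and at radius 2 (diameter up to four bonds), the two
environments are ordered lexicographically inside the token, and `d`
is the topological bond-count distance. Atoms whose neighborhood does
not extend to the full radius contribute their largest available
environment, and a lone atom emits self-pair tokens at distance 0, so
the very common single-atom AFs (`O`, `N`, `F`, `Cl`) are
fingerprintable.

Signatures use 256 MinHash permutations. Tokens are hashed to 64 bits
with BLAKE2b (stable across processes); permutations are seeded
multiply-shift maps `x ↦ a·x + b (mod 2^64)` with odd `a`, drawn from
a seeded generator, and the signature stores the per-permutation
minima together with seed and dimension count. Signatures are
comparable only under identical configuration, which the API enforces.
The matching-position fraction estimates Jaccard similarity with
binomial error `√(J(1−J)/256)`; tests bound the mean absolute error
over 100 random fragment pairs by `3/√256 ≈ 0.19`, and screen
decisions at `d_J ≤ 0.6` are compared against an exact-Jaccard oracle,
tolerating disagreement only when the estimate lies within one
permutation quantum (1/256) of the threshold. The triangle inequality
is *not* asserted for the estimator. Screening is a deterministic
linear scan; results are monotonically nested in `d_max`.

## Selection

Structural selection keeps fragments within explicit bounds — RFs: up
to 2 rings, largest ring ≤ 7, ≤ 3 heteroatoms, ≤ 3 acyclic atoms;
AFs: no quaternary center, ≤ 1 triple bond, ≤ 4 heteroatoms, ≤ 4
terminal atoms — optionally restricted to fragments exclusive to the
source collection. "Ring size up to seven" is implemented as largest
SSSR ring ≤ 7. Similarity selection keeps candidates within
`d_J ≤ 0.6` of at least one active-enriched reference and removes any
candidate within 0.6 of an inactive-enriched reference; removal takes
precedence, and the result is a set difference, hence independent of
screening order. The active/inactive reference sets are taken as
explicit inputs (typically the enrichment module's labels at the
default thresholds) so the two stages compose cleanly.

## Synthetic libraries

The generator attaches acyclic substituents to fully cyclic scaffolds
through single bonds at hydrogen-bearing positions, so ground-truth
fragmentation is unambiguous: the RF is the scaffold plus one head
atom per substituent, the AFs are the substituents. A bridge mode
joins two scaffolds through one acyclic linker, and a single-atom
linker must then appear in both RFs, exercising the duplication rule
with known truth. Chemically invalid draws are rejected and resampled
(tallied). Activity splits assign planted-fragment molecules to the
active subset with probability `p = ρ·N_a/(ρ·N_a + N_i)`, making the
ratio of expected relative occurrences equal the target ρ; remaining
slots fill at random. Everything is deterministic per seed.

The generator emulates the occurrence structure real collections show
(shared frequent fragments, rarer combinations, planted enrichment)
but not realistic property distributions, molecule sizes beyond ~15
atoms, or the functional-group biases of curated databases — passing
tests demonstrate correctness of the counting and selection machinery,
not that any particular database will show a particular fragment
profile.

## Problem sizes and numerical choices

The verification suite runs entirely on generated data: the oracle
fixture holds ~750 unique molecules of ≤12 heavy atoms; enrichment
recovery uses a 4000-molecule library split 2000/2000 with a fragment
planted at ratio 8 and a 25% acceptance band (binomial noise at these
sizes has a relative standard deviation of roughly 13%, so occasional
seeds fall outside the band — the fixed study seeds are part of the
stated conditions); MinHash fidelity uses 100 random fragment pairs
and a 30×10 candidate/reference screen. These sizes were chosen so
the whole suite verifies every contract in well under a minute per
check while keeping sampling error small against the stated bounds.

Degenerate inputs are handled explicitly: empty lines are a skip
signal distinct from parse errors; acyclic molecules yield no RFs and
fully cyclic molecules no AFs (both valid, empty results); empty
shingle sets, empty reference sets and empty activity subsets raise
configuration errors rather than producing silent values.

## Known limitations

* Canonical identity follows RDKit's canonicalization and aromaticity
  model; counts compared across toolkits (or toolkit versions) can
  differ in dialect-sensitive corners.
* The MinHash token grammar is this package's own (documented above);
  signatures are not interchangeable with other atom-pair fingerprint
  implementations, although the estimated distances target the same
  Jaccard geometry.
* Full-database statistics (hundreds of millions of molecules) are
  supported in principle through index merging but are not exercised
  by the test suite.
* Tautomers are distinct identities; no tautomer canonicalization is
  attempted.
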