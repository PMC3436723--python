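# Methods

This note documents the models and procedures implemented in `nplikeness`,
the choices made where the design was genuinely open, and what the bundled
fixture corpora do and do not demonstrate.

## The scoring model

NP-likeness is a per-molecule real number contrasting fragment frequencies
between two training corpora. For a fragment (atom signature) *i*:

```
fragment_i = ln( (NP_i + α) / (SM_i + α) · SM_t / NP_t )
```

- `NP_i`, `SM_i` — **document frequencies**: the number of *distinct*
  molecules of the natural-product and synthetic corpus containing the
  fragment. A molecule containing a fragment several times still counts once.
- `NP_t`, `SM_t` — corpus sizes (distinct molecules).
- `α ≥ 0` — pseudo-count, default 1.

A query molecule with signature multiset `{s_1 … s_N}` (one per heavy atom,
duplicates kept — term frequency on the query side) scores

```
raw   = Σ_k fragment(s_k)
score = raw / N
```

The `1/N` normalisation stops large molecules from accumulating score by
size. Higher is more natural-product-like.

Choices behind this formulation:

- **Logarithm base**: natural log. The base is a pure scale factor — it
  changes no ranking — and ln gives the familiar −3…+3 range on
  well-separated corpora.
- **Smoothing**: the bare log-ratio is undefined when a fragment is missing
  from either corpus (`ln 0` or division by zero). The pseudo-count is added
  to `NP_i` and `SM_i` only, not to the totals: a fragment absent from both
  corpora then scores exactly `ln(SM_t/NP_t)` (zero for equal-size corpora),
  and the statistic converges to the bare ratio as counts grow. With `α = 0`
  the literal equation is evaluated and an uncovered fragment raises an
  explicit error rather than returning ±∞.
- **No clipping**: observed score ranges are a property of the corpora, not
  a defined bound, so nothing is truncated.
- **Exact antisymmetry**: the statistic is evaluated as
  `(ln(NP_i+α) − ln(SM_i+α)) + (ln SM_t − ln NP_t)`. Each parenthesised
  difference negates exactly under a corpus swap, and IEEE addition and
  division commute with negation, so swapping the corpora negates every
  fragment and molecule score bit-for-bit. This is a useful invariant for
  testing and costs nothing.
- **`N` = number of signature records for the molecule's UUID.** After
  curation a molecule may exist as several disconnected fragments sharing
  one UUID; their signatures pool, so `N` is the total heavy-atom count of
  the surviving fragments.

## Atom signatures

An atom signature of height *h* canonically serializes the subgraph induced
on all heavy atoms within *h* bonds of a root atom. Node labels carry
element, formal charge and an aromaticity flag (lowercase element symbol);
edge labels carry bond order (`-`, `=`, `#`, `:`). Hydrogen counts,
stereochemistry and isotopes are excluded: signatures are topological
heavy-atom descriptors, and the score normalises by heavy-atom count.

The environment is unfolded into a layered tree: layer *k* holds atoms at
BFS distance *k*; each tree node expands a child for *every* neighbour in
the next layer (atoms reachable by several shortest paths occur in several
nodes), and same-layer ring bonds appear as paired non-expanding closure
leaves. Atoms occurring in more than one tree node receive occurrence
numbers (`[C,1]`), so merging equally-numbered nodes reconstructs the exact
induced subgraph — this is what decoding does, and it is why equal text
implies isomorphic environments.

Canonical child order is the lexicographic order of the number-free subtree
strings. When two siblings have *equal* number-free strings but different
atom identities (possible only in cycles), every admissible ordering is
serialized and the smallest complete string wins; the candidate set is an
isomorphism invariant, so the minimum is canonical. The search is bounded
(10^5 orderings) — far beyond anything reachable at height 2–3 on molecular
graphs, where tie groups are tiny.

Properties guaranteed by construction (and verified by the test suite
against a networkx subgraph-isomorphism oracle):

- permutation invariance of the text;
- equal text at height *h* ⟺ rooted *h*-environments isomorphic;
- height monotonicity: signatures that differ at height *h* differ at every
  greater height;
- decode → re-encode identity.

Aromaticity is perceived once, by RDKit's default model at parse time, and
the stored flags are reused verbatim everywhere downstream — training
corpora and queries therefore always agree on aromaticity, which is the main
source of cross-toolkit score drift for descriptors of this family. Decoded
fragments keep their flags and are never re-perceived (their partial rings
would not survive it); their open valences are filled with implicit
hydrogens from a standard valence table (aromatic bonds counting 1.5),
purely cosmetic since hydrogen counts do not enter the text.

The default height is 2: two bond layers capture ring/substituent context
while keeping the fragment vocabulary dense enough for frequency statistics
on small corpora.

## Curation

Stages run in fixed order per molecule; each input UUID ends up in exactly
one of *kept* / *discarded*:

1. **Small components**: connected components with fewer than
   `min_fragment_atoms` (default 6) heavy atoms are deleted — counter-ions
   and solvates. All counts are heavy-atom counts, consistent with the
   implicit-hydrogen graph model.
2. **Element whitelist** (C, H, N, O, P, S, F, Cl, Br, I, As, Se, B): any
   other element discards the molecule. Running this *after* the component
   filter means a removable metal counter-ion does not doom an organic
   parent.
3. **Sugar removal** (optional, on by default): see below.
4. **Final size filter**: components shrunk below the cutoff by
   deglycosylation are deleted. A molecule reduced to nothing is discarded
   as `empty_after_curation`; surviving disconnected fragments are emitted
   as separate records sharing the parent UUID.

Sugar removal exists to score the chemically distinctive aglycone rather
than the ubiquitous glycoside decoration. Definitions:

- **Ring sugar**: 5- or 6-ring, exactly one ring oxygen, all other ring
  atoms carbon, no in-ring C=C, and ≥ (ring size − 3) ring carbons bearing
  an exocyclic single-bonded oxygen. Furanoses and pyranoses match; THF,
  pyran and C-glycoside ethers without the oxygen pattern do not.
- **Linear sugar**: an acyclic chain of ≥ 3 contiguous sp3 carbons, each
  bearing exactly one single-bonded oxygen, none in a ring (open-chain
  saccharides, not isolated diols).
- A sugar **unit** is the match plus its terminal hydroxyl oxygens and
  CH2OH-type appendages.
- A unit is removed when every bond leaving it passes through an exocyclic
  bridging oxygen (glycosidic/ether link — C-glycosides are kept) and at
  most one link leads to another sugar unit. Units are perceived once per
  round and peeled outside-in against that fixed list, so oligosaccharide
  chains strip completely even though removing a terminal sugar takes its
  bridging oxygen with it. The bridging oxygen belongs to neither side and
  is always deleted; a sugar bridging two scaffolds therefore splits the
  molecule into UUID-sharing fragments.

Deliberately absent: tautomer canonicalisation, salt dictionaries, charge
neutralisation. The pipeline is idempotent — curating curated output changes
nothing.

## Fixture corpora

`nplikeness.fixtures` generates seeded corpora emulating the structural
contrast between natural-product collections and synthetic screening
libraries: NP-like molecules are assembled from fused/bridged saturated
carbocycles, lactones and cyclic ethers with hydroxyl/methyl/methoxy
decoration (sp3- and oxygen-rich); synthetic-like molecules from flat
(hetero)aromatic scaffolds with halogen, CF3, nitrile, amide and sulfonamide
decoration. Defaults: 30 % of NP-like molecules carry a glycosidically
attached pyranose (glycosylation is common among natural products), 20 % of
synthetic-like molecules carry a disconnected chloride counter-ion (typical
of vendor files), and 0 % carry the non-whitelisted trimethylsilyl marker
(enabled explicitly in curation tests). All randomness flows from one
seeded generator; a config reproduces its corpora byte for byte, and
fraction-controlled features are assigned to an exact `round(f·n)` subset.

What passing tests on these fixtures shows: the pipeline's algebraic
invariants hold end to end, and the scorer separates the two grammars
essentially perfectly (held-out rank separation ≈ 1.0, mean scores around
+3 / −3). What it does **not** show: performance on real corpora, where the
structural contrast is far subtler, scores overlap substantially, and
separation quality depends on the choice and size of training sets.

## Problem sizes and numerics

- The acceptance script trains on 200 + 200 curated fixture molecules and
  scores 100 + 100 held-out ones at height 2 — a few thousand signatures,
  seconds of runtime — which is ample to exercise every code path and the
  separation claim at fixture scale.
- Rank separation is reported as the Mann–Whitney probability
  P(score_NP > score_SM) with ties counted ½.
- Density plots use a Gaussian kernel with Silverman bandwidth on a fixed
  512-point grid spanning the data range ± 3 bandwidths; a zero-variance
  score set is drawn as a narrow triangular spike instead of a KDE.
- Model files are versioned plain text (header with totals, height, α; then
  two signature→count tables), so a trained model is self-describing and
  diffable.

## Known limitations

- Signature text is canonical *within this package*; other toolkits'
  signature strings are not byte-compatible (equivalence is at the level of
  the atom partition, not the serialization).
- The sugar definitions are heuristics; exotic sugars (deoxy/amino sugars
  with few hydroxyls, anhydro forms) can escape them, and heavily oxygenated
  non-sugar rings can match.
- Decoded fragments' hydrogen counts are valence-table estimates; aromatic
  nitrogen H placement (pyrrole vs pyridine type) is not always recoverable
  from a fragment.
- SDF support is V2000 only; V3000 files are rejected with a clear error.
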