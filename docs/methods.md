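# Methods

## Model

The package generates the closure of a small rule system rather than a
curated list: every glycerolipid and glycerophospholipid that can be
assembled from a glycerol backbone, a class-defining head group and 1–3
radyl chains drawn from a bounded fatty-chain space. Records are stored at
the four MS-oriented resolution levels (Species → fatty-acid scan species
→ sub-species → isomer), and every lower-resolution record is exactly the
generalisation of its children: parents forget *sn* order, chain splits or
double-bond positions, never mass or formula.

### Chain space

A chain is `(linkage, carbons, double_bonds, positions?)` with
`linkage ∈ {acyl, alkyl}`. Default bounds (all configurable):

| parameter | default | meaning |
|---|---|---|
| `min_carbons` / `max_carbons` | 2 / 30 | chain length range |
| `allow_odd_carbons` | true | odd chains admitted |
| `min_double_bonds` | 0 | lower bound on unsaturation |
| `max_double_bonds` | none | optional cap; geometry otherwise decides |
| `first_db_min_position` | 2 | first double bond at Δ-position ≥ 2 |
| `db_position_step` | 3 | spacing unit between double bonds |
| `spacing_mode` | `multiples` | see below |
| `allow_terminal_db` | true | position `carbons − 1` admitted |

Positions are Δ-style bond indices from the carboxyl/linkage carbon; the
bond between C_k and C_{k+1} is position k, so feasible positions run
from 2 to `carbons − 1`. Under the defaults this yields 174 chain types
(carbon/double-bond pairs) and, summing the per-type position-set counts,
9,658 positioned chain types.

The community spacing convention ("double bonds at a 3n+2 distance, bonds
may be skipped") admits two readings, and the difference matters at scale:

* **`multiples`** (default): consecutive double-bond positions differ by a
  positive multiple of 3 — methylene-interrupted bonds (difference 3) with
  skips (6, 9, ...). This reproduces the dominant natural patterns
  (9; 9,12; 9,12,15; 5,8,11,14) and is the reading used throughout.
* **`affine`**: the literal arithmetic reading, difference ∈ {2, 5, 8, ...}.
  It admits conjugated-adjacent patterns that are rare in nature and
  enlarges the space to 239 chain types.

Both are implemented; `generation_report()` quantifies the gap (below).
Excluded by design: branched, hydroxylated or otherwise modified chains,
and alkenyl (plasmalogen) linkages.

### Sub-classes and hierarchy conventions

Sub-classes are the Cartesian cross of main classes with linkage multisets
of their slot count: 6 diradyl glycerophospholipid classes × 3 multisets,
6 monoradyl (lyso) partners × 2, plus MG (2), DG (3) and TG (4) — 39 in
all. Linkage-position variants are collapsed into one sub-class; the
drawing/naming canonicalization places alkyl chains in the leading *sn*
slots, so mixed-linkage sub-species counts are ordered assignments with
the alkyl slots pinned.

Conventions where the design was genuinely open:

* **Lyso naming.** Monoradyl glycerophospholipids use the field's
  L-prefixed codes (`LPC 16:0`, sub-species `LPC 16:0/0:0`). A bare
  `PC 16:0` would be ambiguous between the lyso species and the diacyl
  species with 16 total carbons, and the name grammar is required to be
  invertible.
* **TG slots** are ordered triples (sn1 ≠ sn3, no enantiomer collapsing);
  DG is a single sub-class per linkage multiset with two slots (no
  1,2-/1,3- distinction).
* **Species realizability.** A `(total carbons, total double bonds)` pair
  is a Species only if some multiset of valid chains realises it — no
  orphan species.
* **Degenerate names.** The grammar cannot distinguish a one-slot FAS from
  its Species, nor a fully saturated isomer from its sub-species; such
  names parse to the least-resolved record. Everywhere else
  `parse(format(r)) = r` exactly, and non-canonical forms (unsorted FAS
  chains, alkyl outside sn1) are rejected rather than silently
  re-canonicalised.

### Mass arithmetic

Neutral formulas: glycerol + head group + Σ chains − (number of chains +
1 if phospho head) × H2O, with acyl chains contributing the free fatty
acid C_cH_{2c−2d}O2 and alkyl chains the fatty alcohol C_cH_{2c+2−2d}O.
Head-group blocks (phosphocholine C5H14NO4P, phosphoethanolamine
C2H8NO4P, phosphoserine C3H8NO6P, phosphoglycerol C3H9O6P,
phosphoinositol C6H13O9P, phosphate H3PO4, bare hydroxyl for
glycerolipids) are stored as data and each is validated in the tests
against an independently known reference formula (PC 34:1 → C42H82NO8P,
LPC 16:0 → C24H50NO7P, TG 52:2 → C55H102O6, ...). Element masses are
CODATA/IUPAC monoisotopic values at ≥ 6 decimals, cross-checked against
pyteomics in the tests. Records are neutral; charge enters only through
adduct deltas (`mz·|z| = M + δ`, δ including the electron mass), all
singly charged.

### MS1 search

Each query m/z is inverted through every selected adduct and matched
against the Species table (generated on the fly from rules + sub-classes)
within a symmetric tolerance, absolute (Da) or relative to the
theoretical mass (ppm). The implementation uses a sorted-mass bisection
window with an exact final predicate; the tests hold it equal to an
exhaustive linear scan. Hits are ordered by absolute error, ties by
canonical name; category/main-class/sub-class exclusion filters are
applied to the search space, so growing tolerance, adding adducts or
dropping filters can only add hits.

## Whole-space totals and their sensitivity

`count_records` is the closed-form twin of each enumeration (dynamic
programming over chain-type sums for Species; products of multiset
coefficients for FAS; `types^slots` and `positioned_types^slots` for
sub-species and isomers) and is verified against exhaustive enumeration at
reduced bounds. Under the defaults, `generation_report()` computes:

| reconstruction | spacing | chain types | Species | SubSpecies |
|---|---|---|---|---|
| 39 sub-classes (default) | multiples of 3 | 174 | 21,637 | 21,710,328 |
| 39 sub-classes | literal 3n+2 | 239 | 30,050 | 55,810,563 |
| without trialkyl-TG | multiples of 3 | 174 | 20,223 | 16,442,304 |
| acyl-only glycerolipids | multiples of 3 | 174 | 15,931 | 5,845,530 |

The published totals this system descends from (20,297 Species, 36.15
million sub-species) were produced with a sub-class table defined only in
supplementary material and an implementation whose spacing reading is not
recoverable from the prose; as the table shows, both choices move the
totals by tens of percent, and the published values fall inside the
spanned range (the no-trialkyl-TG variant reproduces the Species total to
0.4 %). The package therefore reports its totals together with this
sensitivity table instead of tuning either choice toward the printed
numbers.

## Numerical and engineering choices

* Formula arithmetic is exact integer arithmetic; masses are IEEE doubles,
  with additivity asserted to 1e-9 Da and published-value comparisons at
  their printed precision.
* All enumerations have fixed, documented orders; repeated runs are
  byte-identical. Isomer-level enumeration is streamed, never
  materialised.
* Tolerance boundaries are inclusive (|Δ| ≤ t); the bisection candidate
  window is padded by 1 % + 1 ns-scale epsilon before the exact test so
  no boundary hit is lost to float rounding.
* Reduced-bounds test spaces use `max_carbons` 4–10 (full four-level
  enumerations up to ~2·10⁵ records), chosen so the exhaustive oracles
  stay exact while the suite completes in a couple of minutes.

## Limitations

* The space is theoretical: enumeration says nothing about biological
  occurrence or chromatographic/ionisation behaviour, and the search
  engine ranks by mass error only.
* Only glycerolipids and glycerophospholipids are modelled; sphingolipids,
  sterols, cardiolipins and plasmalogens are out of scope, as are MS2
  fragments, isotope patterns and multiply charged ions.
* Double-bond stereochemistry is deliberately below the isomer level's
  resolution.
* The default sub-class table is a reconstruction (see the sensitivity
  discussion above), not a copy of any published table.
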