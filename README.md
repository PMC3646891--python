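# theolipid

Rule-based generation of the theoretical glycerolipid and
glycerophospholipid space for high-throughput MS1 lipidomics, with a
four-level identification hierarchy, shorthand nomenclature, exact
monoisotopic masses and a precursor-ion search engine.

## The problem

A single MS1 precursor mass (say 759.58 Da) cannot identify a lipid
structure: it constrains only the lipid class and the *totals* — summed
chain carbons and double bonds. Fragmentation resolves the individual
chains, specialist protocols resolve their *sn* positions and double-bond
positions. Reporting should match the evidence, so records here live at
four levels of structural resolution:

| level | example | resolved |
|---|---|---|
| Species | `PC 34:1` | class + total carbons : total double bonds |
| Fatty-acid scan species | `PC 16:0_18:1` | chain compositions, *sn* unknown |
| Sub-species | `PC 18:1/16:0` | chains assigned to *sn* slots |
| Isomer | `PC 18:1(9)/16:0` | double-bond positions (no stereochemistry) |

Rather than curating observed lipids, the package *enumerates every
theoretically feasible* record under community-agreed chain bounds
(2–30 carbons, odd chains allowed, first double bond at position ≥ 2,
subsequent double bonds spaced by multiples of 3), over sub-classes built
by a Cartesian cross of main classes (PC, PE, PS, PG, PI, PA, their lyso
partners, MG, DG, TG) with acyl/alkyl linkage multisets — 39 sub-classes
and 174 distinct chain types by default. Whole-space record counts are
computed combinatorially, so the 10⁷-scale sub-species and 10¹²-scale
isomer spaces are counted without being enumerated.

Neutral formulas come from condensation arithmetic: glycerol + head group
+ chains − one water per ester/ether/phosphodiester bond. For the diacyl-PC
species 34:1 that is C3H8O3 + C5H14NO4P + C16H32O2 + C18H34O2 − 3 H2O =
C42H82NO8P, monoisotopic mass 759.5778 Da.

## Worked example

```text
$ theolipid mass "PC 34:1"
PC 34:1	C42H82NO8P	759.5778

$ printf '759.58\n' > masses.txt
$ theolipid search masses.txt --tolerance 0.05da --adducts neutral
query_mz	adduct	species_name	subclass	category	theoretical_mass	delta_mDa	delta_ppm
759.5800	neutral	PC 34:1	diacylglycerophosphocholines	glycerophospholipids	759.5778	2.195	2.89
759.5800	neutral	PE 37:1	diacylglycerophosphoethanolamines	glycerophospholipids	759.5778	2.195	2.89
759.5800	neutral	PS dO-36:2	dialkylglycerophosphoserines	glycerophospholipids	759.5778	2.195	2.89
759.5800	neutral	PC dO-37:8	dialkylglycerophosphocholines	glycerophospholipids	759.5567	23.324	30.71
759.5800	neutral	PE dO-40:8	dialkylglycerophosphoethanolamines	glycerophospholipids	759.5567	23.324	30.71
759.5800	neutral	PC O-35:1	monoalkyl,monoacylglycerophosphocholines	glycerophospholipids	759.6142	-34.191	-45.01
759.5800	neutral	PE O-38:1	monoalkyl,monoacylglycerophosphoethanolamines	glycerophospholipids	759.6142	-34.191	-45.01
759.5800	neutral	PS O-35:2	monoalkyl,monoacylglycerophosphoserines	glycerophospholipids	759.5414	38.580	50.79
```

One mass, eight isobaric Species candidates within ±0.05 Da — the diacyl
`PC 34:1` (759.5778, off by 2.2 mDa) and the ether `PC O-35:1` (759.6142)
among them; at ±0.01 Da only the first three isobars survive. Hits are
sorted by absolute mass error; `--adducts "[M+H]+,[M-H]-"` searches
charged precursors, `--tolerance 5ppm` switches to relative tolerance, and
`--exclude-category/-class/-subclass` encode prior knowledge such as a
class-specific extraction.

Other commands: `subclasses` (the constructed table), `generate --level
species|fas|subspecies|isomer` (streamed TSV/CSV/JSON enumeration),
`count` (combinatorial per-sub-class counts), `parse` / `name` (shorthand
round-trip utilities). All of them accept `--config file.yaml` and dotted
overrides such as `--set rules.max_carbons=4`; everything is importable
from Python via `theolipid.*` as well.

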