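"""Molecular-formula arithmetic and condensation assembly of whole-lipid formulas.

A glycerolipid or glycerophospholipid is assembled from building blocks:
a glycerol backbone, an optional phosphorylated head group, and one radyl
chain per occupied *sn* slot.  Every ester, ether or phosphodiester
condensation releases exactly one water, so the neutral formula is

    glycerol + head + sum(chains) - (n_chains + [phospho head]) * H2O

where an acyl chain of ``c`` carbons and ``d`` double bonds contributes the
free fatty acid C_c H_{2c-2d} O2 and an alkyl chain the fatty alcohol
C_c H_{2c+2-2d} O.  Everything here is neutral; charge enters only through
adduct arithmetic in :mod:`theolipid.ms1_search`.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from typing import Iterable


class ChemError(ValueError):
    """Base class for chemistry-level errors."""


class UnknownElementError(ChemError):
    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unknown element symbol: {symbol!r}")


class NegativeCountError(ChemError):
    """Raised when formula subtraction would drop an element below zero."""


#: Monoisotopic masses in Da (most abundant isotope; C is exactly 12 by the
#: definition of the dalton).  CODATA/IUPAC values, >= 6 decimal places.
ELEMENT_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

#: Electron rest mass in Da; used by adduct deltas, never by neutral masses.
ELECTRON_MASS: float = 0.00054857990946

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping):
    """An immutable elemental composition: element symbol -> positive count.

    Supports element-wise ``+`` and ``-`` (subtraction below zero raises
    :class:`NegativeCountError`) and integer scaling.  Elements with a zero
    count are absent from the mapping.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kw:
            for sym, n in source.items():
                if not isinstance(n, int):
                    raise ChemError(f"element count must be an integer: {sym}={n!r}")
                merged[sym] = merged.get(sym, 0) + n
        for sym, n in merged.items():
            if n < 0:
                raise NegativeCountError(f"negative count for {sym}: {n}")
        object.__setattr__(self, "_counts", {s: n for s, n in sorted(merged.items()) if n})

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a plain formula string such as ``"C42H82NO8P"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ChemError(f"malformed formula {text!r} at position {pos}")
            sym, digits = match.groups()
            counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise ChemError(f"malformed formula {text!r} at position {pos}")
        return cls(counts)

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, sym: str) -> int:
        return self._counts[sym]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    # Arithmetic -------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        counts = dict(self._counts)
        for sym, n in other.items():
            counts[sym] = counts.get(sym, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        counts = dict(self._counts)
        for sym, n in other.items():
            counts[sym] = counts.get(sym, 0) - n
        return Formula(counts)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int):
            return NotImplemented
        if k < 0:
            raise NegativeCountError(f"cannot scale a formula by {k}")
        return Formula({s: n * k for s, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def hill(self) -> str:
        """Hill-order string: C first, H second, remaining symbols alphabetical."""
        parts = []
        for sym in ("C", "H"):
            n = self._counts.get(sym, 0)
            if n:
                parts.append(sym + (str(n) if n > 1 else ""))
        for sym in sorted(self._counts):
            if sym in ("C", "H"):
                continue
            n = self._counts[sym]
            parts.append(sym + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"


WATER = Formula(H=2, O=1)
GLYCEROL = Formula(C=3, H=8, O=3)
H2 = Formula(H=2)


def monoisotopic_mass(formula: Mapping[str, int],
                      masses: Mapping[str, float] = ELEMENT_MASSES) -> float:
    """Neutral monoisotopic mass in Da of an elemental composition."""
    total = 0.0
    for sym, n in formula.items():
        try:
            total += n * masses[sym]
        except KeyError:
            raise UnknownElementError(sym) from None
    return total


@dataclass(frozen=True)
class HeadGroup:
    """A head-group building block attached to the glycerol backbone.

    ``phospho`` marks a phosphodiester attachment, which costs one extra
    condensation water on top of the per-chain ones.
    """

    name: str
    formula: Formula
    phospho: bool


def _heads() -> dict[str, HeadGroup]:
    def h(name: str, f: str, phospho: bool = True) -> tuple[str, HeadGroup]:
        return name, HeadGroup(name, Formula.parse(f) if f else Formula(), phospho)

    return dict([
        h("phosphocholine", "C5H14NO4P"),
        h("phosphoethanolamine", "C2H8NO4P"),
        h("phosphoserine", "C3H8NO6P"),
        h("phosphoglycerol", "C3H9O6P"),
        h("phosphoinositol", "C6H13O9P"),
        h("phosphate", "H3O4P"),
        h("none", "", phospho=False),  # bare hydroxyl: glycerolipids
    ])


@dataclass(frozen=True)
class BuildingBlocks:
    """The condensation building blocks for lipid formula assembly."""

    backbone: Formula = GLYCEROL
    water: Formula = WATER
    heads: Mapping[str, HeadGroup] = field(default_factory=_heads)

    def head(self, name: str) -> HeadGroup:
        try:
            return self.heads[name]
        except KeyError:
            raise ChemError(
                f"unknown head group {name!r}; known: {', '.join(sorted(self.heads))}"
            ) from None

    def chain_formula(self, linkage: str, carbons: int, double_bonds: int) -> Formula:
        """Free building-block formula of one radyl chain.

        acyl  -> fatty acid    C_c H_{2c-2d} O2
        alkyl -> fatty alcohol C_c H_{2c+2-2d} O
        """
        if carbons < 1 or double_bonds < 0:
            raise ChemError(f"invalid chain {linkage} {carbons}:{double_bonds}")
        if linkage == "acyl":
            h = 2 * carbons - 2 * double_bonds
            o = 2
        elif linkage == "alkyl":
            h = 2 * carbons + 2 - 2 * double_bonds
            o = 1
        else:
            raise ChemError(f"unknown linkage {linkage!r}")
        if h < 0:
            raise ChemError(
                f"chain {carbons}:{double_bonds} is over-unsaturated for its length")
        return Formula(C=carbons, H=h, O=o)


DEFAULT_BUILDING_BLOCKS = BuildingBlocks()


def assemble_formula(head: HeadGroup,
                     n_acyl: int,
                     n_alkyl: int,
                     total_carbons: int,
                     total_double_bonds: int,
                     blocks: BuildingBlocks = DEFAULT_BUILDING_BLOCKS) -> Formula:
    """Whole-lipid formula from radyl totals.

    The composed formula depends only on the linkage counts and the summed
    carbons/double bonds, which is what makes Species-level records (totals
    only) chemically well defined.
    """
    n_chains = n_acyl + n_alkyl
    if total_carbons < 0 or total_double_bonds < 0 or n_chains < 0:
        raise ChemError("negative totals")
    chains_h = 2 * total_carbons - 2 * total_double_bonds + 2 * n_alkyl
    if n_chains and chains_h < 0:
        raise ChemError("over-unsaturated totals")
    chains = (Formula(C=total_carbons, H=chains_h, O=2 * n_acyl + n_alkyl)
              if n_chains else Formula())
    condensations = n_chains + (1 if head.phospho else 0)
    return blocks.backbone + head.formula + chains - condensations * blocks.water


def compose_lipid_formula(subclass, chains: Iterable,
                          blocks: BuildingBlocks = DEFAULT_BUILDING_BLOCKS) -> Formula:
    """Condense a sub-class head/backbone with explicit chains.

    ``subclass`` provides ``head`` (a :class:`HeadGroup`) and
    ``linkage_multiset``; ``chains`` provide ``linkage``, ``carbons`` and
    ``double_bonds``.  The chain linkage multiset must match the sub-class.
    """
    chains = list(chains)
    want = sorted(subclass.linkage_multiset)
    got = sorted(ch.linkage for ch in chains)
    if want != got:
        raise ChemError(
            f"linkage mismatch: sub-class requires {want}, chains provide {got}")
    total = blocks.backbone + subclass.head.formula
    for ch in chains:
        basic = getattr(ch, "basic_check", None)
        if basic is not None:
            basic()
        total = total + blocks.chain_formula(ch.linkage, ch.carbons, ch.double_bonds)
    condensations = len(chains) + (1 if subclass.head.phospho else 0)
    return total - condensations * blocks.water
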