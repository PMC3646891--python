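"""Enumeration and counting of theoretical fatty chains.

The chain space is bounded by a small set of community-style rules: carbon
range, odd-carbon allowance, a minimum double-bond count, and a double-bond
spacing convention.  Positions are Delta-style bond indices counted from the
carboxyl/linkage carbon (C1): the bond between C_k and C_{k+1} is position k,
so positions run from 2 (the first allowed) up to carbons - 1.

Two readings of the spacing convention are supported:

* ``"multiples"`` (default): the gap between consecutive double-bond
  positions is a positive multiple of ``db_position_step`` (3 by default) —
  methylene-interrupted bonds (gap 3) plus skipped repeats (6, 9, ...).
  This reproduces the common natural patterns 9; 9,12; 9,12,15; 5,8,11,14.
* ``"affine"``: the gap is ``db_position_step * n + 2`` for n >= 0
  (2, 5, 8, ... with the default step), the literal "3n+2" reading.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterator


class ChainRuleError(ValueError):
    """A chain or rule set violates the configured chemical bounds."""


SPACING_MODES = ("multiples", "affine")
LINKAGES = ("alkyl", "acyl")  # canonical slot order: alkyl before acyl


@dataclass(frozen=True)
class ChainRules:
    """Chemical bounds governing theoretical fatty-chain generation."""

    min_carbons: int = 2
    max_carbons: int = 30
    allow_odd_carbons: bool = True
    min_double_bonds: int = 0
    max_double_bonds: int | None = None  # optional cap; geometry is the default limit
    first_db_min_position: int = 2
    db_position_step: int = 3
    spacing_mode: str = "multiples"
    allow_terminal_db: bool = True  # permit a double bond at position carbons-1

    def __post_init__(self) -> None:
        if not (1 <= self.min_carbons <= self.max_carbons):
            raise ChainRuleError(
                f"carbon bounds must satisfy 1 <= min <= max, got "
                f"[{self.min_carbons}, {self.max_carbons}]")
        if self.first_db_min_position < 2:
            raise ChainRuleError("first_db_min_position must be >= 2")
        if self.db_position_step < 1:
            raise ChainRuleError("db_position_step must be >= 1")
        if self.min_double_bonds < 0:
            raise ChainRuleError("min_double_bonds must be >= 0")
        if self.max_double_bonds is not None and self.max_double_bonds < self.min_double_bonds:
            raise ChainRuleError("max_double_bonds below min_double_bonds")
        if self.spacing_mode not in SPACING_MODES:
            raise ChainRuleError(
                f"spacing_mode must be one of {SPACING_MODES}, got {self.spacing_mode!r}")

    # -- spacing helpers ------------------------------------------------
    def last_position(self, carbons: int) -> int:
        return carbons - 1 if self.allow_terminal_db else carbons - 2

    def min_gap(self) -> int:
        return self.db_position_step if self.spacing_mode == "multiples" else 2

    def gap_allowed(self, gap: int) -> bool:
        if self.spacing_mode == "multiples":
            return gap > 0 and gap % self.db_position_step == 0
        return gap >= 2 and (gap - 2) % self.db_position_step == 0

    def carbons_allowed(self, carbons: int) -> bool:
        return (self.min_carbons <= carbons <= self.max_carbons
                and (self.allow_odd_carbons or carbons % 2 == 0))

    def replace(self, **kw) -> "ChainRules":
        return replace(self, **kw)


DEFAULT_RULES = ChainRules()


@dataclass(frozen=True)
class Chain:
    """One radyl chain: linkage, carbon count, double bonds, optional positions."""

    linkage: str
    carbons: int
    double_bonds: int
    positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.positions is not None:
            object.__setattr__(self, "positions", tuple(self.positions))
        self.basic_check()

    def basic_check(self) -> None:
        """Rule-independent structural sanity (used by formula assembly)."""
        if self.linkage not in LINKAGES:
            raise ChainRuleError(f"unknown linkage {self.linkage!r}")
        if self.carbons < 1:
            raise ChainRuleError(f"carbons must be >= 1, got {self.carbons}")
        if self.double_bonds < 0:
            raise ChainRuleError("double_bonds must be >= 0")
        if 2 * self.carbons - 2 * self.double_bonds < 0:
            raise ChainRuleError(
                f"chain {self.carbons}:{self.double_bonds} is over-unsaturated")
        if self.positions is not None:
            if len(self.positions) != self.double_bonds:
                raise ChainRuleError(
                    f"{len(self.positions)} positions for {self.double_bonds} double bonds")
            if list(self.positions) != sorted(set(self.positions)):
                raise ChainRuleError("positions must be strictly increasing")
            if self.positions and (self.positions[0] < 1
                                   or self.positions[-1] > self.carbons - 1):
                raise ChainRuleError("positions outside the chain")

    def check(self, rules: ChainRules) -> None:
        """Full validation against a rule set."""
        if not rules.carbons_allowed(self.carbons):
            raise ChainRuleError(
                f"carbons {self.carbons} outside configured bounds or parity")
        if self.double_bonds < rules.min_double_bonds:
            raise ChainRuleError("too few double bonds")
        if self.double_bonds > max_double_bonds(self.carbons, rules):
            raise ChainRuleError(
                f"{self.double_bonds} double bonds do not fit in {self.carbons} carbons")
        if self.positions is not None and self.double_bonds:
            if self.positions[0] < rules.first_db_min_position:
                raise ChainRuleError(
                    f"first double bond below position {rules.first_db_min_position}")
            if self.positions[-1] > rules.last_position(self.carbons):
                raise ChainRuleError("double bond beyond the last allowed position")
            for a, b in zip(self.positions, self.positions[1:]):
                if not rules.gap_allowed(b - a):
                    raise ChainRuleError(
                        f"gap {b - a} between positions {a} and {b} violates spacing")

    def is_valid(self, rules: ChainRules) -> bool:
        try:
            self.check(rules)
        except ChainRuleError:
            return False
        return True

    def without_positions(self) -> "Chain":
        return Chain(self.linkage, self.carbons, self.double_bonds)

    def shorthand(self) -> str:
        prefix = "O-" if self.linkage == "alkyl" else ""
        s = f"{prefix}{self.carbons}:{self.double_bonds}"
        if self.positions:
            s += "(" + ",".join(str(p) for p in self.positions) + ")"
        return s


def max_double_bonds(carbons: int, rules: ChainRules = DEFAULT_RULES) -> int:
    """Largest double-bond count for which a valid position set exists."""
    if not (rules.min_carbons <= carbons <= rules.max_carbons):
        raise ChainRuleError(
            f"carbons {carbons} outside [{rules.min_carbons}, {rules.max_carbons}]")
    last = rules.last_position(carbons)
    if last < rules.first_db_min_position:
        d = 0
    else:
        # densest packing: uniform minimal gaps starting at the first position
        d = (last - rules.first_db_min_position) // rules.min_gap() + 1
    if rules.max_double_bonds is not None:
        d = min(d, rules.max_double_bonds)
    return d


def enumerate_db_position_sets(carbons: int, n_db: int,
                               rules: ChainRules = DEFAULT_RULES) -> list[tuple[int, ...]]:
    """All valid sorted double-bond position sets, in lexicographic order.

    Infeasible inputs yield an empty list; ``n_db == 0`` yields one empty set.
    """
    if n_db < 0:
        raise ChainRuleError("n_db must be >= 0")
    if n_db == 0:
        return [()]
    last = rules.last_position(carbons)
    out: list[tuple[int, ...]] = []
    prefix: list[int] = []

    def extend(start: int, remaining: int) -> None:
        # leave room for the densest possible tail
        limit = last - (remaining - 1) * rules.min_gap()
        for p in range(start, limit + 1):
            if prefix and not rules.gap_allowed(p - prefix[-1]):
                continue
            prefix.append(p)
            if remaining == 1:
                out.append(tuple(prefix))
            else:
                extend(p + rules.min_gap(), remaining - 1)
            prefix.pop()

    extend(rules.first_db_min_position, n_db)
    return out


@lru_cache(maxsize=None)
def count_db_position_sets(carbons: int, n_db: int,
                           rules: ChainRules = DEFAULT_RULES) -> int:
    """Combinatorial twin of the enumerator: equal to its length for all inputs."""
    if n_db < 0:
        raise ChainRuleError("n_db must be >= 0")
    if n_db == 0:
        return 1
    last = rules.last_position(carbons)
    memo: dict[tuple[int, int], int] = {}

    def tail(prev: int, remaining: int) -> int:
        if remaining == 0:
            return 1
        key = (prev, remaining)
        if key not in memo:
            total = 0
            limit = last - (remaining - 1) * rules.min_gap()
            for p in range(prev + rules.min_gap(), limit + 1):
                if rules.gap_allowed(p - prev):
                    total += tail(p, remaining - 1)
            memo[key] = total
        return memo[key]

    return sum(tail(p, n_db - 1)
               for p in range(rules.first_db_min_position,
                              last - (n_db - 1) * rules.min_gap() + 1))


@lru_cache(maxsize=None)
def enumerate_chain_types(rules: ChainRules = DEFAULT_RULES) -> tuple[tuple[int, int], ...]:
    """All (carbons, double_bonds) pairs admitted by the rules, sorted."""
    types = []
    for c in range(rules.min_carbons, rules.max_carbons + 1):
        if not rules.carbons_allowed(c):
            continue
        for d in range(rules.min_double_bonds, max_double_bonds(c, rules) + 1):
            types.append((c, d))
    return tuple(types)


@lru_cache(maxsize=None)
def positioned_chain_type_count(rules: ChainRules = DEFAULT_RULES) -> int:
    """Number of (carbons, double_bonds, position-set) triples — the per-slot
    alphabet size for Isomer-level counting."""
    return sum(count_db_position_sets(c, d, rules)
               for c, d in enumerate_chain_types(rules))


def iter_positioned_chains(linkage: str,
                           rules: ChainRules = DEFAULT_RULES) -> Iterator[Chain]:
    for c, d in enumerate_chain_types(rules):
        for pos in enumerate_db_position_sets(c, d, rules):
            yield Chain(linkage, c, d, pos)
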