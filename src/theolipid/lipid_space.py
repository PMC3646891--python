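"""The four-level theoretical lipid space.

Lipid records live at four levels of MS structural resolution:

* ``Species`` — class plus total carbons/double bonds (one MS1 precursor
  mass), e.g. ``PC 34:1``;
* ``FasSpecies`` — the multiset of radyl chains without *sn* assignment
  (fatty-acid scan), e.g. ``PC 16:0_18:1``;
* ``SubSpecies`` — chains assigned to *sn* slots, e.g. ``PC 18:1/16:0``;
* ``Isomer`` — double-bond positions fixed on every unsaturated chain,
  e.g. ``PC 18:1(9)/16:0``.  No stereochemistry.

Sub-classes are built by a Cartesian cross of main classes with linkage
multisets (acyl/alkyl); linkage-position variants are collapsed into a
single sub-class, and the alkyl chain of a mixed-linkage lipid is
canonically placed at *sn1*.  Monoradyl glycerophospholipids (lyso classes)
carry the field-standard ``L`` prefix (LPC, LPE, ...) so that every
canonical name identifies its record unambiguously.
"""

from __future__ import annotations

import enum
import itertools
import math
import re
from collections import Counter
from dataclasses import dataclass
from functools import cached_property, lru_cache
from typing import Iterable, Iterator, Mapping

from .chem_core import (BuildingBlocks, DEFAULT_BUILDING_BLOCKS, Formula,
                        HeadGroup, assemble_formula, compose_lipid_formula,
                        monoisotopic_mass)
from .chain_rules import (Chain, ChainRules, DEFAULT_RULES,
                          enumerate_chain_types, enumerate_db_position_sets,
                          positioned_chain_type_count)


class LipidSpaceError(ValueError):
    """Invalid sub-class, record or hierarchy operation."""


class NameParseError(LipidSpaceError):
    """A shorthand name violates the grammar; carries the first bad position."""

    def __init__(self, text: str, position: int, reason: str):
        self.text = text
        self.position = position
        self.reason = reason
        super().__init__(f"cannot parse {text!r} at position {position}: {reason}")


class Level(str, enum.Enum):
    Species = "species"
    FasSpecies = "fas"
    SubSpecies = "subspecies"
    Isomer = "isomer"


GLYCEROPHOSPHOLIPIDS = "glycerophospholipids"
GLYCEROLIPIDS = "glycerolipids"

_COUNT_PREFIX = {1: "mono", 2: "di", 3: "tri"}
_ETHER_PREFIX = {0: "", 1: "O-", 2: "dO-", 3: "tO-"}


@dataclass(frozen=True)
class MainClassDef:
    """A lipid main class: shorthand code, category, head group, slot count."""

    code: str
    category: str
    head_group: str  # key into BuildingBlocks.heads
    slot_count: int
    stem: str  # tail of the sub-class display name


def _default_main_classes() -> dict[str, MainClassDef]:
    gp = [("PC", "phosphocholine", "glycerophosphocholines"),
          ("PE", "phosphoethanolamine", "glycerophosphoethanolamines"),
          ("PS", "phosphoserine", "glycerophosphoserines"),
          ("PG", "phosphoglycerol", "glycerophosphoglycerols"),
          ("PI", "phosphoinositol", "glycerophosphoinositols"),
          ("PA", "phosphate", "glycerophosphates")]
    classes: dict[str, MainClassDef] = {}
    for code, head, stem in gp:
        classes[code] = MainClassDef(code, GLYCEROPHOSPHOLIPIDS, head, 2, stem)
    for code, head, stem in gp:  # lyso (monoradyl) partners
        classes["L" + code] = MainClassDef("L" + code, GLYCEROPHOSPHOLIPIDS, head, 1, stem)
    classes["MG"] = MainClassDef("MG", GLYCEROLIPIDS, "none", 1, "glycerols")
    classes["DG"] = MainClassDef("DG", GLYCEROLIPIDS, "none", 2, "glycerols")
    classes["TG"] = MainClassDef("TG", GLYCEROLIPIDS, "none", 3, "glycerols")
    return classes


DEFAULT_MAIN_CLASSES: Mapping[str, MainClassDef] = _default_main_classes()


@dataclass(frozen=True)
class SubClassDef:
    """One lipid sub-class: main class crossed with a linkage multiset.

    ``linkage_multiset`` is the canonical slot order: alkyl slots first.
    """

    category: str
    main_class: str
    linkage_multiset: tuple[str, ...]
    display_name: str
    head: HeadGroup

    @property
    def slot_count(self) -> int:
        return len(self.linkage_multiset)

    @property
    def n_alkyl(self) -> int:
        return sum(1 for lk in self.linkage_multiset if lk == "alkyl")

    @property
    def n_acyl(self) -> int:
        return self.slot_count - self.n_alkyl

    @property
    def is_monoradyl_gp(self) -> bool:
        return self.category == GLYCEROPHOSPHOLIPIDS and self.slot_count == 1


def _display_name(mc: MainClassDef, multiset: tuple[str, ...]) -> str:
    n_alkyl = multiset.count("alkyl")
    n_acyl = multiset.count("acyl")
    parts = []
    if n_alkyl:
        parts.append(_COUNT_PREFIX[n_alkyl] + "alkyl")
    if n_acyl:
        parts.append(_COUNT_PREFIX[n_acyl] + "acyl")
    return ",".join(parts) + mc.stem


_subclass_cache: dict = {}


def build_subclasses(config=None) -> list[SubClassDef]:
    """One sub-class per (main class, linkage multiset), in deterministic order.

    ``config`` may supply ``main_classes`` and ``building_blocks``; defaults
    reproduce the embedded tables.
    """
    main_classes = getattr(config, "main_classes", None) or DEFAULT_MAIN_CLASSES
    blocks = getattr(config, "building_blocks", None) or DEFAULT_BUILDING_BLOCKS
    cache_key = (tuple(main_classes.items()),
                 tuple(sorted(blocks.heads.items())), blocks.backbone)
    cached = _subclass_cache.get(cache_key)
    if cached is not None:
        return list(cached)
    out: list[SubClassDef] = []
    for code, mc in main_classes.items():
        if code != mc.code:
            raise LipidSpaceError(f"main-class key {code!r} does not match code {mc.code!r}")
        if not (1 <= mc.slot_count <= 3):
            raise LipidSpaceError(f"slot count for {code} must be in 1..3")
        if mc.category == GLYCEROPHOSPHOLIPIDS and mc.slot_count > 2:
            raise LipidSpaceError(f"glycerophospholipid {code} cannot have >2 slots")
        head = blocks.head(mc.head_group)
        for n_alkyl in range(mc.slot_count + 1):
            multiset = ("alkyl",) * n_alkyl + ("acyl",) * (mc.slot_count - n_alkyl)
            out.append(SubClassDef(mc.category, code, multiset,
                                   _display_name(mc, multiset), head))
    _subclass_cache[cache_key] = tuple(out)
    return out


def find_subclass(subclasses: Iterable[SubClassDef], main_class: str,
                  n_alkyl: int) -> SubClassDef:
    for sc in subclasses:
        if sc.main_class == main_class and sc.n_alkyl == n_alkyl:
            return sc
    raise LipidSpaceError(
        f"no sub-class of {main_class} with {n_alkyl} alkyl chain(s)")


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class LipidRecord:
    """A record at one of the four hierarchy levels.

    ``chains`` is ``None`` at Species level; at FasSpecies level it is the
    canonically ordered multiset; at SubSpecies/Isomer level it is the *sn*
    slot order (alkyl slots first by canonicalization).
    """

    level: Level
    subclass: SubClassDef
    total_carbons: int
    total_double_bonds: int
    chains: tuple[Chain, ...] | None = None

    def __post_init__(self) -> None:
        if (self.chains is None) != (self.level is Level.Species):
            raise LipidSpaceError("chains are required below Species level only")
        if self.chains is not None:
            if sorted(ch.linkage for ch in self.chains) != \
                    sorted(self.subclass.linkage_multiset):
                raise LipidSpaceError("chain linkages do not match the sub-class")
            if (sum(ch.carbons for ch in self.chains) != self.total_carbons
                    or sum(ch.double_bonds for ch in self.chains) != self.total_double_bonds):
                raise LipidSpaceError("chain sums do not match record totals")

    @cached_property
    def formula(self) -> Formula:
        if self.chains is None:
            return assemble_formula(self.subclass.head, self.subclass.n_acyl,
                                    self.subclass.n_alkyl, self.total_carbons,
                                    self.total_double_bonds)
        return compose_lipid_formula(self.subclass, self.chains)

    @cached_property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @cached_property
    def canonical_name(self) -> str:
        return format_name(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.level.value} {format_name(self)}>"


def _canonical_fas_order(chains: Iterable[Chain]) -> tuple[Chain, ...]:
    return tuple(sorted(chains,
                        key=lambda ch: (ch.linkage != "alkyl", ch.carbons,
                                        ch.double_bonds)))


def species_record(subclass: SubClassDef, total_carbons: int,
                   total_double_bonds: int) -> LipidRecord:
    return LipidRecord(Level.Species, subclass, total_carbons, total_double_bonds)


def fas_record(subclass: SubClassDef, chains: Iterable[Chain]) -> LipidRecord:
    chains = _canonical_fas_order(ch.without_positions() for ch in chains)
    return LipidRecord(Level.FasSpecies, subclass,
                       sum(c.carbons for c in chains),
                       sum(c.double_bonds for c in chains), chains)


def _ordered_record(level: Level, subclass: SubClassDef,
                    chains: tuple[Chain, ...]) -> LipidRecord:
    if tuple(ch.linkage for ch in chains) != subclass.linkage_multiset:
        raise LipidSpaceError(
            "slot linkage order must match the canonical multiset (alkyl first)")
    return LipidRecord(level, subclass, sum(c.carbons for c in chains),
                       sum(c.double_bonds for c in chains), tuple(chains))


def subspecies_record(subclass: SubClassDef, chains: Iterable[Chain]) -> LipidRecord:
    return _ordered_record(Level.SubSpecies, subclass,
                           tuple(ch.without_positions() for ch in chains))


def isomer_record(subclass: SubClassDef, chains: Iterable[Chain]) -> LipidRecord:
    normalized = []
    for ch in chains:
        if ch.double_bonds and ch.positions is None:
            raise LipidSpaceError(
                f"isomer chain {ch.shorthand()} lacks double-bond positions")
        if ch.positions is None:  # saturated chain: canonical empty position set
            ch = Chain(ch.linkage, ch.carbons, ch.double_bonds, ())
        normalized.append(ch)
    return _ordered_record(Level.Isomer, subclass, tuple(normalized))


# ---------------------------------------------------------------------------
# Enumeration and counting


@lru_cache(maxsize=None)
def _achievable_totals(slot_count: int,
                       rules: ChainRules) -> tuple[tuple[int, int], ...]:
    types = enumerate_chain_types(rules)
    sums = {(0, 0)}
    for _ in range(slot_count):
        sums = {(C + c, D + d) for (C, D) in sums for (c, d) in types}
    return tuple(sorted(sums))


def is_realizable(subclass: SubClassDef, total_carbons: int,
                  total_double_bonds: int, rules: ChainRules = DEFAULT_RULES) -> bool:
    return (total_carbons, total_double_bonds) in set(
        _achievable_totals(subclass.slot_count, rules))


def enumerate_species(subclass: SubClassDef,
                      rules: ChainRules = DEFAULT_RULES) -> list[LipidRecord]:
    """All realizable (total carbons, total double bonds) Species records."""
    return [species_record(subclass, C, D)
            for C, D in _achievable_totals(subclass.slot_count, rules)]


def _linkage_groups(subclass: SubClassDef) -> list[tuple[str, int]]:
    counts = Counter(subclass.linkage_multiset)
    return [(lk, counts[lk]) for lk in ("alkyl", "acyl") if counts[lk]]


def iter_fas(subclass: SubClassDef,
             rules: ChainRules = DEFAULT_RULES) -> Iterator[LipidRecord]:
    """Direct enumeration of the FasSpecies level (per-linkage chain multisets)."""
    types = enumerate_chain_types(rules)
    groups = []
    for linkage, m in _linkage_groups(subclass):
        groups.append([tuple(Chain(linkage, c, d) for c, d in combo)
                       for combo in itertools.combinations_with_replacement(types, m)])
    for parts in itertools.product(*groups):
        chains = tuple(itertools.chain.from_iterable(parts))
        yield LipidRecord(Level.FasSpecies, subclass,
                          sum(c.carbons for c in chains),
                          sum(c.double_bonds for c in chains),
                          _canonical_fas_order(chains))


def iter_subspecies(subclass: SubClassDef,
                    rules: ChainRules = DEFAULT_RULES) -> Iterator[LipidRecord]:
    """Direct enumeration of SubSpecies: each canonical slot ranges over all
    chain types independently (alkyl slots are pinned to the front)."""
    types = enumerate_chain_types(rules)
    for combo in itertools.product(types, repeat=subclass.slot_count):
        chains = tuple(Chain(lk, c, d) for lk, (c, d)
                       in zip(subclass.linkage_multiset, combo))
        yield _ordered_record(Level.SubSpecies, subclass, chains)


def iter_isomers(subclass: SubClassDef,
                 rules: ChainRules = DEFAULT_RULES) -> Iterator[LipidRecord]:
    for ss in iter_subspecies(subclass, rules):
        yield from subspecies_children(ss, rules)


def iter_records(subclass: SubClassDef, level: Level,
                 rules: ChainRules = DEFAULT_RULES) -> Iterator[LipidRecord]:
    if level is Level.Species:
        return iter(enumerate_species(subclass, rules))
    if level is Level.FasSpecies:
        return iter_fas(subclass, rules)
    if level is Level.SubSpecies:
        return iter_subspecies(subclass, rules)
    if level is Level.Isomer:
        return iter_isomers(subclass, rules)
    raise LipidSpaceError(f"unknown level {level!r}")


def species_children(species: LipidRecord,
                     rules: ChainRules = DEFAULT_RULES) -> list[LipidRecord]:
    """All FasSpecies whose chain sums match the Species totals."""
    if species.level is not Level.Species:
        raise LipidSpaceError("species_children requires a Species record")
    out = []
    for fas in iter_fas(species.subclass, rules):
        if (fas.total_carbons == species.total_carbons
                and fas.total_double_bonds == species.total_double_bonds):
            out.append(fas)
    return out


def fas_children(fas: LipidRecord,
                 rules: ChainRules = DEFAULT_RULES) -> list[LipidRecord]:
    """All distinct canonical slot assignments of the FAS chain multiset."""
    if fas.level is not Level.FasSpecies:
        raise LipidSpaceError("fas_children requires a FasSpecies record")
    by_linkage: dict[str, list[Chain]] = {"alkyl": [], "acyl": []}
    for ch in fas.chains:
        by_linkage[ch.linkage].append(ch)
    group_orders = []
    for linkage, m in _linkage_groups(fas.subclass):
        perms = sorted(set(itertools.permutations(by_linkage[linkage])),
                       key=lambda p: tuple((c.carbons, c.double_bonds) for c in p))
        group_orders.append(perms)
    out = []
    for parts in itertools.product(*group_orders):
        chains = tuple(itertools.chain.from_iterable(parts))
        out.append(_ordered_record(Level.SubSpecies, fas.subclass, chains))
    return sorted(out, key=lambda r: tuple((c.carbons, c.double_bonds)
                                           for c in r.chains))


def subspecies_children(subspecies: LipidRecord,
                        rules: ChainRules = DEFAULT_RULES) -> list[LipidRecord]:
    """Cartesian product of per-chain double-bond position sets."""
    if subspecies.level is not Level.SubSpecies:
        raise LipidSpaceError("subspecies_children requires a SubSpecies record")
    per_chain = [enumerate_db_position_sets(ch.carbons, ch.double_bonds, rules)
                 for ch in subspecies.chains]
    out = []
    for combo in itertools.product(*per_chain):
        chains = tuple(Chain(ch.linkage, ch.carbons, ch.double_bonds, pos)
                       for ch, pos in zip(subspecies.chains, combo))
        out.append(_ordered_record(Level.Isomer, subspecies.subclass, chains))
    return out


def children(record: LipidRecord,
             rules: ChainRules = DEFAULT_RULES) -> list[LipidRecord]:
    if record.level is Level.Species:
        return species_children(record, rules)
    if record.level is Level.FasSpecies:
        return fas_children(record, rules)
    if record.level is Level.SubSpecies:
        return subspecies_children(record, rules)
    raise LipidSpaceError("Isomer records have no children")


def parent(record: LipidRecord) -> LipidRecord:
    """One step up the hierarchy; Species records have no parent."""
    if record.level is Level.Isomer:
        return subspecies_record(record.subclass, record.chains)
    if record.level is Level.SubSpecies:
        return fas_record(record.subclass, record.chains)
    if record.level is Level.FasSpecies:
        return species_record(record.subclass, record.total_carbons,
                              record.total_double_bonds)
    raise LipidSpaceError("a Species record has no parent within the record space")


def count_records(subclass: SubClassDef, level: Level,
                  rules: ChainRules = DEFAULT_RULES) -> int:
    """Combinatorial twin of the level enumerations (no enumeration involved
    above Species level, so it scales to the full default bounds)."""
    n_types = len(enumerate_chain_types(rules))
    k = subclass.slot_count
    if level is Level.Species:
        return len(_achievable_totals(k, rules))
    if level is Level.FasSpecies:
        return math.prod(math.comb(n_types + m - 1, m)
                         for _, m in _linkage_groups(subclass))
    if level is Level.SubSpecies:
        return n_types ** k
    if level is Level.Isomer:
        return positioned_chain_type_count(rules) ** k
    raise LipidSpaceError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# Shorthand nomenclature

_CHAIN_RE = re.compile(r"(O-)?(\d+):(\d+)(?:\((\d+(?:,\d+)*)\))?")
_SPECIES_RE = re.compile(r"(O-|dO-|tO-)?(\d+):(\d+)")


def format_name(record: LipidRecord) -> str:
    """Canonical shorthand name; the inverse of :func:`parse_name`."""
    sc = record.subclass
    code = sc.main_class
    if record.level is Level.Species:
        prefix = _ETHER_PREFIX[sc.n_alkyl]
        return f"{code} {prefix}{record.total_carbons}:{record.total_double_bonds}"
    if record.level is Level.FasSpecies:
        return f"{code} " + "_".join(ch.shorthand() for ch in record.chains)
    tokens = [ch.shorthand() for ch in record.chains]
    if sc.is_monoradyl_gp:
        tokens.append("0:0")
    return f"{code} " + "/".join(tokens)


def _parse_chain(token: str, offset: int, text: str,
                 allow_positions: bool) -> Chain:
    m = _CHAIN_RE.fullmatch(token)
    if not m:
        raise NameParseError(text, offset, f"malformed chain {token!r}")
    linkage = "alkyl" if m.group(1) else "acyl"
    carbons, double_bonds = int(m.group(2)), int(m.group(3))
    positions = None
    if m.group(4) is not None:
        if not allow_positions:
            raise NameParseError(text, offset + m.start(4),
                                 "double-bond positions not allowed at this level")
        positions = tuple(int(p) for p in m.group(4).split(","))
    try:
        return Chain(linkage, carbons, double_bonds, positions)
    except Exception as exc:
        raise NameParseError(text, offset, str(exc)) from None


def _check_chain(ch: Chain, rules: ChainRules, offset: int, text: str) -> None:
    try:
        ch.check(rules)
    except Exception as exc:
        raise NameParseError(text, offset, str(exc)) from None


def parse_name(text: str, config=None) -> LipidRecord:
    """Parse a canonical shorthand name back into its record.

    Names the grammar cannot distinguish parse to the least-resolved level:
    the bare single-chain name of a one-slot sub-class is its Species, and a
    fully saturated SubSpecies name is returned at SubSpecies (not Isomer)
    level.  Non-canonical forms (unsorted FAS chains, an alkyl chain outside
    *sn1*) are rejected so that format and parse are exact mutual inverses.
    """
    main_classes = getattr(config, "main_classes", None) or DEFAULT_MAIN_CLASSES
    rules = getattr(config, "rules", None) or DEFAULT_RULES
    subclasses = build_subclasses(config)

    sep = text.find(" ")
    if sep < 1:
        raise NameParseError(text, 0, "expected '<CLASS> <body>'")
    code, body = text[:sep], text[sep + 1:]
    if code not in main_classes:
        raise NameParseError(text, 0, f"unknown class code {code!r}")
    if not body or body != body.strip():
        raise NameParseError(text, sep + 1, "empty or padded name body")
    offset = sep + 1
    mc = main_classes[code]

    def subclass_for(n_alkyl: int) -> SubClassDef:
        try:
            return find_subclass(subclasses, code, n_alkyl)
        except LipidSpaceError as exc:
            raise NameParseError(text, offset, str(exc)) from None

    if "/" in body:
        tokens = body.split("/")
        token_offsets = []
        pos = offset
        for tok in tokens:
            token_offsets.append(pos)
            pos += len(tok) + 1
        empty = [i for i, tok in enumerate(tokens) if tok == "0:0"]
        if empty:
            if mc.category != GLYCEROPHOSPHOLIPIDS or mc.slot_count != 1:
                raise NameParseError(text, token_offsets[empty[0]],
                                     "'0:0' slot is only valid for lyso classes")
            if len(tokens) != 2 or empty != [1]:
                raise NameParseError(text, token_offsets[empty[0]],
                                     "a lyso name is '<chain>/0:0'")
            tokens = tokens[:1]
        chains = [_parse_chain(tok, off, text, allow_positions=True)
                  for tok, off in zip(tokens, token_offsets)]
        if len(chains) != mc.slot_count:
            raise NameParseError(text, offset,
                                 f"{code} requires {mc.slot_count} slot(s)")
        n_alkyl = sum(1 for ch in chains if ch.linkage == "alkyl")
        sc = subclass_for(n_alkyl)
        if tuple(ch.linkage for ch in chains) != sc.linkage_multiset:
            bad = next(i for i, ch in enumerate(chains)
                       if ch.linkage != sc.linkage_multiset[i])
            raise NameParseError(text, token_offsets[bad],
                                 "alkyl chains must occupy the leading sn slots")
        has_positions = any(ch.positions is not None for ch in chains)
        if has_positions:
            missing = [i for i, ch in enumerate(chains)
                       if ch.double_bonds and ch.positions is None]
            if missing:
                raise NameParseError(text, token_offsets[missing[0]],
                                     "isomer names require positions on every "
                                     "unsaturated chain")
            for ch, off in zip(chains, token_offsets):
                _check_chain(ch, rules, off, text)
            return isomer_record(sc, chains)
        for ch, off in zip(chains, token_offsets):
            _check_chain(ch, rules, off, text)
        return subspecies_record(sc, chains)

    if "_" in body:
        tokens = body.split("_")
        token_offsets = []
        pos = offset
        for tok in tokens:
            token_offsets.append(pos)
            pos += len(tok) + 1
        chains = [_parse_chain(tok, off, text, allow_positions=False)
                  for tok, off in zip(tokens, token_offsets)]
        if len(chains) != mc.slot_count:
            raise NameParseError(text, offset,
                                 f"{code} requires {mc.slot_count} chain(s)")
        n_alkyl = sum(1 for ch in chains if ch.linkage == "alkyl")
        sc = subclass_for(n_alkyl)
        if tuple(chains) != _canonical_fas_order(chains):
            raise NameParseError(text, offset,
                                 "FAS chains must be in canonical order "
                                 "(alkyl first, then by carbons:double bonds)")
        for ch, off in zip(chains, token_offsets):
            _check_chain(ch, rules, off, text)
        return fas_record(sc, chains)

    # A bare chain with positions is the Isomer of a one-slot glycerolipid
    # (lyso classes carry an explicit "/0:0" slot instead).
    if "(" in body:
        if mc.slot_count != 1 or mc.category != GLYCEROLIPIDS:
            raise NameParseError(text, offset,
                                 "double-bond positions require slot-resolved names")
        ch = _parse_chain(body, offset, text, allow_positions=True)
        if ch.double_bonds and ch.positions is None:
            raise NameParseError(text, offset, "missing double-bond positions")
        _check_chain(ch, rules, offset, text)
        return isomer_record(subclass_for(1 if ch.linkage == "alkyl" else 0), [ch])

    # Species (or the degenerate bare single-chain form of a 1-slot class)
    m = _SPECIES_RE.fullmatch(body)
    if not m:
        raise NameParseError(text, offset,
                             "expected '<C>:<D>' totals with optional ether prefix")
    n_alkyl = {None: 0, "O-": 1, "dO-": 2, "tO-": 3}[m.group(1)]
    if n_alkyl > mc.slot_count:
        raise NameParseError(text, offset,
                             f"{code} has only {mc.slot_count} slot(s)")
    sc = subclass_for(n_alkyl)
    total_c, total_d = int(m.group(2)), int(m.group(3))
    if not is_realizable(sc, total_c, total_d, rules):
        raise NameParseError(text, offset,
                             f"totals {total_c}:{total_d} are not realizable by "
                             f"valid chains of {sc.display_name}")
    return species_record(sc, total_c, total_d)


# ---------------------------------------------------------------------------
# Whole-space totals and the reconstruction sensitivity report


def generation_totals(subclasses: Iterable[SubClassDef],
                      rules: ChainRules = DEFAULT_RULES) -> dict[str, int]:
    """Species/FAS/SubSpecies/Isomer totals over a sub-class table, computed
    purely combinatorially."""
    subclasses = list(subclasses)
    return {
        "n_subclasses": len(subclasses),
        "chain_types": len(enumerate_chain_types(rules)),
        "species": sum(count_records(sc, Level.Species, rules) for sc in subclasses),
        "fas": sum(count_records(sc, Level.FasSpecies, rules) for sc in subclasses),
        "subspecies": sum(count_records(sc, Level.SubSpecies, rules) for sc in subclasses),
        "isomers": sum(count_records(sc, Level.Isomer, rules) for sc in subclasses),
    }


def generation_report(config=None,
                      rules: ChainRules = DEFAULT_RULES) -> dict:
    """Totals for the default sub-class reconstruction together with their
    sensitivity to the double-bond spacing reading and to plausible variants
    of the sub-class table (the exact published table is not recoverable from
    the generation rules alone)."""
    base = build_subclasses(config)
    variants = {
        "default": base,
        "no_trialkyl_tg": [sc for sc in base
                           if not (sc.main_class == "TG" and sc.n_alkyl == 3)],
        "acyl_only_glycerolipids": [sc for sc in base
                                    if sc.category != GLYCEROLIPIDS or sc.n_alkyl == 0],
    }
    spacings = {
        "multiples_of_3": rules,
        "literal_3n_plus_2": rules.replace(spacing_mode="affine"),
    }
    return {vname: {sname: generation_totals(subs, srules)
                    for sname, srules in spacings.items()}
            for vname, subs in variants.items()}
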