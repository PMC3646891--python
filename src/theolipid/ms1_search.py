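"""MS1 precursor-ion search against the theoretical Species space.

Each query m/z is first converted to a neutral mass under every selected
adduct (``neutral = |z| * mz - delta``, where the delta already includes the
electron mass), then matched against Species-level records within a
symmetric tolerance given either in Da or in ppm of the theoretical mass.
Whole categories, main classes or sub-classes can be excluded to encode
a-priori knowledge of the sample. The Species table is generated on the fly
from the chain rules and sub-class table; only singly charged (or neutral)
adducts are supported.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from .chem_core import ELECTRON_MASS, ELEMENT_MASSES
from .chain_rules import ChainRules, DEFAULT_RULES
from .lipid_space import (Level, LipidRecord, SubClassDef, build_subclasses,
                          enumerate_species)


class SearchError(ValueError):
    """Invalid search parameters."""


@dataclass(frozen=True)
class AdductDef:
    """An ion-forming adduct: name, signed charge and neutral->ion mass delta.

    ``mass_delta`` is defined by ``mz * |charge| = neutral_mass + mass_delta``
    and includes the electron-mass correction.  The ``neutral`` pseudo-adduct
    (charge 0, delta 0) searches uncharged masses directly.
    """

    name: str
    charge: int
    mass_delta: float

    def __post_init__(self) -> None:
        if self.charge == 0 and self.mass_delta != 0.0:
            raise SearchError("a neutral adduct must have zero mass delta")
        if abs(self.charge) > 1:
            raise SearchError("multiply charged adducts are out of scope")


def _default_adducts() -> dict[str, AdductDef]:
    H = ELEMENT_MASSES["H"]
    deltas = {
        "neutral": (0, 0.0),
        "[M+H]+": (1, H - ELECTRON_MASS),
        "[M+Na]+": (1, ELEMENT_MASSES["Na"] - ELECTRON_MASS),
        "[M+NH4]+": (1, ELEMENT_MASSES["N"] + 4 * H - ELECTRON_MASS),
        "[M+K]+": (1, ELEMENT_MASSES["K"] - ELECTRON_MASS),
        "[M-H]-": (-1, -(H - ELECTRON_MASS)),
        "[M+Cl]-": (-1, ELEMENT_MASSES["Cl"] + ELECTRON_MASS),
        "[M+HCOO]-": (-1, H + ELEMENT_MASSES["C"] + 2 * ELEMENT_MASSES["O"]
                      + ELECTRON_MASS),
    }
    return {name: AdductDef(name, z, d) for name, (z, d) in deltas.items()}


DEFAULT_ADDUCTS: Mapping[str, AdductDef] = _default_adducts()


def get_adduct(name: str,
               adducts: Mapping[str, AdductDef] = DEFAULT_ADDUCTS) -> AdductDef:
    # tolerate the unicode minus that adduct names are often pasted with
    key = name.replace("−", "-").replace("−", "-")
    try:
        return adducts[key]
    except KeyError:
        raise SearchError(
            f"unknown adduct {name!r}; available: {', '.join(sorted(adducts))}"
        ) from None


def neutral_mass_from_mz(mz: float, adduct: AdductDef) -> float:
    """Invert the adduct arithmetic: observed m/z -> neutral monoisotopic mass."""
    if adduct.charge == 0:
        return mz
    return abs(adduct.charge) * mz - adduct.mass_delta


def mz_from_neutral(neutral: float, adduct: AdductDef) -> float:
    if adduct.charge == 0:
        return neutral
    return (neutral + adduct.mass_delta) / abs(adduct.charge)


_TOL_RE = re.compile(r"^\s*([0-9.]+)\s*(da|ppm)\s*$", re.IGNORECASE)


@dataclass(frozen=True)
class Tolerance:
    """A symmetric match tolerance, in Da or in ppm of the theoretical mass."""

    value: float
    mode: str  # "da" | "ppm"

    def __post_init__(self) -> None:
        if self.mode not in ("da", "ppm"):
            raise SearchError(f"tolerance mode must be 'da' or 'ppm', got {self.mode!r}")
        if not self.value > 0:
            raise SearchError("tolerance must be positive")

    @classmethod
    def parse(cls, text: str) -> "Tolerance":
        m = _TOL_RE.match(text)
        if not m:
            raise SearchError(
                f"cannot parse tolerance {text!r}; expected e.g. '0.01da' or '5ppm'")
        return cls(float(m.group(1)), m.group(2).lower())

    def window_da(self, theoretical_mass: float) -> float:
        if self.mode == "da":
            return self.value
        return self.value * 1e-6 * theoretical_mass

    def matches(self, neutral: float, theoretical_mass: float) -> bool:
        return abs(neutral - theoretical_mass) <= self.window_da(theoretical_mass)


@dataclass(frozen=True)
class SearchFilters:
    """Exclusion filters: categories, main-class codes, sub-class display names."""

    exclude_categories: frozenset[str] = frozenset()
    exclude_main_classes: frozenset[str] = frozenset()
    exclude_subclasses: frozenset[str] = frozenset()

    def admits(self, subclass: SubClassDef) -> bool:
        return (subclass.category not in self.exclude_categories
                and subclass.main_class not in self.exclude_main_classes
                and subclass.display_name not in self.exclude_subclasses)


NO_FILTERS = SearchFilters()


@dataclass(frozen=True)
class SearchHit:
    query_mz: float
    adduct: AdductDef
    record: LipidRecord
    theoretical_mass: float
    delta: float  # neutral(query, adduct) - theoretical, Da

    @property
    def delta_ppm(self) -> float:
        return self.delta / self.theoretical_mass * 1e6


@lru_cache(maxsize=8)
def _species_table(subclasses: tuple[SubClassDef, ...],
                   rules: ChainRules) -> tuple[tuple[float, ...],
                                               tuple[LipidRecord, ...]]:
    records = [rec for sc in subclasses for rec in enumerate_species(sc, rules)]
    records.sort(key=lambda r: (r.neutral_mass, r.canonical_name))
    return tuple(r.neutral_mass for r in records), tuple(records)


def ms1_search(queries: Sequence[float],
               tolerance: Tolerance,
               adducts: Sequence[AdductDef],
               filters: SearchFilters = NO_FILTERS,
               rules: ChainRules = DEFAULT_RULES,
               subclasses: Iterable[SubClassDef] | None = None,
               ) -> list[list[SearchHit]]:
    """Match precursor masses against the Species space.

    Every adduct is tried for every query.  Returns one hit list per query
    (parallel to ``queries``), each sorted by absolute mass error and then by
    canonical name.
    """
    if not adducts:
        raise SearchError("at least one adduct is required")
    if subclasses is None:
        subclasses = build_subclasses()
    subclasses = tuple(sc for sc in subclasses if filters.admits(sc))
    masses, records = _species_table(subclasses, rules)

    results: list[list[SearchHit]] = []
    for mz in queries:
        hits: list[SearchHit] = []
        for adduct in adducts:
            neutral = neutral_mass_from_mz(mz, adduct)
            # generous candidate window, then the exact predicate
            pad = tolerance.window_da(max(abs(neutral), 1.0)) * 1.01 + 1e-9
            lo = bisect.bisect_left(masses, neutral - pad)
            hi = bisect.bisect_right(masses, neutral + pad)
            for rec in records[lo:hi]:
                if tolerance.matches(neutral, rec.neutral_mass):
                    hits.append(SearchHit(mz, adduct, rec, rec.neutral_mass,
                                          neutral - rec.neutral_mass))
        hits.sort(key=lambda h: (abs(h.delta), h.record.canonical_name,
                                 h.adduct.name))
        results.append(hits)
    return results


def read_mass_list(lines: Iterable[str]) -> list[float]:
    """Parse a newline-separated precursor mass list; blanks and ``#`` comments
    are ignored."""
    masses = []
    for i, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            masses.append(float(line))
        except ValueError:
            raise SearchError(f"line {i}: not a mass: {line!r}") from None
    return masses
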