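"""Hierarchy construction, navigation, counting and nomenclature."""

import itertools
import random

import pytest

from theolipid import (Chain, ChainRules, DEFAULT_RULES, Level, NameParseError,
                       build_subclasses, children, count_records,
                       enumerate_chain_types, enumerate_species, fas_children,
                       fas_record, find_subclass, format_name, iter_records,
                       load_config, parent, parse_name, species_children,
                       species_record, subspecies_children, subspecies_record)
from theolipid.lipid_space import LipidSpaceError, iter_fas


# -- sub-class construction -------------------------------------------------

def test_cartesian_cross_yields_39_subclasses(subclasses):
    assert len(subclasses) == 39
    per_class = {}
    for sc in subclasses:
        per_class.setdefault(sc.main_class, []).append(sc)
    assert len(per_class["PC"]) == 3     # acyl/acyl, alkyl/acyl, alkyl/alkyl
    assert len(per_class["TG"]) == 4     # multisets of size 3 over 2 linkages
    assert len(per_class["MG"]) == 2     # one per linkage
    assert len(per_class["LPC"]) == 2


def test_subclass_display_names(subclasses):
    names = {sc.display_name for sc in subclasses}
    assert "diacylglycerophosphocholines" in names
    assert "monoalkyl,monoacylglycerophosphocholines" in names
    assert "monoacylglycerophosphocholines" in names
    assert "triacylglycerols" in names
    assert "monoalkyl,diacylglycerols" in names


def test_one_subclass_per_main_class_and_linkage_multiset(subclasses):
    keys = [(sc.main_class, sc.linkage_multiset) for sc in subclasses]
    assert len(keys) == len(set(keys))


def test_unknown_main_class_code_errors(subclasses):
    with pytest.raises(LipidSpaceError):
        find_subclass(subclasses, "XX", 0)


# -- species enumeration ----------------------------------------------------

def test_diacyl_species_reduced_bounds(diacyl_pc, rules4):
    totals = [(r.total_carbons, r.total_double_bonds)
              for r in enumerate_species(diacyl_pc, rules4)]
    assert totals == [(4, 0), (5, 0), (5, 1), (6, 0), (6, 1), (6, 2),
                      (7, 0), (7, 1), (7, 2), (8, 0), (8, 1), (8, 2)]


def test_default_species_contain_published_names(diacyl_pc, alkyl_acyl_pc):
    names = {r.canonical_name for r in enumerate_species(diacyl_pc)}
    assert "PC 34:1" in names
    ether = {r.canonical_name for r in enumerate_species(alkyl_acyl_pc)}
    assert "PC O-35:1" in ether


# -- children / parent ------------------------------------------------------

def test_species_children_include_published_fas(diacyl_pc):
    pc_34_1 = species_record(diacyl_pc, 34, 1)
    names = {r.canonical_name for r in species_children(pc_34_1)}
    assert "PC 16:0_18:1" in names
    assert all(r.total_carbons == 34 and r.total_double_bonds == 1
               for r in species_children(pc_34_1))


def test_unique_split_species_has_one_child(diacyl_pc, rules4):
    rec = species_record(diacyl_pc, 4, 0)
    kids = species_children(rec, rules4)
    assert [k.canonical_name for k in kids] == ["PC 2:0_2:0"]


def test_species_children_match_bruteforce_pairs(diacyl_pc, rules4):
    """Oracle: filter all unordered chain-type pairs by the totals."""
    types = enumerate_chain_types(rules4)
    expected = {tuple(sorted(pair))
                for pair in itertools.combinations_with_replacement(types, 2)
                if sum(c for c, _ in pair) == 8 and sum(d for _, d in pair) == 2}
    rec = species_record(diacyl_pc, 8, 2)
    got = {tuple(sorted((c.carbons, c.double_bonds) for c in k.chains))
           for k in species_children(rec, rules4)}
    assert got == expected
    assert len(got) == 1  # only 4:1_4:1 fits within four carbons per chain


def test_fas_children_orderings(diacyl_pc, alkyl_acyl_pc):
    fas = fas_record(diacyl_pc, [Chain("acyl", 16, 0), Chain("acyl", 18, 1)])
    assert {r.canonical_name for r in fas_children(fas)} \
        == {"PC 16:0/18:1", "PC 18:1/16:0"}
    symmetric = fas_record(diacyl_pc, [Chain("acyl", 16, 0), Chain("acyl", 16, 0)])
    assert [r.canonical_name for r in fas_children(symmetric)] == ["PC 16:0/16:0"]
    mixed = fas_record(alkyl_acyl_pc, [Chain("alkyl", 16, 0), Chain("acyl", 18, 1)])
    kids = fas_children(mixed)
    assert [r.canonical_name for r in kids] == ["PC O-16:0/18:1"]
    assert kids[0].chains[0].linkage == "alkyl"  # alkyl canonically at sn1


def test_subspecies_children_positions(diacyl_pc):
    ss = subspecies_record(diacyl_pc, [Chain("acyl", 18, 1), Chain("acyl", 16, 0)])
    isomers = subspecies_children(ss)
    assert len(isomers) == 16
    saturated = subspecies_record(diacyl_pc,
                                  [Chain("acyl", 16, 0), Chain("acyl", 18, 0)])
    assert len(subspecies_children(saturated)) == 1
    tri = subspecies_record(diacyl_pc, [Chain("acyl", 18, 3), Chain("acyl", 16, 0)])
    assert any(r.chains[0].positions == (9, 12, 15)
               for r in subspecies_children(tri))


def test_parent_published_examples(diacyl_pc):
    ss = parse_name("PC 18:1/16:0")
    assert parent(ss).canonical_name == "PC 16:0_18:1"
    assert parent(parent(ss)).canonical_name == "PC 34:1"
    with pytest.raises(LipidSpaceError):
        parent(parse_name("PC 34:1"))


def test_parent_of_children_is_identity(subclasses, rules6):
    rng = random.Random(20260928)
    for sc in rng.sample(subclasses, 10):
        species = enumerate_species(sc, rules6)
        for rec in rng.sample(species, min(3, len(species))):
            kids = species_children(rec, rules6)
            for fas in rng.sample(kids, min(3, len(kids))):
                assert parent(fas) == rec
                for ss in fas_children(fas, rules6):
                    assert parent(ss) == fas
                    for iso in subspecies_children(ss, rules6):
                        assert parent(iso) == ss


def test_children_partition_the_next_level(subclasses, rules6):
    for sc in subclasses[:6] + subclasses[-3:]:
        direct = [r.canonical_name for r in iter_fas(sc, rules6)]
        assert len(direct) == len(set(direct))
        via_parents = [k.canonical_name
                       for sp in enumerate_species(sc, rules6)
                       for k in species_children(sp, rules6)]
        assert sorted(via_parents) == sorted(direct)


# -- counting ---------------------------------------------------------------

def test_default_diacyl_subspecies_count(diacyl_pc):
    assert count_records(diacyl_pc, Level.SubSpecies, DEFAULT_RULES) == 30276


def test_two_acyl_slot_count_reduced(diacyl_pc, rules4):
    assert count_records(diacyl_pc, Level.SubSpecies, rules4) == 25  # 5 types squared


def test_counts_match_enumeration_at_reduced_bounds(subclasses, rules10, rules8):
    for sc in subclasses:
        for level in (Level.Species, Level.FasSpecies, Level.SubSpecies):
            assert count_records(sc, level, rules10) \
                == sum(1 for _ in iter_records(sc, level, rules10)), \
                (sc.display_name, level)
        assert count_records(sc, Level.Isomer, rules8) \
            == sum(1 for _ in iter_records(sc, Level.Isomer, rules8)), \
            sc.display_name


def test_all_saturated_isomer_count_equals_subspecies_count(diacyl_pc):
    saturated = ChainRules(max_carbons=8, max_double_bonds=0)
    assert count_records(diacyl_pc, Level.Isomer, saturated) \
        == count_records(diacyl_pc, Level.SubSpecies, saturated)


# -- mass and formula consistency -------------------------------------------

def test_descendants_share_formula_and_mass(subclasses, rules6):
    rng = random.Random(7)
    for sc in rng.sample(subclasses, 8):
        for rec in enumerate_species(sc, rules6):
            for fas in species_children(rec, rules6):
                assert fas.formula == rec.formula
                for ss in fas_children(fas, rules6):
                    assert ss.formula == rec.formula
                    for iso in subspecies_children(ss, rules6):
                        assert iso.formula == rec.formula
                        assert iso.neutral_mass == pytest.approx(
                            rec.neutral_mass, abs=1e-9)


# -- nomenclature -----------------------------------------------------------

def _expected_degenerate(rec):
    """The least-resolved record sharing the same canonical name."""
    if rec.level is Level.Isomer and rec.total_double_bonds == 0:
        rec = subspecies_record(rec.subclass, rec.chains)
    if rec.subclass.slot_count == 1:
        bare_subspecies = (rec.level is Level.SubSpecies
                           and not rec.subclass.is_monoradyl_gp)
        if rec.level is Level.FasSpecies or bare_subspecies:
            return species_record(rec.subclass, rec.total_carbons,
                                  rec.total_double_bonds)
    return rec


def test_name_roundtrip_over_full_reduced_enumeration(subclasses):
    config = load_config(overrides=["rules.max_carbons=6"])
    n = 0
    for sc in build_subclasses(config):
        for level in Level:
            for rec in iter_records(sc, level, config.rules):
                parsed = parse_name(format_name(rec), config)
                expected = _expected_degenerate(rec)
                assert parsed == expected, format_name(rec)
                assert format_name(parsed) == format_name(rec)
                n += 1
    assert n > 10000  # the reduced space is fully exercised


@pytest.mark.parametrize("name, reason", [
    ("PC 34", "totals"),                    # missing double-bond field
    ("XX 34:1", "unknown class"),
    ("PC 34:1:2", "totals"),
    ("PC 18:1/O-16:0", "sn"),               # alkyl must sit at sn1
    ("PC 18:1_16:0", "canonical order"),    # FAS chains must be sorted
    ("PC 16:0/0:0", "lyso"),                # empty slot needs the lyso class
    ("MG 16:0/0:0", "0:0"),
])
def test_parse_rejects_malformed_names(name, reason):
    with pytest.raises(NameParseError):
        parse_name(name)


def test_parse_error_reports_position():
    with pytest.raises(NameParseError) as exc:
        parse_name("PC 18:1/16:x")
    assert exc.value.position == 8


def test_species_name_is_unambiguous_for_lyso_classes():
    lyso = parse_name("LPC 16:0")
    diacyl = parse_name("PC 16:0")
    assert lyso.subclass.slot_count == 1
    assert diacyl.subclass.slot_count == 2
    assert lyso.neutral_mass != diacyl.neutral_mass


def test_unrealizable_species_is_rejected():
    config = load_config(overrides=["rules.max_carbons=4"])
    with pytest.raises(NameParseError, match="not realizable"):
        parse_name("PC 34:1", config)


def test_ether_species_prefixes(subclasses):
    assert parse_name("TG tO-52:2").subclass.n_alkyl == 3
    assert parse_name("PC dO-34:1").subclass.n_alkyl == 2
    assert format_name(parse_name("TG dO-52:2")) == "TG dO-52:2"
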