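import pytest

from theolipid import ChainRules, build_subclasses, find_subclass


@pytest.fixture(scope="session")
def subclasses():
    return build_subclasses()


@pytest.fixture(scope="session")
def diacyl_pc(subclasses):
    return find_subclass(subclasses, "PC", 0)


@pytest.fixture(scope="session")
def alkyl_acyl_pc(subclasses):
    return find_subclass(subclasses, "PC", 1)


@pytest.fixture(scope="session")
def rules4():
    return ChainRules(max_carbons=4)


@pytest.fixture(scope="session")
def rules6():
    return ChainRules(max_carbons=6)


@pytest.fixture(scope="session")
def rules8():
    return ChainRules(max_carbons=8)


@pytest.fixture(scope="session")
def rules10():
    return ChainRules(max_carbons=10)


def brute_force_position_sets(carbons, n_db, rules):
    """Independent oracle: filter all position subsets by the spacing predicate."""
    from itertools import combinations

    if n_db == 0:
        return [()]
    last = rules.last_position(carbons)
    candidates = range(rules.first_db_min_position, last + 1)
    out = []
    for combo in combinations(candidates, n_db):
        if all(rules.gap_allowed(b - a) for a, b in zip(combo, combo[1:])):
            out.append(combo)
    return out
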