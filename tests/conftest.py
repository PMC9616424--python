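import numpy as np
import pytest

from extrae.mining import TransactionDB


@pytest.fixture
def toy_db() -> TransactionDB:
    """Four patients over items a, b, c; supports countable by hand."""
    return TransactionDB.from_itemsets([["a", "b"], ["a", "b", "c"], ["a"], ["c"]])


def random_db(rng: np.random.Generator, n_transactions: int, n_items: int) -> TransactionDB:
    """Random small database for oracle comparisons; every transaction non-empty."""
    items = [f"i{k}" for k in range(n_items)]
    baskets = []
    for _ in range(n_transactions):
        mask = rng.random(n_items) < rng.uniform(0.2, 0.7)
        if not mask.any():
            mask[rng.integers(n_items)] = True
        baskets.append([items[k] for k in np.flatnonzero(mask)])
    return TransactionDB.from_itemsets(baskets)


def brute_force_itemsets(db: TransactionDB, min_support: float):
    """Exhaustive subset enumeration over the observed item universe."""
    from itertools import combinations

    universe = sorted({it for t in db for it in t.items})
    out = {}
    for r in range(1, len(universe) + 1):
        for combo in combinations(universe, r):
            target = frozenset(combo)
            count = sum(1 for t in db if target <= t.items)
            if count / db.N >= min_support - 1e-12:
                out[target] = count / db.N
    return out


def brute_force_rules(db: TransactionDB, min_support: float, min_confidence: float):
    """All single-consequent rules (X, y, support, confidence, lift) by enumeration."""
    freq = brute_force_itemsets(db, min_support)
    rules = {}
    for itemset, supp in freq.items():
        if len(itemset) < 2:
            continue
        for y in sorted(itemset):
            antecedent = itemset - {y}
            conf = supp / freq[antecedent]
            if conf >= min_confidence - 1e-12:
                rules[(tuple(sorted(antecedent)), y)] = (
                    supp,
                    conf,
                    conf / freq[frozenset({y})],
                )
    return rules
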