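"""Association-rule mining over patient-diagnosis transactions.

A transaction is the set of distinct health disorders recorded for one
patient; repeated diagnoses over follow-up collapse to a set.  Frequent
itemsets are mined with FP-Growth and turned into rules ``X => y`` with a
single-item consequent (configurable), carrying support, confidence and
lift:

    support(X => y)    = count(X ∪ {y}) / N
    confidence(X => y) = support(X ∪ {y}) / support(X)
    lift(X => y)       = confidence(X => y) / support({y})

Items are compared case-insensitively after whitespace normalization,
because clinical strings vary in capitalization across centers.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence


def normalize_item(name: str) -> str:
    """Canonical form of a disorder string: trimmed, single-spaced, casefolded."""
    canon = " ".join(str(name).split()).casefold()
    if not canon:
        raise ValueError("item name is empty after normalization")
    return canon


@dataclass(frozen=True, slots=True)
class Transaction:
    """One patient's set of distinct disorder items."""

    patient_id: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(f"transaction {self.patient_id!r} has no items")


class TransactionDB:
    """An ordered collection of transactions."""

    def __init__(self, transactions: Sequence[Transaction]):
        self.transactions: list[Transaction] = list(transactions)

    @classmethod
    def from_itemsets(
        cls, itemsets: Iterable[Iterable[str]], ids: Iterable[str] | None = None
    ) -> "TransactionDB":
        itemsets = list(itemsets)
        if ids is None:
            ids = (f"p{i}" for i in range(len(itemsets)))
        txns = [
            Transaction(str(pid), frozenset(normalize_item(i) for i in items))
            for pid, items in zip(ids, itemsets)
        ]
        return cls(txns)

    @property
    def N(self) -> int:
        return len(self.transactions)

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self) -> Iterator[Transaction]:
        return iter(self.transactions)

    def item_sets(self) -> list[frozenset[str]]:
        return [t.items for t in self.transactions]


@dataclass(frozen=True, slots=True)
class AssociationRule:
    """A rule antecedent => consequent with its interestingness measures.

    ``consequent`` holds one or more items (pipe-free strings); the default
    mining configuration produces single-item consequents only.
    """

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")
        if self.support <= 0:
            raise ValueError("rule support must be positive")

    @property
    def items(self) -> frozenset[str]:
        """Full item content: antecedent ∪ consequent."""
        return self.antecedent | self.consequent

    @property
    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Canonical identity used for ordering, deduplication and files."""
        return (tuple(sorted(self.antecedent)), tuple(sorted(self.consequent)))

    def canonical_items(self) -> list[str]:
        """Antecedent in lexicographic order, then consequent items."""
        return sorted(self.antecedent) + sorted(self.consequent)


def rule_sort_key(rule: AssociationRule):
    """Reproducible file order: support desc, confidence desc, then canonical id."""
    return (-rule.support, -rule.confidence, rule.key)


# ---------------------------------------------------------------------------
# Elementary measures


def support(db: TransactionDB, itemset: Iterable[str]) -> float:
    """Fraction of transactions containing every item of ``itemset``."""
    if db.N == 0:
        raise ValueError("empty transaction database")
    target = frozenset(normalize_item(i) for i in itemset)
    if not target:
        raise ValueError("empty itemset")
    count = sum(1 for t in db if target <= t.items)
    return count / db.N


def confidence(db: TransactionDB, antecedent: Iterable[str], consequent: str) -> float:
    """Fraction of antecedent-containing transactions that also contain the consequent."""
    ante = frozenset(normalize_item(i) for i in antecedent)
    supp_a = support(db, ante)
    if supp_a == 0:
        raise ValueError("undefined confidence: antecedent has zero support")
    supp_ay = support(db, ante | {normalize_item(consequent)})
    return supp_ay / supp_a


def lift(posterior_confidence: float, prior_confidence: float) -> float:
    """Quotient of the posterior and prior confidence of a rule.

    The prior confidence of ``X => y`` is the confidence of the empty-antecedent
    rule ``∅ => y``, i.e. the support of the consequent.
    """
    if prior_confidence <= 0:
        raise ValueError("undefined lift: prior confidence must be positive")
    if posterior_confidence < 0:
        raise ValueError("posterior confidence must be non-negative")
    return posterior_confidence / prior_confidence


# ---------------------------------------------------------------------------
# FP-Growth


class _FPNode:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item: str | None, parent: "_FPNode | None"):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, _FPNode] = {}


def _build_tree(
    itemlists: Iterable[tuple[tuple[str, ...], int]],
    min_count: int,
) -> tuple[_FPNode, dict[str, list[_FPNode]], dict[str, int]]:
    """Build an FP-tree from (items, weight) pairs; returns root, header, item counts."""
    counts: Counter[str] = Counter()
    cached = []
    for items, weight in itemlists:
        cached.append((items, weight))
        for it in items:
            counts[it] += weight
    frequent = {it: c for it, c in counts.items() if c >= min_count}
    # Global order: frequency descending, name ascending (deterministic).
    rank = {
        it: r
        for r, (it, _) in enumerate(
            sorted(frequent.items(), key=lambda kv: (-kv[1], kv[0]))
        )
    }
    root = _FPNode(None, None)
    header: dict[str, list[_FPNode]] = {it: [] for it in frequent}
    for items, weight in cached:
        ordered = sorted((it for it in items if it in rank), key=rank.__getitem__)
        node = root
        for it in ordered:
            child = node.children.get(it)
            if child is None:
                child = _FPNode(it, node)
                node.children[it] = child
                header[it].append(child)
            child.count += weight
            node = child
    return root, header, frequent


def _single_path(root: _FPNode) -> list[tuple[str, int]] | None:
    """Return the node path if the tree is a single chain, else None."""
    path = []
    node = root
    while node.children:
        if len(node.children) > 1:
            return None
        (node,) = node.children.values()
        path.append((node.item, node.count))
    return path


def _mine_tree(
    root: _FPNode,
    header: dict[str, list[_FPNode]],
    item_counts: dict[str, int],
    min_count: int,
    suffix: tuple[str, ...],
    max_len: int | None,
    emit,
) -> None:
    """Recursive FP-Growth; ``emit(items, count)`` receives every frequent itemset."""
    budget = None if max_len is None else max_len - len(suffix)
    if budget is not None and budget <= 0:
        return
    path = _single_path(root)
    if path is not None:
        # All combinations of path items joined with the suffix.
        limit = len(path) if budget is None else min(budget, len(path))
        for r in range(1, limit + 1):
            for combo in combinations(path, r):
                count = min(c for _, c in combo)
                emit(tuple(it for it, _ in combo) + suffix, count)
        return
    # Process items from least to most frequent.
    for item, count in sorted(item_counts.items(), key=lambda kv: (kv[1], kv[0])):
        new_suffix = (item,) + suffix
        emit(new_suffix, count)
        if budget is not None and budget == 1:
            continue
        # Conditional pattern base for this item.
        cond: list[tuple[tuple[str, ...], int]] = []
        for node in header[item]:
            prefix = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                prefix.append(parent.item)
                parent = parent.parent
            if prefix:
                cond.append((tuple(prefix), node.count))
        if not cond:
            continue
        croot, cheader, ccounts = _build_tree(cond, min_count)
        if ccounts:
            _mine_tree(croot, cheader, ccounts, min_count, new_suffix, max_len, emit)


def mine_frequent_itemsets(
    db: TransactionDB,
    min_support: float,
    max_len: int | None = None,
) -> list[tuple[frozenset[str], float]]:
    """All itemsets with support >= ``min_support`` via FP-Growth.

    The result is downward-closed (every non-empty subset of a returned
    itemset is returned) and deterministically ordered by descending
    support then lexicographic items.
    """
    if db.N == 0:
        raise ValueError("empty transaction database")
    if not (0 < min_support <= 1):
        raise ValueError("min_support must lie in (0, 1]")
    # support >= min_support  <=>  count >= ceil(min_support * N), robust to float fuzz
    min_count = max(1, math.ceil(min_support * db.N - 1e-9))
    weighted = [(tuple(t.items), 1) for t in db]
    root, header, counts = _build_tree(weighted, min_count)
    del weighted
    out: list[tuple[frozenset[str], int]] = []
    if counts:
        _mine_tree(
            root, header, counts, min_count, (), max_len,
            lambda items, c: out.append((frozenset(items), c)),
        )
    del root, header
    N = db.N
    result = [(items, c / N) for items, c in out]
    del out
    result.sort(key=lambda pair: (-pair[1], tuple(sorted(pair[0]))))
    return result


def generate_rules(
    frequent: Sequence[tuple[frozenset[str], float]],
    db: TransactionDB,
    min_confidence: float = 0.6,
    max_consequent_len: int = 1,
    max_antecedent_len: int | None = None,
) -> list[AssociationRule]:
    """Rules from frequent itemsets: all X => Y with confidence >= threshold.

    ``frequent`` must be downward-closed with correct supports (as produced
    by :func:`mine_frequent_itemsets`); supports of sub-itemsets are looked
    up there.  The lift prior of a rule is the support of its consequent.
    """
    supports = {items: s for items, s in frequent}
    # canonical store so rules share frozenset objects with the frequent set
    canon = {items: items for items in supports}
    rules: list[AssociationRule] = []
    for itemset, supp in supports.items():
        if len(itemset) < 2:
            continue
        members = sorted(itemset)
        max_c = min(max_consequent_len, len(itemset) - 1)
        for clen in range(1, max_c + 1):
            for consequent_tuple in combinations(members, clen):
                antecedent = itemset - frozenset(consequent_tuple)
                if max_antecedent_len is not None and len(antecedent) > max_antecedent_len:
                    continue
                supp_a = supports[antecedent]
                conf = supp / supp_a
                # tolerance so ratios of float supports keep boundary rules
                if conf < min_confidence - 1e-12:
                    continue
                consequent = canon[frozenset(consequent_tuple)]
                rules.append(
                    AssociationRule(
                        antecedent=canon[antecedent],
                        consequent=consequent,
                        support=supp,
                        confidence=min(conf, 1.0),
                        lift=conf / supports[consequent],
                    )
                )
    rules.sort(key=rule_sort_key)
    return rules


def iter_rules(
    db: TransactionDB,
    min_support: float = 0.0001,
    min_confidence: float = 0.6,
    max_antecedent_len: int | None = None,
) -> Iterator[AssociationRule]:
    """Stream single-consequent rules without materializing the frequent set.

    Equivalent to :func:`mine_rules` with ``max_consequent_len=1`` except for
    output order (streaming order is not the canonical file order).  Itemset
    supports are held as a bit-mask -> count table, so memory stays bounded
    even when permissive thresholds make the frequent set very large; use
    this for big cohorts and :func:`mine_rules` when the full sorted rule
    list is wanted.
    """
    if db.N == 0:
        raise ValueError("empty transaction database")
    if not (0 < min_support <= 1):
        raise ValueError("min_support must lie in (0, 1]")
    min_count = max(1, math.ceil(min_support * db.N - 1e-9))
    max_len = None if max_antecedent_len is None else max_antecedent_len + 1
    weighted = [(tuple(t.items), 1) for t in db]
    root, header, counts = _build_tree(weighted, min_count)
    del weighted
    if not counts:
        return
    names = sorted(counts)
    bit = {it: i for i, it in enumerate(names)}
    supports: dict[int, int] = {}

    def emit(items: tuple[str, ...], count: int) -> None:
        mask = 0
        for it in items:
            mask |= 1 << bit[it]
        supports[mask] = count

    _mine_tree(root, header, counts, min_count, (), max_len, emit)
    del root, header

    N = db.N
    single = {}  # per-item prior supports
    for it, b in bit.items():
        c = supports.get(1 << b)
        if c is not None:
            single[1 << b] = c
    for mask, count in supports.items():
        if mask.bit_count() < 2:
            continue
        if max_antecedent_len is not None and mask.bit_count() > max_antecedent_len + 1:
            continue
        m = mask
        while m:
            y_bit = m & -m
            m ^= y_bit
            ante_mask = mask ^ y_bit
            conf = count / supports[ante_mask]
            if conf < min_confidence - 1e-12:
                continue
            antecedent = frozenset(
                names[b] for b in range(ante_mask.bit_length()) if ante_mask >> b & 1
            )
            consequent = frozenset([names[(y_bit.bit_length() - 1)]])
            yield AssociationRule(
                antecedent=antecedent,
                consequent=consequent,
                support=count / N,
                confidence=min(conf, 1.0),
                lift=conf / (single[y_bit] / N),
            )


def mine_rules(
    db: TransactionDB,
    min_support: float = 0.0001,
    min_confidence: float = 0.6,
    max_consequent_len: int = 1,
    max_antecedent_len: int | None = None,
) -> list[AssociationRule]:
    """End-to-end mining with the reference defaults (support 1e-4, confidence 0.6)."""
    max_len = None
    if max_antecedent_len is not None:
        max_len = max_antecedent_len + max_consequent_len
    frequent = mine_frequent_itemsets(db, min_support, max_len=max_len)
    return generate_rules(
        frequent,
        db,
        min_confidence=min_confidence,
        max_consequent_len=max_consequent_len,
        max_antecedent_len=max_antecedent_len,
    )
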