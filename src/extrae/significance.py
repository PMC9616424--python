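"""Unsupervised rule filter: hypergeometric significance over a rule population.

The transaction database is split into an exploratory half and a holdout
half; rules are mined in both.  For each holdout rule ``A => B`` a 2x2
contingency table is counted over the *exploratory rule population*:

    N  — rules in the exploratory set
    n1 — exploratory rules containing A
    n2 — exploratory rules containing B
    k  — exploratory rules containing both

and the rule's p-value is the hypergeometric point probability

    p(R) = C(n1, k) * C(N - n1, n2 - k) / C(N, n2)

evaluated through log-gamma for numerical stability.  An optional tail
mode sums the upper tail P(K >= k) (the one-sided Fisher exact test).
Low p-values mark rules whose sides co-occur across the rule population
more than chance predicts; ranking ascending and thresholding yields the
unsupervised relevance prediction.  The threshold itself is calibrated on
a small labeled seed by maximizing seed accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import hypergeom

from .mining import AssociationRule, TransactionDB, rule_sort_key


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (N, n1, n2, k) of a rule's sides over an exploratory rule set."""

    N: int
    n1: int
    n2: int
    k: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k <= min(self.n1, self.n2)
            and max(self.n1, self.n2) <= self.N
            and self.n1 + self.n2 - self.k <= self.N
        )
        if not ok:
            raise ValueError(f"inconsistent contingency table {self}")


@dataclass(frozen=True)
class ScoredRule:
    rule: AssociationRule
    p_value: float


@dataclass(frozen=True)
class PValueThreshold:
    """A calibrated p-value cut-off; rules with p < value are predicted relevant."""

    value: float
    seed_accuracy: float


def split_exploratory_holdout(
    db: TransactionDB, fraction: float = 0.5, seed: int = 0
) -> tuple[TransactionDB, TransactionDB]:
    """Random disjoint split of transactions into exploratory and holdout halves."""
    if db.N < 2:
        raise ValueError("need at least 2 transactions to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(db.N)
    n_explor = math.ceil(db.N * fraction)
    explor_idx = set(order[:n_explor].tolist())
    explor = [t for i, t in enumerate(db) if i in explor_idx]
    holdout = [t for i, t in enumerate(db) if i not in explor_idx]
    return TransactionDB(explor), TransactionDB(holdout)


Containment = Literal["subset", "exact-antecedent"]


def _rule_side_sets(
    rule: AssociationRule, containment: Containment
) -> tuple[frozenset[str], frozenset[str]]:
    if containment not in ("subset", "exact-antecedent"):
        raise ValueError(f"unknown containment mode {containment!r}")
    return rule.antecedent, rule.consequent


def build_contingency(
    rule: AssociationRule,
    exploratory_rules: Sequence[AssociationRule],
    containment: Containment = "subset",
) -> ContingencyTable:
    """Count how often the rule's sides appear in the exploratory rule population.

    Under the default subset containment, an exploratory rule "contains A"
    when A is a subset of its full item content (antecedent ∪ consequent),
    and "contains B" likewise; ``exact-antecedent`` restricts the A side to
    rules whose antecedent equals A.
    """
    if not exploratory_rules:
        raise ValueError("empty exploratory rule set")
    a_side, b_side = _rule_side_sets(rule, containment)
    n1 = n2 = k = 0
    for other in exploratory_rules:
        content = other.items
        if containment == "exact-antecedent":
            has_a = other.antecedent == a_side
        else:
            has_a = a_side <= content
        has_b = b_side <= content
        n1 += has_a
        n2 += has_b
        k += has_a and has_b
    return ContingencyTable(N=len(exploratory_rules), n1=n1, n2=n2, k=k)


def hypergeom_pvalue(table: ContingencyTable, tail: bool = False) -> float:
    """Point hypergeometric probability of the table (or the upper tail).

    Computed via scipy's log-space hypergeometric pmf/sf, clipped into (0, 1].
    """
    N, n1, n2, k = table.N, table.n1, table.n2, table.k
    if tail:
        if k == 0:
            p = 1.0
        else:
            p = float(hypergeom.sf(k - 1, N, n1, n2))
    else:
        p = float(math.exp(hypergeom.logpmf(k, N, n1, n2)))
    if not math.isfinite(p):
        raise ValueError(f"inconsistent contingency table {table}")
    return min(max(p, math.ulp(0.0)), 1.0)


# ---------------------------------------------------------------------------
# Vectorized population scoring


class RulePopulation:
    """Bit-packed item-content masks of a rule population for fast containment counts."""

    @classmethod
    def from_rule_stream(cls, rules) -> "RulePopulation":
        """Build the packed population from an iterable without retaining the
        rule objects — the memory-bounded path for very large populations."""
        bit: dict[str, int] = {}
        masks_int: list[int] = []
        for r in rules:
            m = 0
            for it in r.items:
                b = bit.setdefault(it, len(bit))
                m |= 1 << b
            masks_int.append(m)
        if not masks_int:
            raise ValueError("empty exploratory rule set")
        obj = cls.__new__(cls)
        obj.rules = None
        obj._bit = bit
        obj._words = max(1, (len(bit) + 63) // 64)
        obj._masks = np.zeros((len(masks_int), obj._words), dtype=np.uint64)
        full = (1 << 64) - 1
        for w in range(obj._words):
            shift = 64 * w
            obj._masks[:, w] = [(m >> shift) & full for m in masks_int]
        return obj

    def __len__(self) -> int:
        return self._masks.shape[0]

    def __init__(self, rules: Sequence[AssociationRule]):
        if not rules:
            raise ValueError("empty exploratory rule set")
        self.rules = list(rules)
        vocab = sorted({it for r in self.rules for it in r.items})
        self._bit = {it: i for i, it in enumerate(vocab)}
        self._words = max(1, (len(vocab) + 63) // 64)
        self._masks = np.zeros((len(self.rules), self._words), dtype=np.uint64)
        # chunked fill keeps the transient index arrays small
        bit = self._bit
        chunk = 65536
        for start in range(0, len(self.rules), chunk):
            rows, bits = [], []
            for row, r in enumerate(self.rules[start : start + chunk], start=start):
                for it in r.items:
                    rows.append(row)
                    bits.append(bit[it])
            rows_a = np.asarray(rows, dtype=np.intp)
            bits_a = np.asarray(bits, dtype=np.uint64)
            np.bitwise_or.at(
                self._masks,
                (rows_a, (bits_a >> np.uint64(6)).astype(np.intp)),
                np.uint64(1) << (bits_a & np.uint64(63)),
            )

    def _mask_of(self, items: Iterable[str]) -> np.ndarray | None:
        mask = np.zeros(self._words, dtype=np.uint64)
        for it in items:
            b = self._bit.get(it)
            if b is None:
                return None  # item absent from population vocabulary
            mask[b >> 6] |= np.uint64(1 << (b & 63))
        return mask

    def contingency(self, rule: AssociationRule) -> ContingencyTable:
        a = self._mask_of(rule.antecedent)
        b = self._mask_of(rule.consequent)
        has_a = (
            np.zeros(len(self), dtype=bool)
            if a is None
            else ((self._masks & a) == a).all(axis=1)
        )
        has_b = (
            np.zeros(len(self), dtype=bool)
            if b is None
            else ((self._masks & b) == b).all(axis=1)
        )
        return ContingencyTable(
            N=len(self),
            n1=int(has_a.sum()),
            n2=int(has_b.sum()),
            k=int((has_a & has_b).sum()),
        )


def score_rules(
    holdout_rules: Sequence[AssociationRule],
    exploratory_rules: "Sequence[AssociationRule] | RulePopulation",
    tail: bool = False,
) -> list[ScoredRule]:
    """Score every holdout rule against the exploratory population; ascending p-value.

    ``exploratory_rules`` may be a rule list or an already-packed
    :class:`RulePopulation`.
    """
    if not holdout_rules:
        raise ValueError("empty holdout rule set")
    population = (
        exploratory_rules
        if isinstance(exploratory_rules, RulePopulation)
        else RulePopulation(exploratory_rules)
    )
    N = len(population)
    masks = population._masks
    zeros = np.zeros(N, dtype=bool)

    def side_vector(items) -> np.ndarray:
        m = population._mask_of(items)
        return zeros if m is None else ((masks & m) == m).all(axis=1)

    # Rules sharing a consequent (or antecedent) share a containment vector;
    # grouping roughly halves the work on multi-million-rule populations.
    order = sorted(
        range(len(holdout_rules)),
        key=lambda i: tuple(sorted(holdout_rules[i].consequent)),
    )
    pvals: list[float] = [0.0] * len(holdout_rules)
    current_consequent = None
    has_b = zeros
    n2 = 0
    for i in order:
        r = holdout_rules[i]
        if r.consequent != current_consequent:
            current_consequent = r.consequent
            has_b = side_vector(r.consequent)
            n2 = int(has_b.sum())
        has_a = side_vector(r.antecedent)
        n1 = int(has_a.sum())
        k = int((has_a & has_b).sum())
        table = ContingencyTable(N=N, n1=n1, n2=n2, k=k)
        pvals[i] = hypergeom_pvalue(table, tail=tail)

    scored = [
        ScoredRule(rule=r, p_value=pvals[i]) for i, r in enumerate(holdout_rules)
    ]
    scored.sort(key=lambda s: (s.p_value, rule_sort_key(s.rule)))
    return scored


# ---------------------------------------------------------------------------
# Threshold calibration


def tune_threshold(seed: Sequence[tuple[ScoredRule, bool]]) -> PValueThreshold:
    """Threshold maximizing seed accuracy under the rule "relevant iff p < threshold".

    Candidate thresholds are geometric midpoints between consecutive distinct
    seed p-values, plus one sentinel below the smallest and one above the
    largest (the latter capped at 1.0, since p-values never exceed 1).  Ties
    in accuracy resolve toward the smaller threshold.
    """
    if not seed:
        raise ValueError("empty seed set")
    ps = np.array([s.p_value for s, _ in seed], dtype=float)
    labels = np.array([bool(lab) for _, lab in seed], dtype=bool)
    distinct = np.unique(ps)
    candidates = [distinct[0] / 2.0]
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        candidates.append(math.sqrt(lo * hi))
    candidates.append(min(distinct[-1] * 2.0, 1.0))
    best_thr, best_acc = candidates[0], -1.0
    for thr in candidates:
        acc = float(((ps < thr) == labels).mean())
        if acc > best_acc:
            best_thr, best_acc = thr, acc
    return PValueThreshold(value=best_thr, seed_accuracy=best_acc)


def classify_by_threshold(scored: ScoredRule, threshold: PValueThreshold) -> bool:
    """Relevant iff the rule's p-value lies strictly below the threshold."""
    return scored.p_value < threshold.value
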