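"""Significance-filter tests: exact-arithmetic p-value oracle, threshold scan."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extrae.mining import AssociationRule, TransactionDB
from extrae.significance import (
    ContingencyTable,
    PValueThreshold,
    ScoredRule,
    build_contingency,
    classify_by_threshold,
    hypergeom_pvalue,
    score_rules,
    split_exploratory_holdout,
    tune_threshold,
)


def make_rule(antecedent, consequent, support=0.1, confidence=0.7, lift=1.5):
    return AssociationRule(
        antecedent=frozenset(antecedent),
        consequent=frozenset([consequent]),
        support=support,
        confidence=confidence,
        lift=lift,
    )


def exact_pvalue(N, n1, n2, k) -> Fraction:
    """Eq-by-definition point probability in exact rational arithmetic."""
    return Fraction(math.comb(n1, k) * math.comb(N - n1, n2 - k), math.comb(N, n2))


def feasible_tables(max_N):
    for N in range(1, max_N + 1):
        for n1 in range(N + 1):
            for n2 in range(N + 1):
                for k in range(max(0, n1 + n2 - N), min(n1, n2) + 1):
                    yield N, n1, n2, k


class TestSplit:
    def test_partition_properties(self):
        db = TransactionDB.from_itemsets([[f"i{j}"] for j in range(10)])
        a, b = split_exploratory_holdout(db, 0.5, seed=1)
        assert a.N == b.N == 5
        ids = {t.patient_id for t in a} | {t.patient_id for t in b}
        assert len(ids) == 10

    def test_odd_split_sizes(self):
        db = TransactionDB.from_itemsets([[f"i{j}"] for j in range(7)])
        a, b = split_exploratory_holdout(db, 0.5, seed=0)
        assert (a.N, b.N) == (4, 3)

    def test_determinism_and_seed_sensitivity(self):
        db = TransactionDB.from_itemsets([[f"i{j}"] for j in range(100)])
        a1, _ = split_exploratory_holdout(db, 0.5, seed=5)
        a2, _ = split_exploratory_holdout(db, 0.5, seed=5)
        a3, _ = split_exploratory_holdout(db, 0.5, seed=6)
        ids = lambda d: {t.patient_id for t in d}
        assert ids(a1) == ids(a2)
        assert ids(a1) != ids(a3)

    def test_too_small_errors(self):
        db = TransactionDB.from_itemsets([["a"]])
        with pytest.raises(ValueError):
            split_exploratory_holdout(db, 0.5, seed=0)


class TestContingency:
    def test_hand_count(self):
        exploratory = [
            make_rule(["a"], "b"),
            make_rule(["a"], "c"),
            make_rule(["c"], "b"),
        ]
        table = build_contingency(make_rule(["a"], "b"), exploratory)
        assert (table.N, table.n1, table.n2, table.k) == (3, 2, 2, 1)

    def test_absent_antecedent(self):
        exploratory = [make_rule(["a"], "b")]
        table = build_contingency(make_rule(["z"], "b"), exploratory)
        assert (table.n1, table.k) == (0, 0)

    def test_empty_population_errors(self):
        with pytest.raises(ValueError):
            build_contingency(make_rule(["a"], "b"), [])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ContingencyTable(N=5, n1=3, n2=3, k=4)
        with pytest.raises(ValueError, match="inconsistent"):
            ContingencyTable(N=3, n1=3, n2=3, k=1)  # n1+n2-k > N

    @pytest.mark.parametrize("seed", range(5))
    def test_k_bounded_on_random_populations(self, seed):
        rng = np.random.default_rng(seed)
        items = [f"d{j}" for j in range(8)]
        pop = []
        for _ in range(200):
            ante = rng.choice(items, size=rng.integers(1, 4), replace=False)
            cons = rng.choice([i for i in items if i not in ante])
            pop.append(make_rule(list(ante), cons))
        for _ in range(5):
            probe = pop[rng.integers(len(pop))]
            t = build_contingency(probe, pop)
            assert 0 <= t.k <= min(t.n1, t.n2) <= t.N


class TestHypergeomPValue:
    def test_direct_combinatorial_value(self):
        # C(5,5)*C(5,0)/C(10,5) = 1/252
        p = hypergeom_pvalue(ContingencyTable(N=10, n1=5, n2=5, k=5))
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_degenerate_table_is_one(self):
        assert hypergeom_pvalue(ContingencyTable(N=10, n1=0, n2=4, k=0)) == pytest.approx(1.0)

    def test_matches_exact_rational_oracle_small_N(self):
        for N, n1, n2, k in feasible_tables(12):
            exact = float(exact_pvalue(N, n1, n2, k))
            got = hypergeom_pvalue(ContingencyTable(N, n1, n2, k))
            assert got == pytest.approx(exact, rel=1e-12, abs=1e-300)

    @pytest.mark.parametrize("seed", range(20))
    def test_pmf_normalization(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(1, 200))
        n1 = int(rng.integers(0, N + 1))
        n2 = int(rng.integers(0, N + 1))
        total = sum(
            hypergeom_pvalue(ContingencyTable(N, n1, n2, k))
            for k in range(max(0, n1 + n2 - N), min(n1, n2) + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_tail_mode_is_upper_tail_sum(self):
        table = ContingencyTable(N=20, n1=8, n2=10, k=6)
        tail = hypergeom_pvalue(table, tail=True)
        point_sum = sum(
            float(exact_pvalue(20, 8, 10, kk)) for kk in range(6, min(8, 10) + 1)
        )
        assert tail == pytest.approx(point_sum, rel=1e-10)


class TestScoring:
    def _population(self, rng, n=100):
        items = [f"d{j}" for j in range(10)]
        pop = []
        for _ in range(n):
            ante = rng.choice(items, size=int(rng.integers(1, 4)), replace=False)
            cons = rng.choice([i for i in items if i not in ante])
            pop.append(make_rule(list(ante), str(cons)))
        return pop

    def test_scoring_is_order_invariant_and_complete(self):
        rng = np.random.default_rng(0)
        pop = self._population(rng)
        holdout = self._population(np.random.default_rng(1), 30)
        scored = score_rules(holdout, pop)
        assert len(scored) == 30
        shuffled = list(holdout)
        np.random.default_rng(2).shuffle(shuffled)
        scored2 = score_rules(shuffled, pop)
        assert [s.rule.key for s in scored] == [s.rule.key for s in scored2]
        ps = [s.p_value for s in scored]
        assert ps == sorted(ps)

    def test_matched_population_ranks_before_disjoint(self):
        # under the tail test, sides that always co-occur (k = n1 = n2) score
        # lower p than sides never seen together (k = 0, tail probability 1)
        pop = [make_rule(["a"], "b")] * 3 + [make_rule(["c"], "d")] * 17
        strong = make_rule(["a"], "b")
        absent = make_rule(["a"], "d")
        scored = {
            s.rule.key: s.p_value for s in score_rules([strong, absent], pop, tail=True)
        }
        assert scored[strong.key] < scored[absent.key]
        assert scored[absent.key] == pytest.approx(1.0)

    def test_scored_against_enumeration(self):
        rng = np.random.default_rng(3)
        pop = self._population(rng, 50)
        probe = pop[0]
        table = build_contingency(probe, pop)
        expected = hypergeom_pvalue(table)
        scored = score_rules([probe], pop)
        assert scored[0].p_value == pytest.approx(expected, rel=1e-12)


class TestThreshold:
    def test_separable_seed(self):
        seed = [
            (ScoredRule(make_rule(["a"], "b"), 1e-5), True),
            (ScoredRule(make_rule(["a"], "c"), 1e-3), True),
            (ScoredRule(make_rule(["b"], "c"), 0.2), False),
        ]
        thr = tune_threshold(seed)
        assert 1e-3 < thr.value < 0.2
        assert thr.seed_accuracy == 1.0

    def test_all_relevant_threshold_above_max(self):
        seed = [
            (ScoredRule(make_rule(["a"], "b"), 1e-4), True),
            (ScoredRule(make_rule(["a"], "c"), 1e-2), True),
        ]
        thr = tune_threshold(seed)
        assert thr.value > 1e-2
        assert thr.seed_accuracy == 1.0

    def test_accuracy_at_least_majority_class(self):
        rng = np.random.default_rng(7)
        seed = [
            (ScoredRule(make_rule([f"x{i}"], "y"), float(p)), bool(lab))
            for i, (p, lab) in enumerate(
                zip(rng.uniform(1e-8, 1, 40), rng.random(40) < 0.5)
            )
        ]
        labels = [lab for _, lab in seed]
        majority = max(sum(labels), len(labels) - sum(labels)) / len(labels)
        assert tune_threshold(seed).seed_accuracy >= majority

    @pytest.mark.parametrize("seed_int", range(25))
    def test_optimality_vs_dense_scan(self, seed_int):
        rng = np.random.default_rng(seed_int)
        n = int(rng.integers(2, 30))
        ps = rng.uniform(1e-12, 1.0, n)
        labels = rng.random(n) < rng.uniform(0.2, 0.8)
        seed = [
            (ScoredRule(make_rule([f"x{i}"], "y"), float(p)), bool(lab))
            for i, (p, lab) in enumerate(zip(ps, labels))
        ]
        thr = tune_threshold(seed)
        # dense exhaustive scan over a fine grid plus all observed values
        grid = np.concatenate([ps, np.geomspace(1e-13, 1.0, 5000)])
        best = max(((ps < t) == labels).mean() for t in grid)
        assert thr.seed_accuracy == pytest.approx(best)

    def test_empty_seed_errors(self):
        with pytest.raises(ValueError):
            tune_threshold([])

    def test_classification_boundary_is_strict(self):
        thr = PValueThreshold(value=1.12e-13, seed_accuracy=1.0)
        assert classify_by_threshold(ScoredRule(make_rule(["a"], "b"), 1e-14), thr)
        assert not classify_by_threshold(
            ScoredRule(make_rule(["a"], "b"), 1.12e-13), thr
        )
        assert not classify_by_threshold(ScoredRule(make_rule(["a"], "b"), 0.5), thr)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.data())
def test_pvalue_in_unit_interval_property(data):
    N = data.draw(st.integers(1, 60))
    n1 = data.draw(st.integers(0, N))
    n2 = data.draw(st.integers(0, N))
    k = data.draw(st.integers(max(0, n1 + n2 - N), min(n1, n2)))
    p = hypergeom_pvalue(ContingencyTable(N, n1, n2, k))
    assert 0 < p <= 1
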