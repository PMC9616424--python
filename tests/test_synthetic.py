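"""Synthetic-cohort generator tests: determinism, planted signal, label oracle."""

import numpy as np
import pytest

from extrae.mining import AssociationRule
from extrae.synthetic import (
    DiseaseOntology,
    PlantedRelation,
    generate_araids_like,
    generate_ontology,
    generate_planted_relations,
    generate_transactions,
    oracle_label,
)


def make_rule(antecedent, consequent):
    return AssociationRule(
        antecedent=frozenset(antecedent),
        consequent=frozenset([consequent]),
        support=0.1,
        confidence=0.8,
        lift=2.0,
    )


class TestOntology:
    def test_default_shape_and_invariants(self):
        ont = generate_ontology(141, rng_seed=1)
        assert len(ont.diseases) == 141
        assert all(0 < d.prevalence < 1 for d in ont.diseases)
        lex = ont.lexicons()
        assert len(lex.adverse_events) == 34
        assert len(lex.causes_of_death) == 123
        assert all(code[0].isalpha() for code in lex.icd10_map.values())

    def test_minimal_ontology(self):
        ont = generate_ontology(2, rng_seed=0)
        assert len(ont.diseases) == 2

    def test_seeded_determinism(self):
        a = generate_ontology(50, rng_seed=3)
        b = generate_ontology(50, rng_seed=3)
        assert a.diseases == b.diseases
        assert a.generalizations == b.generalizations

    def test_generalization_links_are_acyclic_one_level(self):
        ont = generate_ontology(141, rng_seed=2)
        generals = set(ont.generalizations.values())
        specifics = set(ont.generalizations)
        assert not (generals & specifics)

    def test_cycle_rejected(self):
        ont = generate_ontology(4, rng_seed=0)
        names = ont.names
        with pytest.raises(ValueError, match="cycle"):
            DiseaseOntology(
                diseases=ont.diseases,
                generalizations={names[0]: names[1], names[1]: names[0]},
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            generate_ontology(10, rng_seed=0, config={"prevalence_low": 0.5, "prevalence_high": 0.1})


class TestTransactions:
    def test_neutral_strength_gives_unit_lift(self):
        ont = generate_ontology(30, rng_seed=5, config={"generalization_fraction": 0.0})
        names = ont.names
        planted = [PlantedRelation(frozenset(names[:2]), strength=1.0)]
        db = generate_transactions(ont, planted, n_patients=20000, rng_seed=6)
        a, b = names[0], names[1]
        has_a = np.array([a in t.items for t in db])
        has_b = np.array([b in t.items for t in db])
        p_b = has_b.mean()
        p_b_given_a = has_b[has_a].mean()
        assert p_b_given_a == pytest.approx(p_b, abs=0.05)

    def test_planted_strength_raises_conditional_probability(self):
        ont = generate_ontology(30, rng_seed=7, config={"generalization_fraction": 0.0})
        names = ont.names
        pair = frozenset(names[:2])
        planted = [PlantedRelation(pair, strength=10.0)]
        db = generate_transactions(ont, planted, n_patients=20000, rng_seed=8)
        a, b = sorted(pair)
        p_b = np.mean([b in t.items for t in db])
        has_a = np.array([a in t.items for t in db])
        has_b = np.array([b in t.items for t in db])
        target = min(1.0, 10.0 * float(dict((d.name, d.prevalence) for d in ont.diseases)[b]))
        assert has_b[has_a].mean() == pytest.approx(target, rel=0.25)
        assert has_b[has_a].mean() > 3 * p_b or target == 1.0

    def test_generalization_closure_holds_everywhere(self):
        ont = generate_ontology(50, rng_seed=9, config={"generalization_fraction": 0.2})
        db = generate_transactions(ont, [], n_patients=2000, rng_seed=10)
        for t in db:
            for spec, gen in ont.generalizations.items():
                if spec in t.items:
                    assert gen in t.items

    def test_determinism(self):
        ont = generate_ontology(20, rng_seed=0)
        planted = generate_planted_relations(ont, n_pairs=5, rng_seed=1)
        db1 = generate_transactions(ont, planted, n_patients=500, rng_seed=2)
        db2 = generate_transactions(ont, planted, n_patients=500, rng_seed=2)
        assert db1.item_sets() == db2.item_sets()


class TestOracleLabel:
    @pytest.fixture
    def setting(self):
        ont = generate_ontology(20, rng_seed=4)
        names = ont.names
        # remove generated links, install a known one: names[5] specializes names[6]
        ont.generalizations.clear()
        ont.generalizations[names[5]] = names[6]
        planted = [PlantedRelation(frozenset((names[0], names[1])), 3.0)]
        return ont, planted, names

    def test_any_related_antecedent_suffices(self, setting):
        ont, planted, n = setting
        rule = make_rule([n[0], n[2], n[3]], n[1])  # only n[0] is related to n[1]
        assert oracle_label(rule, ont, planted)

    def test_direction_is_ignored(self, setting):
        ont, planted, n = setting
        assert oracle_label(make_rule([n[1]], n[0]), ont, planted)
        assert oracle_label(make_rule([n[0]], n[1]), ont, planted)

    def test_unrelated_rule_is_false(self, setting):
        ont, planted, n = setting
        assert not oracle_label(make_rule([n[2], n[3]], n[4]), ont, planted)

    def test_generalization_counts_both_ways(self, setting):
        ont, planted, n = setting
        assert oracle_label(make_rule([n[5]], n[6]), ont, planted)
        assert oracle_label(make_rule([n[6]], n[5]), ont, planted)

    def test_antecedent_antecedent_relations_ignored(self, setting):
        ont, planted, n = setting
        # n[0]-n[1] planted, but both sit in the antecedent; consequent unrelated
        assert not oracle_label(make_rule([n[0], n[1]], n[4]), ont, planted)

    def test_pure_function(self, setting):
        ont, planted, n = setting
        rule = make_rule([n[0]], n[1])
        assert all(oracle_label(rule, ont, planted) for _ in range(3))


class TestPlantedSignalRecovery:
    def test_planted_pair_rules_score_lower_than_matched_flukes(self):
        """Rules over planted pairs recur across cohort halves, so their tail
        p-values rank systematically below those of unrelated rules."""
        from scipy.stats import mannwhitneyu

        from extrae.mining import mine_rules
        from extrae.significance import score_rules, split_exploratory_holdout

        ont = generate_ontology(60, rng_seed=3, config={"generalization_fraction": 0.0})
        planted = generate_planted_relations(ont, n_pairs=20, rng_seed=4)
        db = generate_transactions(ont, planted, n_patients=8000, rng_seed=5)
        explor, hold = split_exploratory_holdout(db, 0.5, seed=6)
        min_supp = 2 / explor.N
        explor_rules = mine_rules(explor, min_support=min_supp, min_confidence=0.3,
                                  max_antecedent_len=2)
        hold_rules = mine_rules(hold, min_support=min_supp, min_confidence=0.3,
                                max_antecedent_len=2)
        scored = score_rules(hold_rules, explor_rules, tail=True)
        planted_p = [s.p_value for s in scored if oracle_label(s.rule, ont, planted)]
        other_p = [s.p_value for s in scored if not oracle_label(s.rule, ont, planted)]
        assert len(planted_p) >= 5 and len(other_p) >= 5
        stat = mannwhitneyu(planted_p, other_p, alternative="less")
        assert stat.pvalue < 1e-3


@pytest.fixture(scope="module")
def small_benchmark():
    """Down-scaled cohort so the full generation path stays fast."""
    ont = generate_ontology(60, rng_seed=11)
    planted = generate_planted_relations(ont, n_pairs=25, rng_seed=12)
    labeled, db = generate_araids_like(
        ont,
        planted,
        target_n_rules=200,
        target_relevant_fraction=0.613,
        rng_seed=13,
        n_patients=6000,
    )
    return ont, planted, labeled, db


class TestAraidsLike:

    def test_target_size_and_balance(self, small_benchmark):
        _, _, labeled, _ = small_benchmark
        assert len(labeled) == 200
        frac = np.mean([lr.label for lr in labeled])
        assert frac == pytest.approx(0.613, abs=0.05)

    def test_rule_shape(self, small_benchmark):
        _, _, labeled, _ = small_benchmark
        assert all(1 <= len(lr.rule.antecedent) <= 4 for lr in labeled)
        assert all(len(lr.rule.consequent) == 1 for lr in labeled)

    def test_labels_match_oracle(self, small_benchmark):
        ont, planted, labeled, _ = small_benchmark
        for lr in labeled[::17]:
            assert lr.label == oracle_label(lr.rule, ont, planted)

    def test_deterministic(self, small_benchmark):
        ont, planted, labeled, db = small_benchmark
        again, _ = generate_araids_like(
            ont, planted, target_n_rules=200, target_relevant_fraction=0.613,
            rng_seed=13, n_patients=6000,
        )
        assert [(lr.rule.key, lr.label) for lr in labeled] == [
            (lr.rule.key, lr.label) for lr in again
        ]

    def test_infeasible_target_raises_with_hint(self, small_benchmark):
        ont, planted, _, db = small_benchmark
        with pytest.raises(ValueError, match="adjust|raise|lower"):
            generate_araids_like(
                ont, planted, target_n_rules=10**6, rng_seed=1, db=db
            )
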