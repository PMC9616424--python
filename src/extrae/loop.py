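"""Semi-supervised agreement loop (EXTRAE).

Starting from a small annotated seed, each iteration (1) trains the
random-forest on the current seed, (2) re-calibrates the p-value threshold
of the significance filter on the same seed, (3) predicts relevance on the
remaining development rules with both components, and (4) moves the
*coincident* rules — those on which the two predictions agree — into the
seed with the agreed label as a pseudo-label.  The loop stops when no
coincident rule remains or the development set is exhausted.  Each
productive iteration strictly shrinks the development set, so termination
is guaranteed in at most |development| iterations; a safety cap guards the
unproductive-loop case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from . import classifier as clf
from .features import LexiconSet, feature_matrix
from .mining import AssociationRule, rule_sort_key
from .significance import (
    PValueThreshold,
    RulePopulation,
    ScoredRule,
    hypergeom_pvalue,
    tune_threshold,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class LabeledRule:
    """An association rule with its (expert or oracle) relevance label."""

    rule: AssociationRule
    label: bool


@dataclass(frozen=True, slots=True)
class SeedEntry:
    rule: AssociationRule
    label: bool
    provenance: str  # "annotated" | "pseudo"


@dataclass
class LoopTrace:
    """Per-iteration record of the self-training run."""

    records: list[dict[str, Any]] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    @property
    def coincident_counts(self) -> list[int]:
        return [r["coincident_rules"] for r in self.records]


def select_seed(
    training_rules: Sequence[LabeledRule],
    size: int,
    rng_seed: int = 0,
    stratified: bool = True,
) -> tuple[list[SeedEntry], list[LabeledRule]]:
    """Draw the annotated seed; the rest becomes the development set.

    Development labels are carried along only for tracing/evaluation — the
    loop itself never reads them.  Stratified selection matches the seed's
    class ratio to the pool's within one rule.
    """
    pool = list(training_rules)
    if size > len(pool):
        raise ValueError(f"seed size {size} exceeds available rules ({len(pool)})")
    if size < 1:
        raise ValueError("seed size must be at least 1")
    rng = np.random.default_rng(rng_seed)
    if stratified:
        pos = [i for i, lr in enumerate(pool) if lr.label]
        neg = [i for i, lr in enumerate(pool) if not lr.label]
        if not pos or not neg:
            raise ValueError("stratified seed selection requires both classes")
        n_pos = int(round(size * len(pos) / len(pool)))
        n_pos = min(max(n_pos, 1), size - 1, len(pos))
        n_neg = size - n_pos
        if n_neg > len(neg):
            raise ValueError("not enough negative rules for a stratified seed")
        chosen = set(rng.choice(pos, size=n_pos, replace=False).tolist())
        chosen |= set(rng.choice(neg, size=n_neg, replace=False).tolist())
    else:
        chosen = set(rng.choice(len(pool), size=size, replace=False).tolist())
    seed = [
        SeedEntry(pool[i].rule, pool[i].label, "annotated") for i in sorted(chosen)
    ]
    development = [lr for i, lr in enumerate(pool) if i not in chosen]
    return seed, development


def _pvalue_lookup(
    rules: Sequence[AssociationRule],
    exploratory_rules: Sequence[AssociationRule],
    pvalues: Mapping | None,
    tail: bool = False,
) -> dict:
    """p-value per rule key, computed against the exploratory population unless given."""
    if pvalues is not None:
        return dict(pvalues)
    population = (
        exploratory_rules
        if isinstance(exploratory_rules, RulePopulation)
        else RulePopulation(exploratory_rules)
    )
    return {
        r.key: hypergeom_pvalue(population.contingency(r), tail=tail) for r in rules
    }


def iterate_once(
    seed: Sequence[SeedEntry],
    development: Sequence[LabeledRule],
    exploratory_rules: Sequence[AssociationRule],
    lexicons: LexiconSet | None = None,
    hyperparams: Mapping[str, Any] | None = None,
    rng_seed: int = 0,
    pvalues: Mapping | None = None,
) -> tuple[list[SeedEntry], list[LabeledRule], int, PValueThreshold]:
    """One agreement round; returns (new_seed, remaining_development,
    coincident_count, threshold)."""
    if not seed:
        raise ValueError("empty seed set")
    lexicons = lexicons or LexiconSet.empty()
    all_rules = [e.rule for e in seed] + [lr.rule for lr in development]
    pmap = _pvalue_lookup(all_rules, exploratory_rules, pvalues)

    seed_X = feature_matrix([e.rule for e in seed], lexicons).to_numpy()
    seed_y = [e.label for e in seed]
    model = clf.train(seed_X, seed_y, hyperparams=hyperparams, rng_seed=rng_seed)
    threshold = tune_threshold(
        [(ScoredRule(e.rule, pmap[e.rule.key]), e.label) for e in seed]
    )
    if not development:
        return list(seed), [], 0, threshold

    dev_X = feature_matrix([lr.rule for lr in development], lexicons).to_numpy()
    sup_pred, _ = clf.predict(model, dev_X)
    unsup_pred = np.array(
        [pmap[lr.rule.key] < threshold.value for lr in development], dtype=bool
    )
    agree = sup_pred == unsup_pred

    new_seed = list(seed)
    seed_keys = {e.rule.key for e in seed}
    remaining: list[LabeledRule] = []
    moved = 0
    for i, lr in enumerate(development):
        if agree[i] and lr.rule.key not in seed_keys:
            new_seed.append(SeedEntry(lr.rule, bool(sup_pred[i]), "pseudo"))
            seed_keys.add(lr.rule.key)
            moved += 1
        else:
            remaining.append(lr)
    return new_seed, remaining, moved, threshold


def run_extrae(
    training_rules: Sequence[LabeledRule],
    exploratory_rules: Sequence[AssociationRule],
    seed_size: int = 35,
    lexicons: LexiconSet | None = None,
    hyperparams: Mapping[str, Any] | None = None,
    rng_seed: int = 0,
    stratified: bool = True,
    max_iterations: int = 100,
    pvalues: Mapping | None = None,
    trace_metrics: bool = False,
) -> tuple[clf.RelevanceModel, PValueThreshold, LoopTrace]:
    """Run the full self-training loop until the coincident set is empty.

    ``pvalues`` may carry precomputed p-values (rule key -> p) to avoid
    re-scoring; otherwise they are computed from ``exploratory_rules``.
    With ``trace_metrics``, each record also reports the model's F-measure
    on the remaining development rules against their withheld labels.
    """
    lexicons = lexicons or LexiconSet.empty()
    rng = np.random.default_rng(rng_seed)
    seed_sel, iter_seed = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
    seed, development = select_seed(
        training_rules, seed_size, rng_seed=seed_sel, stratified=stratified
    )
    all_rules = [lr.rule for lr in training_rules]
    pmap = _pvalue_lookup(all_rules, exploratory_rules, pvalues)

    trace = LoopTrace()
    threshold = tune_threshold(
        [(ScoredRule(e.rule, pmap[e.rule.key]), e.label) for e in seed]
    )
    total = len(seed) + len(development)
    if development:
        for iteration in range(1, max_iterations + 1):
            seed, development, moved, threshold = iterate_once(
                seed,
                development,
                exploratory_rules,
                lexicons=lexicons,
                hyperparams=hyperparams,
                rng_seed=iter_seed,
                pvalues=pmap,
            )
            assert len(seed) + len(development) == total, "rule conservation violated"
            record = {
                "iteration": iteration,
                "coincident_rules": moved,
                "threshold": threshold.value,
                "seed_size": len(seed),
                "development_remaining": len(development),
            }
            if trace_metrics and development:
                dev_X = feature_matrix(
                    [lr.rule for lr in development], lexicons
                ).to_numpy()
                seed_X = feature_matrix([e.rule for e in seed], lexicons).to_numpy()
                probe = clf.train(
                    seed_X, [e.label for e in seed], hyperparams=hyperparams,
                    rng_seed=iter_seed,
                )
                pred, _ = clf.predict(probe, dev_X)
                from .evaluation import f_measure  # local import avoids a cycle

                record["dev_f_measure"] = f_measure(
                    pred, [lr.label for lr in development]
                )
            trace.records.append(record)
            # An iteration that empties the development set is followed by one
            # more (trivial) round so the trace ends on a zero coincident count.
            if moved == 0:
                break
        else:
            logger.warning(
                "self-training stopped at the max_iterations cap (%d) with %d "
                "development rules remaining",
                max_iterations,
                len(development),
            )

    # Final model trained on the final seed.
    seed_X = feature_matrix([e.rule for e in seed], lexicons).to_numpy()
    model = clf.train(
        seed_X, [e.label for e in seed], hyperparams=hyperparams, rng_seed=iter_seed
    )
    threshold = tune_threshold(
        [(ScoredRule(e.rule, pmap[e.rule.key]), e.label) for e in seed]
    )
    return model, threshold, trace
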