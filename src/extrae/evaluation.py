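"""Metrics and the fivefold cross-validation harness.

F-measure is the harmonic mean of precision and recall on the relevant
class; AUC-ROC is the area under the receiver-operating-characteristic
curve (equal to the Mann-Whitney concordance probability); AU-PRC is the
area under the precision-recall curve using right-continuous step
interpolation (average-precision style).  Cross-validation is stratified
by label and compares three modes: the full semi-supervised loop, a
supervised-only forest, and the threshold-only unsupervised filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import classifier as clf
from .features import LexiconSet, feature_matrix
from .loop import LabeledRule, run_extrae, select_seed
from .mining import TransactionDB, mine_rules
from .significance import (
    PValueThreshold,
    ScoredRule,
    score_rules,
    split_exploratory_holdout,
    tune_threshold,
)


def _check_lengths(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty input")
    return a, b


def f_measure(predictions: Sequence[bool], labels: Sequence[bool]) -> float:
    """Harmonic mean of precision and recall on the relevant class (0 if undefined)."""
    pred, lab = _check_lengths(np.asarray(predictions, dtype=bool), labels)
    tp = int((pred & lab).sum())
    fp = int((pred & ~lab).sum())
    fn = int((~pred & lab).sum())
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def f_measure_weighted(predictions: Sequence[bool], labels: Sequence[bool]) -> float:
    """Prevalence-weighted mean of the per-class F-measures.

    This is the headline convention of several ML toolkits; a
    majority-class predictor scores poorly here (the minority class
    contributes an F of 0), unlike the relevant-class F-measure.
    """
    pred, lab = _check_lengths(np.asarray(predictions, dtype=bool), labels)
    f_pos = f_measure(pred, lab)
    f_neg = f_measure(~pred, ~lab)
    w = lab.mean()
    return w * f_pos + (1 - w) * f_neg


def auc_roc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve; requires both classes."""
    s, lab = _check_lengths(scores, labels)
    if lab.all() or not lab.any():
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(lab, s))


def au_prc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the precision-recall curve (step-wise / average precision)."""
    s, lab = _check_lengths(scores, labels)
    if not lab.any():
        raise ValueError("AU-PRC undefined: no positive labels")
    return float(average_precision_score(lab, s))


@dataclass
class EvaluationReport:
    """Per-fold and mean metrics of one cross-validated configuration."""

    mode: str
    fold_metrics: pd.DataFrame  # columns: fold, f_measure, auc_roc, au_prc, ...
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def means(self) -> dict[str, float]:
        cols = [c for c in self.fold_metrics.columns if c != "fold"]
        return {c: float(self.fold_metrics[c].mean()) for c in cols}

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "mode": self.mode,
            "config": self.config,
            "folds": self.fold_metrics.to_dict(orient="records"),
            "means": self.means,
        }


Mode = Literal["extrae", "supervised_only", "unsupervised_only"]

DEFAULT_MINING = {"min_support": 0.0001, "min_confidence": 0.6}


def _safe_curve_metrics(scores, labels) -> tuple[float, float]:
    lab = np.asarray(labels, dtype=bool)
    roc = auc_roc(scores, lab) if (lab.any() and not lab.all()) else float("nan")
    prc = au_prc(scores, lab) if lab.any() else float("nan")
    return roc, prc


def cross_validate(
    labeled_rules: Sequence[LabeledRule],
    transactions: TransactionDB,
    k: int = 5,
    seed_size: int = 35,
    rng_seed: int = 0,
    mode: Mode = "extrae",
    lexicons: LexiconSet | None = None,
    mining_params: Mapping[str, float] | None = None,
    supervised_full_fold: bool = False,
    max_iterations: int = 100,
    exploratory_rules: Sequence | None = None,
    pvalues: Mapping | None = None,
    tail: bool = True,
) -> EvaluationReport:
    """Stratified k-fold evaluation of one system mode.

    Per fold the system is built on the training 80% and scored on the held
    out 20%.  ``supervised_only`` trains either on a random ``seed_size``
    subset of the fold or, with ``supervised_full_fold``, on the entire
    training fold.  ``unsupervised_only`` calibrates the p-value threshold
    on the training fold and classifies the test fold by it.

    ``exploratory_rules`` and ``pvalues`` (rule key -> p) can carry
    precomputed significance inputs so repeated evaluations on the same
    cohort do not re-mine the exploratory half.  Scoring defaults to the
    one-sided tail probability P(K >= k) — the probability of a table at
    least as extreme, which is monotone in observed co-occurrence; the
    point probability is available with ``tail=False``.
    """
    rules = list(labeled_rules)
    if len(rules) < k:
        raise ValueError(f"need at least k={k} labeled rules, got {len(rules)}")
    lexicons = lexicons or LexiconSet.empty()
    mining = dict(DEFAULT_MINING)
    mining.update(mining_params or {})
    rng = np.random.default_rng(rng_seed)
    split_seed, fold_seed = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))

    # Exploratory rule population for the significance component, fixed for
    # all folds: mine the exploratory transaction half at the same thresholds.
    if pvalues is not None:
        pvalue_by_key = dict(pvalues)
        exploratory_rules = exploratory_rules if exploratory_rules is not None else []
    else:
        if exploratory_rules is None:
            explor_db, _ = split_exploratory_holdout(transactions, 0.5, seed=split_seed)
            # The significance population needs co-occurrence counts of at
            # least 2: a support fraction that rounds to a single transaction
            # would admit every observed sub-itemset and carry no signal.
            explor_mining = dict(mining)
            explor_mining["min_support"] = max(
                mining["min_support"], 2 / explor_db.N
            )
            exploratory_rules = mine_rules(
                explor_db, max_antecedent_len=4, **explor_mining
            )
        scored = score_rules([lr.rule for lr in rules], exploratory_rules, tail=tail)
        pvalue_by_key = {s.rule.key: s.p_value for s in scored}

    features = feature_matrix([lr.rule for lr in rules], lexicons).to_numpy()
    labels = np.array([lr.label for lr in rules], dtype=bool)

    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed % 2**32)
    records: list[dict[str, Any]] = []
    for fold, (train_idx, test_idx) in enumerate(folds.split(features, labels)):
        fold_rng = np.random.default_rng((rng_seed, fold))
        inner_seed = int(fold_rng.integers(0, 2**31 - 1))
        train_rules = [rules[i] for i in train_idx]
        record: dict[str, Any] = {"fold": fold}
        if mode == "extrae":
            model, threshold, trace = run_extrae(
                train_rules,
                exploratory_rules,
                seed_size=seed_size,
                lexicons=lexicons,
                rng_seed=inner_seed,
                pvalues=pvalue_by_key,
                max_iterations=max_iterations,
            )
            pred, score = clf.predict(model, features[test_idx])
            record["iterations"] = trace.n_iterations
            record["threshold"] = threshold.value
        elif mode == "supervised_only":
            if supervised_full_fold:
                chosen = list(range(len(train_rules)))
            else:
                seed_set, _ = select_seed(
                    train_rules, seed_size, rng_seed=inner_seed, stratified=True
                )
                key_to_idx = {lr.rule.key: i for i, lr in enumerate(train_rules)}
                chosen = [key_to_idx[e.rule.key] for e in seed_set]
            sub_idx = train_idx[chosen]
            model = clf.train(
                features[sub_idx], labels[sub_idx], rng_seed=inner_seed
            )
            pred, score = clf.predict(model, features[test_idx])
        elif mode == "unsupervised_only":
            seed_pairs = [
                (
                    ScoredRule(lr.rule, pvalue_by_key[lr.rule.key]),
                    lr.label,
                )
                for lr in train_rules
            ]
            threshold = tune_threshold(seed_pairs)
            p_test = np.array([pvalue_by_key[rules[i].rule.key] for i in test_idx])
            pred = p_test < threshold.value
            score = 1.0 - p_test  # monotone in significance
            record["threshold"] = threshold.value
        else:
            raise ValueError(f"unknown mode {mode!r}")
        test_labels = labels[test_idx]
        record["f_measure"] = f_measure(pred, test_labels)
        record["f_measure_weighted"] = f_measure_weighted(pred, test_labels)
        record["auc_roc"], record["au_prc"] = _safe_curve_metrics(score, test_labels)
        records.append(record)

    report = EvaluationReport(
        mode=mode,
        fold_metrics=pd.DataFrame.from_records(records),
        config={
            "k": k,
            "seed_size": seed_size,
            "rng_seed": rng_seed,
            "mining": mining,
            "supervised_full_fold": supervised_full_fold,
            "n_exploratory_rules": len(exploratory_rules),
        },
    )
    return report
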