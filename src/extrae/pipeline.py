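"""End-to-end orchestration: cohort -> mining -> significance -> loop -> report.

``run_pipeline`` executes the whole study from one configuration: load (or
synthesize) the transaction cohort, split it, mine rules in both halves,
score the labeled rules against the exploratory population, run the
cross-validated evaluation of the semi-supervised loop and its two
component baselines, and write every intermediate artifact plus a
reproducibility manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__, io, synthetic
from .config import PipelineConfig
from .evaluation import EvaluationReport, cross_validate
from .features import LexiconSet
from .mining import mine_rules
from .significance import score_rules, split_exploratory_holdout

logger = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig) -> dict[str, EvaluationReport]:
    """Run the full study; returns the evaluation report per system mode."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    mining = {
        "min_support": config.min_support,
        "min_confidence": config.min_confidence,
    }

    # --- stage: cohort -----------------------------------------------------
    exploratory_rules = None
    if config.transactions:
        db = io.read_transactions(config.transactions)
        lexicons = (
            io.read_lexicons(config.lexicons) if config.lexicons else LexiconSet.empty()
        )
        if config.labeled_rules:
            labeled = io.read_labeled_rules(config.labeled_rules)
        else:
            raise ValueError(
                "a labeled-rule file is required when transactions are supplied"
            )
        logger.info("stage=cohort loaded N=%d labeled_rules=%d", db.N, len(labeled))
    else:
        bench = synthetic.generate_benchmark(
            rng_seed=config.stage_seed("synthetic"),
            n_diseases=config.n_diseases,
            n_patients=config.n_patients,
            n_planted=config.n_planted,
            strength_range=(config.strength_low, config.strength_high),
            target_n_rules=config.target_n_rules,
            target_relevant_fraction=config.target_relevant_fraction,
            mining_params=mining,
        )
        db, labeled, lexicons = bench.transactions, bench.labeled_rules, bench.lexicons
        exploratory_rules = bench.exploratory_population
        io.write_transactions(db, out / "transactions.tsv")
        io.write_labeled_rules(labeled, out / "labeled_rules.tsv")
        io.write_lexicons(lexicons, out / "lexicons")
        logger.info(
            "stage=cohort synthetic N=%d labeled_rules=%d", db.N, len(labeled)
        )

    # --- stage: split + mine + score --------------------------------------
    if exploratory_rules is None:
        split_seed = config.stage_seed("split")
        explor_db, holdout_db = split_exploratory_holdout(
            db, config.split_fraction, seed=split_seed
        )
        # Keep the significance population informative: require co-occurrence
        # counts of at least 2 whatever the support fraction implies at this N.
        explor_mining = dict(mining)
        explor_mining["min_support"] = max(config.min_support, 2 / explor_db.N)
        exploratory_rules = mine_rules(
            explor_db, max_antecedent_len=config.max_antecedent_len, **explor_mining
        )
    logger.info("stage=mine exploratory_rules=%d", len(exploratory_rules))
    scored = score_rules([lr.rule for lr in labeled], exploratory_rules, tail=True)
    io.write_scored_rules(scored, out / "scored_rules.tsv")
    pvalues = {s.rule.key: s.p_value for s in scored}

    # --- stage: cross-validated evaluation ---------------------------------
    reports: dict[str, EvaluationReport] = {}
    for mode, extra in (
        ("extrae", {}),
        ("supervised_only", {}),
        ("supervised_full", {"supervised_full_fold": True}),
        ("unsupervised_only", {}),
    ):
        base_mode = "supervised_only" if mode == "supervised_full" else mode
        report = cross_validate(
            labeled,
            db,
            k=config.k_folds,
            seed_size=config.seed_size,
            rng_seed=config.stage_seed(f"cv-{mode}"),
            mode=base_mode,
            lexicons=lexicons,
            mining_params=mining,
            max_iterations=config.max_iterations,
            exploratory_rules=exploratory_rules,
            pvalues=pvalues,
            **extra,
        )
        reports[mode] = report
        report.fold_metrics.to_csv(out / f"report_{mode}.csv", index=False)
        logger.info("stage=evaluate mode=%s means=%s", mode, report.means)

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(
            {mode: rep.to_json_dict() for mode, rep in reports.items()},
            fh,
            indent=2,
            default=float,
        )
        fh.write("\n")
    io.write_manifest(
        out / "manifest.json",
        version=__version__,
        config=config.to_dict(),
        stage_seeds={
            stage: config.stage_seed(stage)
            for stage in ["synthetic", "split"]
            + [f"cv-{m}" for m in reports]
        },
        n_transactions=db.N,
        n_labeled_rules=len(labeled),
        n_exploratory_rules=len(exploratory_rules),
    )
    return reports
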