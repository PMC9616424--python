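"""Synthetic patient-diagnosis cohorts with planted disease relationships.

Real HIV-cohort diagnosis data is access-restricted, so every stage of the
pipeline is exercised on generated data that reproduces its *shape*: a few
hundred distinct disorders with widely varying prevalence, patients carrying
small sets of co-occurring diagnoses, a handful of genuinely related disease
pairs, and generalization links (a specific disorder implying its catch-all
category, e.g. a specific neoplasm entailing a generic "neoplasm" item).

The generative model is deliberately simple and controllable: each patient
draws diseases as independent Bernoulli variables at per-disease baseline
prevalence; for each *planted* pair the conditional probability of one
member given the other is multiplied by a relative-risk strength (capped at
1); generalization items are added whenever one of their specializations is
present.  A relevance oracle labels a mined rule as relevant exactly when
some antecedent item has a planted relation with the consequent (direction
ignored) or generalizes/specializes it — antecedent-antecedent relations do
not count, and one related pair suffices even when other items are noise.

Defaults emulate the annotated reference collection this package targets:
~1000 labeled rules with ~61.3% relevant, 1-4 antecedents, one consequent,
141 distinct disorders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .features import LexiconSet
from .loop import LabeledRule
from .mining import AssociationRule, Transaction, TransactionDB, iter_rules, mine_rules

_ICD_LETTERS = "ABCDEFGHIJKLMNR"  # disease chapters; external-cause letters unused


@dataclass(frozen=True)
class Disease:
    name: str
    prevalence: float
    icd10: str
    in_cdc: bool
    is_adverse: bool
    cod_index: int | None  # position in the cause-of-death list, if any


@dataclass
class DiseaseOntology:
    """Disease universe: prevalences, generalization links and lexicon flags."""

    diseases: list[Disease]
    generalizations: dict[str, str]  # specific -> general disease name

    def __post_init__(self) -> None:
        names = {d.name for d in self.diseases}
        for spec, gen in self.generalizations.items():
            if spec not in names or gen not in names:
                raise ValueError(f"generalization link {spec!r}->{gen!r} off-ontology")
        # acyclicity check via repeated parent walking
        for start in self.generalizations:
            seen, node = set(), start
            while node in self.generalizations:
                if node in seen:
                    raise ValueError(f"generalization cycle through {start!r}")
                seen.add(node)
                node = self.generalizations[node]

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.diseases]

    def generalization_closure(self, name: str) -> set[str]:
        """All (transitive) generalizations of a disease."""
        out, node = set(), name
        while node in self.generalizations:
            node = self.generalizations[node]
            out.add(node)
        return out

    def related_by_generalization(self, a: str, b: str) -> bool:
        return b in self.generalization_closure(a) or a in self.generalization_closure(b)

    def lexicons(self) -> LexiconSet:
        """Lexicon files implied by the ontology's flags."""
        cod = sorted(
            (d for d in self.diseases if d.cod_index is not None),
            key=lambda d: d.cod_index,
        )
        return LexiconSet.from_terms(
            cdc_terms=[d.name for d in self.diseases if d.in_cdc],
            disease_terms=[d.name for d in self.diseases],
            adverse_events=[d.name for d in self.diseases if d.is_adverse],
            causes_of_death=[d.name for d in cod],
            icd10_map={d.name: d.icd10 for d in self.diseases},
        )


@dataclass(frozen=True)
class PlantedRelation:
    """A genuinely related disease pair with a relative-risk multiplier > 1."""

    pair: frozenset[str]
    strength: float

    def __post_init__(self) -> None:
        if len(self.pair) != 2:
            raise ValueError("planted relation needs two distinct diseases")
        if self.strength <= 0:
            raise ValueError("strength must be positive")


DEFAULT_ONTOLOGY_CONFIG: dict[str, float] = {
    "prevalence_low": 0.002,
    "prevalence_high": 0.2,
    "generalization_fraction": 0.10,
    "cdc_fraction": 0.4,
    "n_adverse": 34,
    "n_causes_of_death": 123,
}


def generate_ontology(
    n_diseases: int = 141,
    rng_seed: int = 0,
    config: Mapping[str, float] | None = None,
) -> DiseaseOntology:
    """Reproducible disease universe with log-uniform prevalences and lexicon flags."""
    if n_diseases < 2:
        raise ValueError("need at least 2 diseases")
    cfg = dict(DEFAULT_ONTOLOGY_CONFIG)
    cfg.update(config or {})
    lo, hi = cfg["prevalence_low"], cfg["prevalence_high"]
    if not (0 < lo < hi < 1):
        raise ValueError(f"invalid prevalence range ({lo}, {hi})")
    if not (0 <= cfg["generalization_fraction"] < 0.5):
        raise ValueError("generalization_fraction must lie in [0, 0.5)")
    rng = np.random.default_rng(rng_seed)
    prevalences = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_diseases))
    letters = rng.choice(list(_ICD_LETTERS), size=n_diseases)
    codes = [f"{letters[i]}{rng.integers(0, 100):02d}" for i in range(n_diseases)]
    in_cdc = rng.random(n_diseases) < cfg["cdc_fraction"]
    n_adv = min(int(cfg["n_adverse"]), n_diseases)
    adverse_idx = set(rng.choice(n_diseases, size=n_adv, replace=False).tolist())
    n_cod = min(int(cfg["n_causes_of_death"]), n_diseases)
    cod_order = rng.choice(n_diseases, size=n_cod, replace=False)
    cod_index = {int(d): i for i, d in enumerate(cod_order)}

    diseases = [
        Disease(
            name=f"disorder {i:03d}",
            prevalence=float(prevalences[i]),
            icd10=codes[i],
            in_cdc=bool(in_cdc[i]),
            is_adverse=i in adverse_idx,
            cod_index=cod_index.get(i),
        )
        for i in range(n_diseases)
    ]

    # One-level generalization links: a fraction of diseases specialize into
    # designated general (catch-all) diseases; generals are never specifics.
    n_links = int(round(cfg["generalization_fraction"] * n_diseases))
    generalizations: dict[str, str] = {}
    if n_links:
        pool = rng.permutation(n_diseases)
        n_general = max(1, n_links // 3)
        generals = pool[:n_general]
        specifics = pool[n_general : n_general + n_links]
        for i, spec in enumerate(specifics):
            generalizations[diseases[int(spec)].name] = diseases[
                int(generals[i % n_general])
            ].name
    return DiseaseOntology(diseases=diseases, generalizations=generalizations)


def generate_planted_relations(
    ontology: DiseaseOntology,
    n_pairs: int = 60,
    strength_range: tuple[float, float] = (2.0, 8.0),
    rng_seed: int = 0,
    exclude: Sequence[frozenset[str]] = (),
    chapter_pairs: Sequence[frozenset[str]] | None = None,
) -> list[PlantedRelation]:
    """Random related pairs, avoiding generalization links and ``exclude`` pairs.

    With ``chapter_pairs`` (unordered pairs of ICD-10 first letters), pair
    members must fall in one of the given chapter combinations — genuine
    comorbidity relations cluster within and between specific organ
    systems, which is also what makes them learnable from chapter-count
    features.
    """
    rng = np.random.default_rng(rng_seed)
    names = ontology.names
    letter = {d.name: d.icd10[0].upper() for d in ontology.diseases}
    allowed = None if chapter_pairs is None else {frozenset(p) for p in chapter_pairs}
    chosen: set[frozenset[str]] = set(exclude)
    out: list[PlantedRelation] = []
    attempts = 0
    while len(out) < n_pairs:
        attempts += 1
        if attempts > 1000 * n_pairs:
            raise ValueError("could not place the requested number of planted pairs")
        i, j = rng.choice(len(names), size=2, replace=False)
        a, b = names[int(i)], names[int(j)]
        pair = frozenset((a, b))
        if pair in chosen or ontology.related_by_generalization(a, b):
            continue
        if allowed is not None and frozenset((letter[a], letter[b])) not in allowed:
            continue
        chosen.add(pair)
        out.append(
            PlantedRelation(pair=pair, strength=float(rng.uniform(*strength_range)))
        )
    return out


def generate_linked_chapters(
    ontology: DiseaseOntology, n_links: int = 8, rng_seed: int = 0
) -> list[frozenset[str]]:
    """Random unordered ICD-10 chapter-letter pairs acting as the clinically
    linked organ systems along which true relations concentrate."""
    rng = np.random.default_rng(rng_seed)
    letters = sorted({d.icd10[0].upper() for d in ontology.diseases})
    candidates = [
        frozenset((letters[i], letters[j]))
        for i in range(len(letters))
        for j in range(i, len(letters))
    ]
    if n_links > len(candidates):
        raise ValueError("more chapter links requested than letter pairs exist")
    picks = rng.choice(len(candidates), size=n_links, replace=False)
    return [candidates[int(i)] for i in picks]


def generate_transactions(
    ontology: DiseaseOntology,
    planted: Sequence[PlantedRelation],
    n_patients: int = 20000,
    rng_seed: int = 0,
    confounded: Sequence[PlantedRelation] = (),
) -> TransactionDB:
    """Sample a patient-diagnosis database with the planted co-occurrences.

    Baseline draws are independent Bernoulli per disease.  For a planted pair
    (a, b) with strength s, the probability of b among patients whose baseline
    draw includes a is raised to min(1, s * prevalence(b)) by an extra draw
    (and symmetrically for a given b).  ``confounded`` pairs co-occur through
    the same mechanism but represent spurious (e.g. shared-risk-factor)
    correlations: the relevance oracle does not count them, mirroring rules
    that are statistically associated yet clinically uninteresting.
    Generalization items are closed over: a specialization always brings its
    general item.  Patients who end up with no disease at all are dropped
    (transactions must be non-empty).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    rng = np.random.default_rng(rng_seed)
    names = ontology.names
    idx = {n: i for i, n in enumerate(names)}
    prev = np.array([d.prevalence for d in ontology.diseases])
    baseline = rng.random((n_patients, len(names))) < prev
    present = baseline.copy()
    for rel in list(planted) + list(confounded):
        a, b = sorted(rel.pair)
        for src, dst in ((a, b), (b, a)):
            p_dst = prev[idx[dst]]
            target = min(1.0, rel.strength * p_dst)
            # extra-draw probability q with p + (1-p) q = target
            q = max(0.0, (target - p_dst) / (1.0 - p_dst)) if p_dst < 1 else 0.0
            if q <= 0:
                continue
            trigger = baseline[:, idx[src]]
            extra = rng.random(n_patients) < q
            present[:, idx[dst]] |= trigger & extra
    # generalization closure (one pass per chain level)
    changed = True
    while changed:
        changed = False
        for spec, gen in ontology.generalizations.items():
            col_s, col_g = idx[spec], idx[gen]
            add = present[:, col_s] & ~present[:, col_g]
            if add.any():
                present[:, col_g] |= add
                changed = True
    txns = []
    for p in range(n_patients):
        items = frozenset(names[i] for i in np.flatnonzero(present[p]))
        if items:
            txns.append(Transaction(patient_id=f"patient {p:05d}", items=items))
    return TransactionDB(txns)


def oracle_label(
    rule: AssociationRule,
    ontology: DiseaseOntology,
    planted: Sequence[PlantedRelation],
) -> bool:
    """Ground-truth relevance of a rule under the planted model.

    Relevant iff ANY antecedent item is planted-related to the consequent
    (direction ignored) or generalizes/specializes it.  Relations among
    antecedents are ignored, and a single related pair makes the rule
    relevant even when the remaining items are noise.
    """
    planted_pairs = {rel.pair for rel in planted}
    for y in rule.consequent:
        for x in rule.antecedent:
            if frozenset((x, y)) in planted_pairs:
                return True
            if ontology.related_by_generalization(x, y):
                return True
    return False


DEFAULT_MINING_PARAMS: dict[str, float] = {
    "min_support": 0.0001,
    "min_confidence": 0.6,
}


def generate_araids_like(
    ontology: DiseaseOntology,
    planted: Sequence[PlantedRelation],
    target_n_rules: int = 1000,
    target_relevant_fraction: float = 0.613,
    mining_params: Mapping[str, float] | None = None,
    rng_seed: int = 0,
    n_patients: int = 20000,
    db: TransactionDB | None = None,
) -> tuple[list[LabeledRule], TransactionDB]:
    """A labeled rule collection shaped like the annotated reference set.

    Mines a generated cohort (or ``db`` when provided), labels every rule
    with the oracle, restricts to 1-4 antecedents with one consequent, and
    subsamples to ``target_n_rules`` at the requested class balance.
    Returns the labeled rules together with the cohort they came from.

    Within each class the antecedent-length mix follows a truncated
    geometric distribution (ratio 1/2 over lengths 1-4, capped by
    availability, shortfall reallocated to neighbouring lengths): an
    expert-curated rule collection skews toward parsimonious rules, and at
    permissive mining thresholds the raw candidate pool is instead
    dominated by long low-count itemsets whose sides carry no population
    signal.
    """
    rng = np.random.default_rng(rng_seed)
    if db is None:
        db = generate_transactions(
            ontology, planted, n_patients=n_patients,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
    params = dict(DEFAULT_MINING_PARAMS)
    params.update(mining_params or {})

    # Stream mining + labeling through per-(class, length) uniform reservoirs:
    # the candidate pool can run into millions of rules at permissive
    # thresholds, and only a uniform subsample per stratum is ever needed.
    cap = target_n_rules
    reservoirs: dict[tuple[bool, int], list[LabeledRule]] = {
        (lab, L): [] for lab in (True, False) for L in _LENGTH_WEIGHTS
    }
    seen: dict[tuple[bool, int], int] = {key: 0 for key in reservoirs}
    total = 0
    for rule in iter_rules(db, max_antecedent_len=4, **params):
        total += 1
        label = oracle_label(rule, ontology, planted)
        key = (label, len(rule.antecedent))
        seen[key] += 1
        res = reservoirs[key]
        if len(res) < cap:
            res.append(LabeledRule(rule, label))
        else:
            j = int(rng.integers(seen[key]))
            if j < cap:
                res[j] = LabeledRule(rule, label)

    if total < target_n_rules:
        raise ValueError(
            f"mining produced only {total} candidate rules "
            f"(target {target_n_rules}); raise planted strengths or prevalences, "
            f"or lower the mining thresholds"
        )
    n_rel = int(round(target_n_rules * target_relevant_fraction))
    n_irr = target_n_rules - n_rel
    avail_rel = sum(seen[(True, L)] for L in _LENGTH_WEIGHTS)
    avail_irr = sum(seen[(False, L)] for L in _LENGTH_WEIGHTS)
    if avail_rel < n_rel or avail_irr < n_irr:
        raise ValueError(
            f"class balance infeasible: {avail_rel} relevant / "
            f"{avail_irr} irrelevant candidates for targets "
            f"{n_rel}/{n_irr}; adjust planted pair count or strengths"
        )
    relevant = [lr for L in sorted(_LENGTH_WEIGHTS) for lr in reservoirs[(True, L)]]
    irrelevant = [lr for L in sorted(_LENGTH_WEIGHTS) for lr in reservoirs[(False, L)]]
    chosen = _sample_by_length(relevant, n_rel, rng) + _sample_by_length(
        irrelevant, n_irr, rng
    )
    chosen.sort(key=lambda lr: lr.rule.key)
    return chosen, db


_LENGTH_WEIGHTS = {1: 8 / 15, 2: 4 / 15, 3: 2 / 15, 4: 1 / 15}


def _sample_by_length(
    pool: list[LabeledRule], total: int, rng: np.random.Generator
) -> list[LabeledRule]:
    """Sample ``total`` rules with a truncated-geometric antecedent-length mix."""
    by_len: dict[int, list[LabeledRule]] = {L: [] for L in _LENGTH_WEIGHTS}
    for lr in pool:
        by_len[len(lr.rule.antecedent)].append(lr)
    alloc = {
        L: min(len(by_len[L]), int(round(total * w)))
        for L, w in _LENGTH_WEIGHTS.items()
    }
    # reallocate any shortfall deterministically, shortest strata first
    while sum(alloc.values()) < total:
        progressed = False
        for L in sorted(_LENGTH_WEIGHTS):
            if sum(alloc.values()) == total:
                break
            if alloc[L] < len(by_len[L]):
                alloc[L] += 1
                progressed = True
        if not progressed:  # cannot happen when len(pool) >= total
            raise ValueError("insufficient rules to fill the length allocation")
    while sum(alloc.values()) > total:
        for L in sorted(_LENGTH_WEIGHTS, reverse=True):
            if sum(alloc.values()) == total:
                break
            if alloc[L] > 0:
                alloc[L] -= 1
    out: list[LabeledRule] = []
    for L in sorted(_LENGTH_WEIGHTS):
        if alloc[L]:
            picks = rng.choice(len(by_len[L]), size=alloc[L], replace=False)
            out.extend(by_len[L][int(i)] for i in picks)
    return out


@dataclass
class Benchmark:
    """A fully generated study: ontology, planted truth, cohort, labeled rules.

    The cohort is split once: the labeled rules are mined from the holdout
    half (the rules an annotator would see and score), while the
    exploratory half provides the rule population the significance filter
    counts over.  Keeping both halves with the benchmark makes downstream
    evaluations use the same split the rules came from.  The exploratory
    population is held in bit-packed form (item-content masks only): at
    permissive mining thresholds it runs into millions of rules, and the
    contingency counts need nothing but the masks.
    """

    ontology: DiseaseOntology
    planted: list[PlantedRelation]
    confounded: list[PlantedRelation]
    transactions: TransactionDB
    labeled_rules: list[LabeledRule]
    lexicons: LexiconSet
    exploratory: TransactionDB
    holdout: TransactionDB
    exploratory_population: "RulePopulation"


def generate_benchmark(
    rng_seed: int = 0,
    n_diseases: int = 141,
    n_patients: int = 20000,
    n_planted: int = 60,
    strength_range: tuple[float, float] = (2.0, 8.0),
    n_confounded: int = 60,
    confounded_strength_range: tuple[float, float] = (2.0, 8.0),
    n_linked_chapters: int = 8,
    target_n_rules: int = 1000,
    target_relevant_fraction: float = 0.613,
    mining_params: Mapping[str, float] | None = None,
    ontology_config: Mapping[str, float] | None = None,
) -> Benchmark:
    """One-call benchmark generation with a single master seed.

    Besides the planted (truly related) pairs, the cohort carries
    ``n_confounded`` spurious correlations — pairs that co-occur through
    the same conditional mechanism and with the same strength range, but
    that the relevance oracle does not count.  Raw association strength
    therefore does not identify relevance, matching annotated clinical
    rule collections, where some strong associations are judged false.
    What does distinguish the classes is structure: planted pairs
    concentrate in ``n_linked_chapters`` clinically linked ICD-10 chapter
    combinations, while confounded pairs fall anywhere — so relevance is
    learnable from the chapter-count features, but only with enough
    labeled examples, and independently detectable by the significance
    filter through cross-half co-occurrence.

    Mining in each cohort half floors the support threshold at a count of
    two transactions: a fraction that rounds to a single transaction admits
    every observed sub-itemset and carries no co-occurrence information.
    """
    from .significance import RulePopulation, split_exploratory_holdout

    rng = np.random.default_rng(rng_seed)
    s_ont, s_link, s_rel, s_conf, s_txn, s_split, s_rules = (
        int(x) for x in rng.integers(0, 2**31 - 1, size=7)
    )
    ontology = generate_ontology(n_diseases, rng_seed=s_ont, config=ontology_config)
    linked = generate_linked_chapters(ontology, n_links=n_linked_chapters, rng_seed=s_link)
    planted = generate_planted_relations(
        ontology,
        n_pairs=n_planted,
        strength_range=strength_range,
        rng_seed=s_rel,
        chapter_pairs=linked,
    )
    confounded = generate_planted_relations(
        ontology,
        n_pairs=n_confounded,
        strength_range=confounded_strength_range,
        rng_seed=s_conf,
        exclude=[rel.pair for rel in planted],
    )
    db = generate_transactions(
        ontology, planted, n_patients=n_patients, rng_seed=s_txn,
        confounded=confounded,
    )
    explor_db, holdout_db = split_exploratory_holdout(db, 0.5, seed=s_split)

    params = dict(DEFAULT_MINING_PARAMS)
    params.update(mining_params or {})
    # Holdout candidates are mined, labeled and subsampled first so the full
    # candidate list is released before the exploratory population is built
    # (both are of order 10^6 rules; holding them together doubles the peak).
    holdout_params = dict(params)
    holdout_params["min_support"] = max(params["min_support"], 2 / holdout_db.N)
    labeled, _ = generate_araids_like(
        ontology,
        planted,
        target_n_rules=target_n_rules,
        target_relevant_fraction=target_relevant_fraction,
        mining_params=holdout_params,
        rng_seed=s_rules,
        db=holdout_db,
    )
    explor_params = dict(params)
    explor_params["min_support"] = max(params["min_support"], 2 / explor_db.N)
    exploratory_population = RulePopulation.from_rule_stream(
        iter_rules(explor_db, max_antecedent_len=4, **explor_params)
    )
    return Benchmark(
        ontology=ontology,
        planted=list(planted),
        confounded=list(confounded),
        transactions=db,
        labeled_rules=labeled,
        lexicons=ontology.lexicons(),
        exploratory=explor_db,
        holdout=holdout_db,
        exploratory_population=exploratory_population,
    )
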