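"""Rule-level feature engineering for the supervised relevance classifier.

Each association rule becomes a fixed-length vector of 33 numbers:

* 5 form features from the rule itself and the mining output —
  support, confidence, lift, number of antecedents, number of consequents;
* 4 medical-lexicon features —
  ``cdc``  fraction of rule items on a public-health (CDC-style) disease list,
  ``dis``  fraction of rule items that are diseases but NOT on the CDC list,
  ``add``  fraction of rule items on an adverse-event list,
  ``cod``  categorical identifier of the first rule item found on a
           cause-of-death list (0 when absent, else 1 + lexicon index);
* 24 ICD-10 chapter counts — rule items are mapped to ICD-10 codes and
  bucketed by the code's first character into 24 chapter groups.

Membership fractions are normalized by the total number of rule items
(antecedent plus consequent).  Lexicon matching is exact string equality
after the same normalization applied to items; no fuzzy matching, so the
vectors are reproducible.  The column order is frozen in
:data:`FEATURE_NAMES` so persisted models remain portable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .mining import AssociationRule, normalize_item

logger = logging.getLogger(__name__)


def _load_chapter_buckets() -> tuple[tuple[str, ...], dict[str, int]]:
    text = (
        resources.files("extrae").joinpath("data/icd10_chapters.yaml").read_text()
    )
    spec = yaml.safe_load(text)
    names = []
    char_to_bucket: dict[str, int] = {}
    for idx, bucket in enumerate(spec["buckets"]):
        names.append(str(bucket["name"]))
        for ch in bucket["chars"]:
            char_to_bucket[str(ch).upper()] = idx
    if len(names) != 24:
        raise ValueError(f"chapter configuration must define 24 buckets, got {len(names)}")
    return tuple(names), char_to_bucket


CHAPTER_NAMES, _CHAR_TO_BUCKET = _load_chapter_buckets()
N_CHAPTERS = len(CHAPTER_NAMES)

FORM_FEATURES = ("support", "confidence", "lift", "n_antecedents", "n_consequents")
LEXICON_FEATURES = ("cdc", "dis", "add", "cod")
FEATURE_NAMES: tuple[str, ...] = (
    FORM_FEATURES + LEXICON_FEATURES + tuple(f"cie_{name}" for name in CHAPTER_NAMES)
)
N_FEATURES = len(FEATURE_NAMES)  # 33


def _normset(terms: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_item(t) for t in terms)


@dataclass(frozen=True)
class LexiconSet:
    """Medical word lists used by the lexicon features.

    ``causes_of_death`` is ordered: the ``cod`` feature encodes 1 + position
    of the matched term, so the file order is part of the feature definition.
    """

    cdc_terms: frozenset[str] = frozenset()
    disease_terms: frozenset[str] = frozenset()
    adverse_events: frozenset[str] = frozenset()
    causes_of_death: tuple[str, ...] = ()
    icd10_map: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_terms(
        cls,
        cdc_terms: Iterable[str] = (),
        disease_terms: Iterable[str] = (),
        adverse_events: Iterable[str] = (),
        causes_of_death: Iterable[str] = (),
        icd10_map: Mapping[str, str] | None = None,
    ) -> "LexiconSet":
        icd = {
            normalize_item(k): str(v).strip().upper()
            for k, v in (icd10_map or {}).items()
        }
        for item, code in icd.items():
            if not code or not code[0].isalpha():
                raise ValueError(f"ICD-10 code for {item!r} must begin with a letter: {code!r}")
        return cls(
            cdc_terms=_normset(cdc_terms),
            disease_terms=_normset(disease_terms),
            adverse_events=_normset(adverse_events),
            causes_of_death=tuple(normalize_item(t) for t in causes_of_death),
            icd10_map=icd,
        )

    @classmethod
    def empty(cls) -> "LexiconSet":
        return cls()


def normalized_membership(items: Iterable[str], terms: frozenset[str]) -> float:
    """Fraction of the rule's items found in the term list."""
    items = list(items)
    if not items:
        raise ValueError("rule has no items")
    return sum(1 for it in items if it in terms) / len(items)


def dis_membership(items: Iterable[str], lexicons: LexiconSet) -> float:
    """Fraction of rule items that are diseases but absent from the CDC list."""
    items = list(items)
    if not items:
        raise ValueError("rule has no items")
    hits = sum(
        1
        for it in items
        if it in lexicons.disease_terms and it not in lexicons.cdc_terms
    )
    return hits / len(items)


def cod_identifier(items: Sequence[str], causes_of_death: Sequence[str]) -> int:
    """0 when no item is a cause-of-death term, else 1 + lexicon index of the
    first matching item in canonical rule order."""
    index = {term: i for i, term in enumerate(causes_of_death)}
    for it in items:
        if it in index:
            return 1 + index[it]
    return 0


def icd10_chapter_counts(
    items: Iterable[str], icd10_map: Mapping[str, str]
) -> np.ndarray:
    """Counts of rule items per ICD-10 chapter bucket (first code character)."""
    counts = np.zeros(N_CHAPTERS, dtype=float)
    for it in items:
        code = icd10_map.get(it)
        if code is None:
            continue
        bucket = _CHAR_TO_BUCKET.get(code[0].upper())
        if bucket is None:
            logger.warning("ICD-10 code %r of item %r has no chapter bucket; ignored", code, it)
            continue
        counts[bucket] += 1
    return counts


def extract_features(rule: AssociationRule, lexicons: LexiconSet) -> np.ndarray:
    """Assemble the 33-feature vector of one rule in the frozen column order."""
    items = rule.canonical_items()
    vec = np.empty(N_FEATURES, dtype=float)
    vec[0] = rule.support
    vec[1] = rule.confidence
    vec[2] = rule.lift
    vec[3] = len(rule.antecedent)
    vec[4] = len(rule.consequent)
    vec[5] = normalized_membership(items, lexicons.cdc_terms)
    vec[6] = dis_membership(items, lexicons)
    vec[7] = normalized_membership(items, lexicons.adverse_events)
    vec[8] = cod_identifier(items, lexicons.causes_of_death)
    vec[9:] = icd10_chapter_counts(items, lexicons.icd10_map)
    return vec


def feature_matrix(
    rules: Sequence[AssociationRule], lexicons: LexiconSet | None = None
) -> pd.DataFrame:
    """Feature vectors of many rules as a DataFrame with the frozen columns."""
    lexicons = lexicons or LexiconSet.empty()
    data = np.vstack([extract_features(r, lexicons) for r in rules]) if rules else (
        np.empty((0, N_FEATURES))
    )
    return pd.DataFrame(data, columns=list(FEATURE_NAMES))
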