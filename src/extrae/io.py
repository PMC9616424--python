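"""File formats: transactions, rules, labeled rules, lexicons, manifests.

Transactions come in two delimited-text dialects, auto-detected by header:

* wide — one line per patient: ``patient_id<TAB>item1|item2|...``
  (header ``patient_id\titems``);
* long — CSV with one (patient, item) pair per row (header
  ``patient_id,item``).

Rules are TSV with pipe-joined antecedents in canonical order, plus the
mined measures; labeled-rule files add a ``label`` column accepting
true/false or 1/0.  A JSON-lines variant of the rule file is also read and
written.  All text is UTF-8.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml

from .features import LexiconSet
from .loop import LabeledRule
from .mining import AssociationRule, Transaction, TransactionDB, normalize_item, rule_sort_key
from .significance import ScoredRule

_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f"}


def _parse_label(token, lineno: int) -> bool:
    s = str(token).strip().casefold()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise ValueError(f"line {lineno}: unknown label token {token!r}")


# ---------------------------------------------------------------------------
# Transactions


def write_transactions(db: TransactionDB, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\titems\n")
        for t in db:
            fh.write(f"{t.patient_id}\t{'|'.join(sorted(t.items))}\n")


def read_transactions(path) -> TransactionDB:
    """Read either the wide (tab + pipe) or long (CSV pair) dialect."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    if "\t" in header:
        txns = []
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    pid, items = line.split("\t")
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed line") from exc
                txns.append(
                    Transaction(
                        pid,
                        frozenset(normalize_item(i) for i in items.split("|")),
                    )
                )
        return TransactionDB(txns)
    if header.replace(" ", "") == "patient_id,item":
        frame = pd.read_csv(path, dtype=str)
        grouped = frame.groupby("patient_id", sort=True)["item"]
        txns = [
            Transaction(str(pid), frozenset(normalize_item(i) for i in items))
            for pid, items in grouped
        ]
        return TransactionDB(txns)
    raise ValueError(f"{path}: unrecognized transaction header {header!r}")


# ---------------------------------------------------------------------------
# Rules


_RULE_COLUMNS = ["antecedent", "consequent", "support", "confidence", "lift"]


def _rule_record(rule: AssociationRule) -> dict[str, Any]:
    return {
        "antecedent": "|".join(sorted(rule.antecedent)),
        "consequent": "|".join(sorted(rule.consequent)),
        "support": rule.support,
        "confidence": rule.confidence,
        "lift": rule.lift,
    }


def _rule_from_record(rec, lineno: int) -> AssociationRule:
    try:
        return AssociationRule(
            antecedent=frozenset(
                normalize_item(i) for i in str(rec["antecedent"]).split("|")
            ),
            consequent=frozenset(
                normalize_item(i) for i in str(rec["consequent"]).split("|")
            ),
            support=float(rec["support"]),
            confidence=float(rec["confidence"]),
            lift=float(rec["lift"]),
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"line {lineno}: malformed rule record: {exc}") from exc


def write_rules(rules: Sequence[AssociationRule], path, p_values=None) -> None:
    """Rule TSV in canonical order; optionally with a p_value column."""
    records = [_rule_record(r) for r in rules]
    frame = pd.DataFrame.from_records(records, columns=_RULE_COLUMNS)
    if p_values is not None:
        frame["p_value"] = [float(f"{p:.6g}") for p in p_values]
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_scored_rules(scored: Sequence[ScoredRule], path) -> None:
    write_rules([s.rule for s in scored], path, p_values=[s.p_value for s in scored])


def read_rules(path) -> list[AssociationRule]:
    path = Path(path)
    if path.suffix in (".jsonl", ".json"):
        rules = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    rules.append(_rule_from_record(json.loads(line), lineno))
        return rules
    frame = pd.read_csv(path, sep="\t")
    return [
        _rule_from_record(rec, lineno)
        for lineno, rec in enumerate(frame.to_dict(orient="records"), start=2)
    ]


def write_rules_jsonl(rules: Sequence[AssociationRule], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in rules:
            fh.write(json.dumps(_rule_record(r)) + "\n")


# ---------------------------------------------------------------------------
# Labeled rules


def write_labeled_rules(labeled: Sequence[LabeledRule], path) -> None:
    records = [
        {**_rule_record(lr.rule), "label": "true" if lr.label else "false"}
        for lr in labeled
    ]
    pd.DataFrame.from_records(records, columns=_RULE_COLUMNS + ["label"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_labeled_rules(path) -> list[LabeledRule]:
    """Labeled-rule TSV; rejects duplicate rules and unknown label tokens."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(_RULE_COLUMNS + ["label"]) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    seen: set = set()
    out: list[LabeledRule] = []
    for lineno, rec in enumerate(frame.to_dict(orient="records"), start=2):
        rule = _rule_from_record(rec, lineno)
        if rule.key in seen:
            raise ValueError(
                f"line {lineno}: duplicate rule "
                f"{'|'.join(sorted(rule.antecedent))} => "
                f"{'|'.join(sorted(rule.consequent))}"
            )
        seen.add(rule.key)
        out.append(LabeledRule(rule, _parse_label(rec["label"], lineno)))
    return out


# ---------------------------------------------------------------------------
# Lexicons


def _read_term_file(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def read_lexicons(path) -> LexiconSet:
    """Lexicon bundle from a YAML file.

    Keys (all optional): ``cdc``, ``diseases``, ``adverse_events``,
    ``causes_of_death`` — each either an inline list of terms or a path to a
    one-term-per-line file (relative to the YAML) — and ``icd10_map``,
    either an inline mapping or a path to a CSV ``item,icd10_code``.
    """
    path = Path(path)
    spec = yaml.safe_load(path.read_text(encoding="utf-8")) or {}

    def terms(key) -> list[str]:
        val = spec.get(key)
        if val is None:
            return []
        if isinstance(val, str):
            return _read_term_file(path.parent / val)
        return [str(v) for v in val]

    icd = spec.get("icd10_map") or {}
    if isinstance(icd, str):
        frame = pd.read_csv(path.parent / icd, dtype=str)
        icd = dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))
    return LexiconSet.from_terms(
        cdc_terms=terms("cdc"),
        disease_terms=terms("diseases"),
        adverse_events=terms("adverse_events"),
        causes_of_death=terms("causes_of_death"),
        icd10_map=icd,
    )


def write_lexicons(lexicons: LexiconSet, directory) -> Path:
    """Write the lexicon bundle as term files plus a YAML index; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "cdc": ("cdc_terms.txt", sorted(lexicons.cdc_terms)),
        "diseases": ("disease_terms.txt", sorted(lexicons.disease_terms)),
        "adverse_events": ("adverse_events.txt", sorted(lexicons.adverse_events)),
        "causes_of_death": ("causes_of_death.txt", list(lexicons.causes_of_death)),
    }
    spec: dict[str, Any] = {}
    for key, (fname, terms) in files.items():
        (directory / fname).write_text(
            "".join(t + "\n" for t in terms), encoding="utf-8"
        )
        spec[key] = fname
    icd_frame = pd.DataFrame(
        sorted(lexicons.icd10_map.items()), columns=["item", "icd10_code"]
    )
    icd_frame.to_csv(directory / "icd10_map.csv", index=False)
    spec["icd10_map"] = "icd10_map.csv"
    index = directory / "lexicons.yaml"
    index.write_text(yaml.safe_dump(spec, sort_keys=True), encoding="utf-8")
    return index


def write_manifest(path, **entries: Any) -> None:
    """JSON manifest of seeds, parameters and artifact paths for reproducibility."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
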