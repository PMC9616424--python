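# extrae

Semi-supervised filtering of **relevant association rules** among
co-occurring diseases.

Association-rule mining over patient-diagnosis data (each patient a
basket of diagnoses) produces thousands of rules `X ⇒ y` that meet
support and confidence thresholds, but most are clinically uninteresting:
frequent diseases co-occur with everything. A rule is *relevant* when at
least one antecedent disease has a genuine relationship — causal in
either direction, or generalization (`lung neoplasm ⇒ non-AIDS
neoplasm`) — with the consequent. Expert labels for such rules are
scarce, so this package implements an agreement-based self-training
pipeline (the EXTRAE scheme) that needs only a few dozen labeled rules:

1. **Mining** — FP-Growth over the transaction database; each rule
   carries `support(X⇒y) = count(X∪{y})/N`,
   `conf(X⇒y) = support(X∪{y})/support(X)` and
   `lift = conf(X⇒y)/support({y})`. Defaults: min support 10⁻⁴,
   min confidence 0.6, single-item consequent.
2. **Unsupervised component** — the cohort is split into exploratory and
   holdout halves; for each holdout rule `A ⇒ B` a 2×2 table
   (N, n₁, n₂, k) is counted over the exploratory *rule population* and
   scored with the hypergeometric probability
   `p(R) = C(n₁,k)·C(N−n₁,n₂−k)/C(N,n₂)` (point or one-sided tail).
   A p-value threshold is calibrated on the labeled seed by maximizing
   seed accuracy; `p < threshold` predicts relevant.
3. **Supervised component** — a 33-feature random forest per rule:
   support, confidence, lift, antecedent/consequent counts, four medical
   lexicon features (CDC-list, non-CDC disease, adverse-event fractions,
   cause-of-death identifier) and 24 ICD-10 chapter counts.
4. **Self-training loop** — starting from a ~35-rule seed, rules on which
   both components agree are pseudo-labeled and absorbed into the seed;
   both components are re-fit; the loop ends when no coincident rule
   remains.
5. **Evaluation** — F-measure (relevant-class and class-weighted),
   AUC-ROC and AU-PRC under stratified fivefold cross-validation, for the
   loop and for supervised-only / unsupervised-only baselines.

Because real HIV-cohort data is access-restricted, the package includes a
first-class synthetic cohort generator with planted disease relations, a
ground-truth relevance oracle implementing the annotation criteria, and a
benchmark emulating the shape of the reference labeled collection
(1000 rules, 61.3% relevant, 1–4 antecedents, 141 disorders). See
`docs/methods.md` for the model, the design choices and their rationale.

## Worked example

```python
import extrae as E

# four patients; items are case-insensitive sets
db = E.TransactionDB.from_itemsets(
    [["cough", "flu"], ["cough", "flu", "fever"], ["cough"], ["fever"]]
)
rules = E.mine_rules(db, min_support=0.25, min_confidence=0.6)
for r in rules:
    print(sorted(r.antecedent), "=>", sorted(r.consequent),
          f"support={r.support:.2f} conf={r.confidence:.2f} lift={r.lift:.2f}")
```

prints

```
['flu'] => ['cough'] support=0.50 conf=1.00 lift=1.33
['cough'] => ['flu'] support=0.50 conf=0.67 lift=1.33
['cough', 'fever'] => ['flu'] support=0.25 conf=1.00 lift=2.00
['fever', 'flu'] => ['cough'] support=0.25 conf=1.00 lift=1.33
```

Every transaction containing *flu* also contains *cough*, hence
confidence 1.0; *cough* appears in 3 of 4 patients, so lift
1.00/0.75 = 1.33 says the co-occurrence is a third more frequent than
independence predicts. `fever ⇒ cough` (confidence 0.5) falls below the
0.6 threshold and is not emitted. A rule with 72% posterior and 60% prior
confidence has lift 0.72/0.60 = 1.2:

```python
>>> E.lift(0.72, 0.60)
1.2000000000000002
```

End-to-end on synthetic data:

```python
bench = E.generate_benchmark(rng_seed=1)          # ~90 s: 20k patients, 1000 labeled rules
report = E.cross_validate(
    bench.labeled_rules, bench.transactions, mode="extrae",
    seed_size=35, rng_seed=1, lexicons=bench.lexicons,
    exploratory_rules=bench.exploratory_population,
)
print(report.means)   # mean fivefold f_measure / auc_roc / au_prc, iterations, threshold
```

## Command line

```
extrae simulate  --out-dir cohort --rng 7            # synthetic cohort + labeled rules
extrae mine      --transactions cohort/transactions.tsv --out rules.tsv
extrae filter    --exploratory rules_e.tsv --holdout rules_h.tsv --out scored.tsv
extrae featurize --rules rules.tsv --lexicons cohort/lexicons/lexicons.yaml --out X.csv
extrae train     --labels cohort/labeled_rules.tsv --model model.joblib
extrae extrae    --labels cohort/labeled_rules.tsv --exploratory rules_e.tsv --trace trace.csv
extrae evaluate  --labels cohort/labeled_rules.tsv --transactions cohort/transactions.tsv
extrae run-all   --master-seed 1 --output-dir out/
```

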