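# Methods

`extrae` implements a semi-supervised pipeline for filtering *relevant*
association rules among co-occurring diseases: rules X ⇒ y mined from
patient-diagnosis baskets, where relevance means that at least one
antecedent disease has a genuine (causal in either direction, or
generalization) relationship with the consequent disease. The pipeline
combines an unsupervised significance filter with a supervised random
forest through agreement-based self-training, so that a seed of a few
dozen expert-labeled rules suffices.

## Rule mining

Transactions are per-patient *sets* of distinct disorder items (repeat
diagnoses collapse; item strings are trimmed, single-spaced and casefolded
before comparison, because clinical strings vary in capitalization across
centers). Frequent itemsets are enumerated with FP-Growth, implemented
in-package with header-table conditional trees and a single-path shortcut;
on small databases it is tested for exact agreement with exhaustive subset
enumeration. Rules are all partitions X ⇒ y of a frequent itemset with a
single-item consequent (configurable cap) and

    support(X ⇒ y)    = count(X ∪ {y}) / N
    confidence(X ⇒ y) = support(X ∪ {y}) / support(X)
    lift(X ⇒ y)       = confidence(X ⇒ y) / support({y})

Defaults: minimum support 10⁻⁴, minimum confidence 0.6, unbounded
antecedent, single consequent. `min_support` is a fraction of N; the
count threshold is ⌈min_support·N⌉ with a 10⁻⁹ guard against float fuzz.
Output rules are sorted by (support desc, confidence desc, lexicographic
antecedent) so files are reproducible byte-for-byte.

## Significance filter (unsupervised component)

The cohort is split 50/50 into *exploratory* and *holdout* halves and
rules are mined in both. For a holdout rule A ⇒ B, a 2×2 table is counted
over the exploratory **rule population** (not the transactions): N rules
total, n₁ containing A, n₂ containing B, k containing both. "Containing A"
defaults to subset containment in the rule's full item content
(antecedent ∪ consequent); an `exact-antecedent` mode is available. The
p-value is the hypergeometric point probability

    p(R) = C(n₁, k) · C(N−n₁, n₂−k) / C(N, n₂)

computed through log-gamma (`scipy.stats.hypergeom.logpmf`) and clipped
into (0, 1]; it is validated against exact rational arithmetic to 10⁻¹²
on all feasible tables with N ≤ 30. An optional `tail` mode returns the
one-sided Fisher tail P(K ≥ k); both modes rank the planted signal almost
identically on synthetic cohorts, and the point probability is the
default.

Two scoring conventions are implemented. The *point* mode evaluates the
probability of the observed table exactly; it follows the printed formula
but is non-monotone in the observed co-occurrence (tables extreme in
either direction score small p). The *tail* mode returns P(K ≥ k) — the
probability of a table at least as extreme, i.e. of the rule "or one
stricter" under independence — which is monotone and is what the
evaluation pipeline uses by default; the raw operation keeps the point
probability as its default so the printed formula is available verbatim.

The relevance threshold is calibrated on a labeled seed: candidate cuts
are geometric midpoints between consecutive distinct seed p-values plus
sentinels below the minimum and above the maximum (the upper sentinel is
capped at 1.0, the largest value a p-value can take); the cut maximizing
seed accuracy wins, ties resolving toward the smaller (more conservative)
cut. Prediction is strict: relevant ⇔ p < threshold, so rules sitting
exactly at the threshold — including the degenerate p = 1 mass — are
called irrelevant.

When mining the halves at desk scale, the support floor is raised to a
count of two transactions whenever the configured fraction would round to
a single transaction: a count-1 "frequent" itemset admits every observed
sub-itemset (combinatorially explosive) and a single co-occurrence carries
no information for the population counts above.

## Feature extraction and classifier (supervised component)

Each rule maps to a frozen 33-column vector: five form features (support,
confidence, lift, antecedent count, consequent count), four lexicon
features (fraction of rule items on a CDC-style public-health disease
list; fraction that are diseases *not* on that list; fraction on an
adverse-event list; a categorical cause-of-death identifier equal to
1 + the list index of the first matching item in canonical rule order, 0
when absent), and 24 ICD-10 chapter counts. Chapters are bucketed by the
first character of the mapped code using a shipped 24-bucket
configuration (A/B and S/T merged, every other letter its own bucket);
the bucket file is data, not code, and can be replaced. Membership
fractions are normalized by the total number of rule items; lexicon
matching is exact string equality after item normalization — no fuzzy
matching, so vectors are reproducible.

The classifier is a random forest with explicitly frozen defaults —
100 trees, unlimited depth, √d feature sampling, bootstrap on, no
out-of-bag scoring, fixed seed — rather than any toolkit's implicit
defaults, which are not portable across ecosystems. The relevance score
is the forest's probability for the relevant class (with fully grown
trees, the fraction of trees voting relevant); the hard label is
score ≥ 0.5.

## Self-training loop

From an annotated seed (default 35 rules, stratified by label), each
iteration (1) trains the forest on the current seed, (2) re-calibrates
the p-value threshold on the same seed (annotated + pseudo entries),
(3) predicts the remaining development rules with both components, and
(4) moves the *coincident* rules — identical predictions — into the seed,
labeled with the agreed prediction. The loop ends when no coincident rule
remains; because a productive iteration strictly shrinks the development
set, termination is guaranteed, with a `max_iterations` cap (default 100)
guarding the unproductive case. Annotated entries are never overwritten.
The exploratory rule population is fixed across iterations; only the
threshold is re-tuned. Pseudo-labels carry the agreed prediction — the
only consistent choice, since the true labels are withheld.

## Evaluation

F-measure is the harmonic mean of precision and recall on the relevant
class (0 when no positive is predicted); the prevalence-weighted mean of
the per-class F-measures is reported alongside it, because the two
conventions judge majority-leaning classifiers very differently — a
predict-everything-relevant model scores 0.76 on the relevant class at
61% prevalence but only ~0.47 weighted. AUC-ROC is the trapezoidal area
under the ROC curve, equal to Mann-Whitney concordance (ties count ½);
AU-PRC uses right-continuous step interpolation (average precision), not
linear interpolation. Both are computed with scikit-learn and tested
against independent all-pairs-concordance and threshold-enumeration
oracles. Cross-validation is stratified 5-fold; per fold the system is
built on 80% and scored on 20%. Three modes are compared: the full loop,
a supervised-only forest (seed-sized or full-fold training set), and the
threshold-only unsupervised filter.

## Synthetic cohort generator

Real HIV-cohort diagnosis data is access-restricted, so the package ships
a generator that reproduces the *shape* of such data. Defaults: 141
diseases with log-uniform prevalences in [0.002, 0.2], 20,000 patients,
60 planted related pairs with relative-risk strengths uniform in [2, 8],
10% generalization links (one level: a specific disorder always brings
its catch-all item), lexicon flags (34 adverse events, 123 causes of
death, 40% CDC membership) and random ICD-10 codes over disease-chapter
letters. Patients draw diseases as independent Bernoulli variables; for a
planted pair the conditional probability of one member given the other is
raised to min(1, strength · prevalence) by an extra draw. The relevance
oracle follows the annotation criteria the package targets: a rule is
relevant iff any antecedent is planted-related to the consequent
(direction ignored) or generalizes/specializes it; antecedent-antecedent
relations never count, and one related pair suffices even amid noise
items.

Two further structural elements make the benchmark resemble annotated
clinical rule collections rather than a toy. First, the cohort carries 60
*confounded* pairs — correlations produced by the same conditional
mechanism and drawn from the same strength range, but absent from the
validated-relation list the oracle consults. They model associations that
are statistically real yet judged clinically uninteresting (shared risk
factors, ascertainment); without them every irrelevant mined rule is a
low-count fluke and raw support alone separates the classes, which
annotated collections do not exhibit. Second, planted (validated) pairs
concentrate inside a small random set of *linked ICD-10 chapter pairs*
(default 8), reflecting how true comorbidity relations cluster within and
between organ systems, while confounded pairs fall anywhere. Relevance is
then invisible to any single feature but learnable from chapter-count
combinations given enough labeled rules — the supervised learning curve
is steep — and independently (partially) detectable by the significance
filter through cross-half recurrence.

The benchmark (`generate_benchmark`) reproduces the labeled reference
collection's shape — 1000 rules, 61.3% relevant, 1–4 antecedents, one
consequent. It splits the cohort once, mines the labeled candidates from
the *holdout* half (the rules an annotator would see) and the
significance population from the *exploratory* half, so p-values measure
genuine cross-half recurrence. Because permissive mining floods the
candidate pool with long, low-count itemsets whose sides never recur in
the other half (and therefore carry no population signal), the subsampler
draws each class with a truncated-geometric antecedent-length mix (ratio
½ over lengths 1–4, capped by availability, shortfall reallocated) —
mirroring the parsimony of expert-curated rule sets.

What the generator does **not** model: longitudinal visit structure,
censoring and death processes, higher-order (beyond pairwise) disease
dependencies, terminology noise between centers, and annotator
disagreement. Passing tests therefore demonstrate the pipeline's
mechanics and its ability to recover planted pairwise structure — not
clinical validity on real cohorts.

One structural limitation deserves emphasis. In a synthetic cohort the
relevance oracle is, by construction, a function of the planted
co-occurrence structure — and any co-occurrence strong enough for the
significance filter to detect across cohort halves also raises the rule's
support and confidence, which the forest receives as features. The two
components therefore share most of their signal, and the agreement loop,
whose value lies in combining *complementary* channels, cannot open a
large gap over a supervised model trained on the same seed: on this
benchmark the seed-only forest already sits near its plateau and the
loop's pseudo-label noise typically leaves the final model at or below
it (the acceptance script computes the difference directly as
`extrae_minus_supervised_seed_f`). Expert annotation of real cohorts is
different in kind: the experts' judgment draws on knowledge outside the
mined statistics, which is precisely the regime in which agreement-based
self-training from a tiny seed pays off. The loop's mechanics — seed
growth, convergence, and its ability to exceed the seed-only baseline
when the significance channel is informative — are verified in the unit
suite with controlled channels.

## Problem sizes and numerical choices

Tests and the acceptance script run the benchmark at its default size
(20,000 patients, 10⁶–10⁷ mined candidate rules depending on the
prevalence draw, 1000 labeled rules); unit tests use down-scaled cohorts
(≤6000 patients, ≤60 diseases) chosen to exercise every code path at
interactive speed. At permissive thresholds the candidate pool is too
large to materialize, so the benchmark path streams: FP-Growth emits
itemsets through a callback, supports live in a bit-mask → count table,
holdout candidates pass through per-stratum uniform reservoir sampling,
and the exploratory population is kept only as packed 64-bit item masks
(all the contingency counts need). The list-producing mining API remains
for ordinary cohort sizes and is tested for exact agreement with the
streaming path. Binomial coefficients are
never formed directly (log-gamma); p-values are clipped to a minimum of
one denormal ulp so they stay in (0, 1]; ties in rule ordering are broken
by the canonical (sorted-antecedent, consequent) key everywhere. All
randomness flows from explicit integer seeds; pipeline stages derive
their seeds from one master seed via `SeedSequence` with a CRC-based
stage tag.
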