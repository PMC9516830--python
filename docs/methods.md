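# Methods

This note documents the models and procedures implemented in `gravida`,
the parameter choices that matter, and what the synthetic-data experiments
do and do not demonstrate.

## Time and outcome conventions

Time is an integer day index from an arbitrary origin; gestational weeks
are days / 7. Calendar and timezone handling is deliberately out of scope.
Outcome bands are deterministic in gestational length: preterm < 259 days
(< 37 completed weeks), term in [259, 294), postterm ≥ 294 days (≥ 42
weeks). "Before an anchor" always means *strictly* earlier days — the
conservative reading against outcome leakage.

## Pregnancy-episode phenotyping

Delivery-relevant events are the delivery-type diagnosis codes, delivery
procedure codes, and EGA observations. Demarcation is iterative: anchor at
the latest unassigned event day, group every unassigned event in the
half-open window `(anchor − 259, anchor]`, repeat. Half-open boundaries
guarantee the assignment is a partition and that within-episode spans stay
under 37 weeks; an event exactly 259 days older than the anchor starts a
new episode. Diagnosis and procedure codes are pooled for demarcation.

EGA observations attach to the code-seeded episode whose window — extended
by a 3-day post-anchor grace — contains them; EGA with no containing
window seeds its own episode. The grace period exists because EGA near
delivery is routinely documented a day or two *after* the delivery codes:
a strictly backward window would split those observations into spurious
one-event episodes and destroy conception-date derivation. The same
3-day proximity governs the delivery-date rule (the most recent member
timestamp approximates the delivery date, EGA included) and conception
derivation (conception = delivery − round(EGA·7) using the closest EGA
within 3 days, ties to the latest).

Labels: the code label is the consensus of member codes' implied labels;
the EGA label is the band of the latest member observation. Code/EGA
disagreement resolves by the priority postterm > term > preterm — the
oldest gestational classification wins. The same priority resolves
conflicting code-implied labels within an episode, the minimal consistent
extension of the stated code-vs-EGA rule. A simpler comparator labeler
(EGA within 3 days of delivery only) is available via
`phenotype_cohort(..., labeler="ega_within_3d")` for validation studies.

Multiple-gestation codes flag only the episode whose window contains them,
so an earlier twin pregnancy never excludes a later singleton delivery.

Known limitation: two deliveries fewer than 259 days apart (possible when
a short inter-pregnancy interval meets a very preterm second delivery)
merge into one episode. In the default synthetic regime this affects
≈ 0.1% of pregnancies; the consensus priority then returns the earlier
(older-classification) pregnancy's label, so earliest-delivery validation
is unaffected.

## Time-anchored features

Cohorts anchor either at `conception + 7k` days (k weeks of gestation;
requires a derived conception date, excludes women already delivered at
the anchor) or at `delivery − d` days. Code-count features are per-code
event counts strictly before the anchor; women with no prior events keep
all-zero rows rather than being dropped. Two leakage guards are asserted
programmatically on every build: no cell may derive from an on-or-after
anchor event, and no ascertainment code (delivery type/date, multiple
gestation, mode, subtype families) may appear as a column.

The 12 binary clinical risk factors follow standard obstetric definitions:
high-risk race (Black, Asian or Hispanic), age at delivery > 34 or < 18
years, non-gestational and gestational diabetes, sickle cell disease,
fetal abnormalities, pre-pregnancy BMI ≥ 35 kg/m², pre-pregnancy
hypertension (> 120/80 mmHg), gestational hypertension, preeclampsia,
eclampsia, and cervical abnormalities. Code-based factors require at least
one matching code before the delivery day. Pre-pregnancy BMI/BP use the
most recent measurement more than 270 days (9 months) before delivery
when a measurements table is available, else static demographics. The BMI
threshold is taken as ≥ 35 (the clinical convention for class-II obesity).

Lab summaries use in-pregnancy measurements (conception through delivery).
Outliers beyond 4 standard deviations are excluded with mean/SD computed
per lab over the whole cohort's in-window values (a per-episode variant is
available behind a flag; with ≤ a handful of measurements per episode,
per-episode SDs are too unstable to filter on). Surviving values are
summarized as mean/median/min/max. The polygenic score is the plain
additive sum of dosage × effect size over variants passing a p-value
threshold; ancestry covariates are out of scope.

## Prediction protocol

The classifier is a gradient-boosted tree ensemble (binary logistic
objective, histogram method, single-threaded by default so training is
bit-reproducible). The cohort splits 80/20 stratified by outcome.
Hyperparameters are tuned by seeded random search over a declared space —
tree depth 2–10, learning rate 0.005–0.3 (log-uniform), 50–1000 rounds,
row/column subsampling 0.5–1.0, minimum child weight 1–20, L1/L2 0–5 —
scored by stratified 3-fold cross-validated mean average precision. The
default budget is 50 trials (configurable); runs that skip tuning use
fixed shallow-and-regularized defaults (depth 3, learning rate 0.05, 300
rounds, column subsample 0.6) that generalize well on sparse count
features at cohort sizes of 10³–10⁴ rows.

Evaluation reports ROC-AUC (trapezoidal), PR-AUC as step-wise average
precision without interpolation (its chance level is the outcome
prevalence — the right baseline for a ~10% outcome), and the Brier score.
Precision/recall-style metrics default to a 0.5 probability threshold
(configurable; no threshold is canonical for these models). The logistic
comparator uses the top-k features by mean absolute attribution with
balanced class weights (liblinear, max_iter 10000). Cross-site evaluation
featurizes the second site against the training site's column vocabulary
(unseen codes dropped, missing codes zero-filled) and additionally reports
the Spearman correlation of the two sites' mean-|attribution| vectors.

The null-model experiment — the pipeline's leakage check — trains the full
protocol on a random count table (n = 1000, Poisson(0.5) features, an
exactly-22% outcome assigned independently of the features). Because its
expected result is chance regardless of search effort, the experiment uses
a desk-scale tuning budget (8 trials, rounds capped at 300); averaged over
seeds it lands at ROC-AUC ≈ 0.50 and PR-AUC ≈ 0.22 (the prevalence), the
signature of an intact protocol.

## Attribution, clustering, enrichment

Per-delivery attributions are exact polynomial-time tree-Shapley values
computed on the margin (log-odds) scale, where additivity is exact: base
value + row sum equals the model's margin output. In floating point the
identity holds to ≈ 1e−8 per tree (float32 accumulation), i.e. ~1e−6 for
a 100-tree ensemble; the test suite verifies exactness against an
exhaustive-coalition oracle on small ensembles and the float-level bound
on production-sized ones. Feature importance is the mean absolute
attribution across deliveries, ties broken lexicographically.

For subphenotyping, the attribution matrix is embedded with UMAP (30
components, default neighborhood parameters, seeded) and clustered with
HDBSCAN (Euclidean metric) over a grid of (minimum cluster size, minimum
samples) candidates — by default cluster sizes at 2%, 5% and 10% of n
crossed with min_samples ∈ {5, 10, 20}. The candidate maximizing the
density-based cluster validity index (DBCV) is selected, with the full
trace retained. The DBCV implementation follows the standard definition —
all-points core distances, mutual-reachability minimum spanning trees,
cluster-size-weighted validity in [−1, 1] — computed in log space so
30-dimensional inverse-distance powers stay finite; the MST maximum is
taken over all tree edges (a common simplification of the internal-edge
restriction). Degenerate candidates (fewer than two clusters) score −1 so
they lose the argmax. A separate 2-component embedding is recomputed
independently for display.

Cluster characterization: per-cluster outcome prevalence, precision and
recall at the decision threshold (outliers as their own stratum), and per
binary trait a 2×2 in-cluster × trait table over the clustered rows
(outliers excluded) with the odds ratio ad/bc and the two-sided exact
hypergeometric p-value. Empty-margin odds ratios are reported as 0 or
infinity with a degeneracy flag rather than continuity-corrected; raw
p-values are reported by default with Benjamini–Hochberg adjustment behind
a flag, since the enrichment scan is descriptive rather than confirmatory.

## The synthetic-EHR generator

The generator defines the study conditions under which everything above is
tested. Per patient: independent Bernoulli risk factors; first-pregnancy
preterm probability `logistic(base + Σ active effects)`; an optional
second pregnancy (rate 0.3) adding +1.0 log-odds after a preterm first;
gestational lengths drawn per band (term ~ Normal(273, 8) truncated to
[259, 294); preterm ~ Uniform[175, 259); postterm ~ Uniform[294, 302));
3% postterm among non-preterm; 7.6% multiple gestations; 45% of preterm
births spontaneous, the rest split among induced, cesarean and PPROM.
The default intercept is solved (by closed-form mixture enumeration and
root-finding) so the marginal prevalence hits the site target: 13% for
site A, 6% for site B, with site B also shifting code-emission rates by
0.8× to emulate an independent health system.

The 13 default coded comorbidities carry literature-scale log-odds
(0.35–1.6, e.g. preeclampsia 1.4, history of preterm birth 1.4,
gestational diabetes 0.35). Nine correspond to the code-ascertainable
entries of the 12-factor clinical profile; conditions arising only in
pregnancy (gestational diabetes/hypertension, preeclampsia, eclampsia,
fetal abnormalities) emit codes only at pregnancy visits. The remaining
four (history of preterm birth, genitourinary infection, anemia, substance
use) are captured by billing codes but *not* by the 12-factor profile —
they are the informational margin that lets the code-count model dominate
the risk-factor checklist, mirroring the premise that the coding stream
carries a broader phenome than any fixed factor list.

Visits are Poisson: 0.45/week during pregnancy, 0.06/week over a 365-day
pre-conception background window (visit-frequency distributions are not
reported for real cohorts; these are stated defaults, not fits). Each
visit emits Poisson(2) noise codes from a 300-code vocabulary plus
Poisson(0.6) codes per active factor family. Delivery day emits a
delivery-type diagnosis code (contradicting the truth with probability
0.02 by default), a delivery procedure code, and mode/subtype codes. EGA
is observed with probability 0.8 at delivery ± {0..3} days with
Normal(0, 3 days) error. Labs, static demographics and a 50-variant
genotype panel (5 causal) round out the tables. All randomness flows
through named substreams (truth, visits, codes, delivery, EGA, labs,
demographics, genotypes) so toggling one feature leaves the others
bit-identical; the whole dataset is byte-reproducible from (config, seed).

What the generator does **not** emulate: demographic risk gradients (age,
race, BMI carry no true effect — the 12-factor profile's demographic
indicators are noise by construction), code co-occurrence structure and
semantic hierarchies, care-seeking feedback (sicker patients visiting
more), informative missingness, and temporal trends in coding practice.
Passing tests therefore demonstrate that the algorithms are implemented
correctly and recover planted structure under realistic noise — not that
real-data performance figures transfer.

## Problem sizes and numerical choices

Test experiments run at the sizes a desk check needs: the null experiment
at n = 1000 over 5–10 seeds; noiseless label recovery at 5,000 patients;
consensus-vs-codes accuracy at 2,000 patients over 10 seeds; the temporal
and feature-set orderings at 10,000 patients over 5 seeds with the fixed
default hyperparameters (the orderings are properties of the data
structure, not of per-anchor tuning); subphenotype recovery at 4,000
patients over 3 seeds. Conception rounding is half-up to whole days.
Stratified evaluations drop strata under 50 rows. Seeded runs are
single-threaded; UMAP with a fixed seed forgoes parallelism for
determinism.
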