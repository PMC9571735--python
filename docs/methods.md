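# Methods

This note documents the models, algorithms and modelling choices behind
`podtree`: what is computed, which details were genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Data model

A cohort is a flat patient-by-cue table with a binary POD outcome. The
default cue dictionary holds 23 pre-operative cues (age, sex, body height,
BMI, ASA physical status, Charlson Comorbidity Index, four named
comorbidities — arterial hypertension, coronary artery disease, diabetes,
stroke/TIA — education (ISCED), MMSE, pre-operative cognitive impairment,
ADL and IADL impairment, MNA, frailty status, GDS, long-term
benzodiazepines, hazardous alcohol use, smoking status, pack years, surgery
site) plus two intraoperative cues (duration of anesthesia, premedication).
Two points were open and resolved as follows: the comorbidity list is
illustrative in the source ("such as ..."), so exactly the four named
comorbidities are included; premedication is coded as a single binary cue.

Ordinal codings are explicit and fixed: surgery site 1 = intracranial,
2 = intrathoracic/intra-abdominal/pelvic, 3 = peripheral; frailty
0 = robust, 1 = pre-frail, 2 = frail; ASA PS integer 1–4; MNA 0–3 with
3 = no impairment. Threshold rules operate directly on these codes.

### Missing data

Missing cells are `NaN` internally, `""` or `"."` in CSV. Imputation
follows the study protocol: sample **median** for ISCED, GDS, pack years and
duration of anesthesia; **constant 0** (no impairment / not given) for the
four comorbidities, cognitive impairment, ADL, IADL and premedication;
**constant 3** for MNA; otherwise median (numeric) or mode (ordinal/binary).
Choices the protocol left open: medians of even-count samples on integer
codings are rounded half-up onto the coding grid; mode ties go to the
smallest value. Imputation statistics are computed on the **whole table
before splitting** — deliberately mirroring a protocol that prepared the
dataset once before the model comparison, not per-training-fold. This leaks
a small amount of distributional information into test halves and is the
documented, intended behaviour.

## Fast-and-frugal trees

A tree is an ordered list of nodes `(rule, exit_side)`; a rule is
`cue > t` or `cue <= t`. If a non-final node's rule fires, classification
stops with the node's exit decision; the final node decides both ways
(fires → positive). Evaluation reports hits/misses/false alarms/correct
rejections, sensitivity, specificity, balanced accuracy, unweighted
accuracy, mean cues used (mcu) and percent cues ignored
(`pci = 1 − mcu / n_cues_available`). The pci denominator is the number of
cue columns in the evaluated table (23 pre-operative, 25 with the
intraoperative cues); the source's printed pci values do not pin the
denominator exactly, so this convention is stated rather than inferred.

### Goal

Both builders maximise `w·sens + (1−w)·spec` on the training set with
`w = 0.5` (balanced accuracy). `w` is exposed for sensitivity analyses only;
nothing in the pipeline changes it.

### Single-cue rules

The best rule for a cue scans all unique observed values as candidate
thresholds × both directions and keeps the goal maximiser. Tie-breaking is
fixed everywhere: higher goal, then higher sensitivity, then lower
threshold, then direction `>` before `<=`, then alphabetical cue name. The
higher-sensitivity preference is consistent with the screening aim (do not
sacrifice sensitivity); the rest is arbitrary but deterministic.

### ifan

Cues are ranked by their marginal rule's goal; the top `max_levels` (default
5) cues are taken in rank order; for each depth `k` all `2^(k−1)` exit-side
assignments are enumerated (the *fan*), giving 31 candidates at depth 5.
Candidates are scored on the training set; ties prefer the shallower, then
the earlier-enumerated tree. A negative-exit node stores the complement of
the marginal rule, so that a stored rule firing always means "decide now" —
this makes the published tree notation (e.g. `surgery site > 2` exiting
negative) directly representable.

### dfan

Recursive construction with conditional re-ranking: at each node the best
rule of every unused cue is recomputed **on the cases still undecided at
that node**, the best cue is selected (same tie rule), and both exit sides
are branched. Every completed candidate (closing at each depth up to the cap,
default 4) is scored on the **full** training set; a deeper tree is kept only
if it strictly improves on every shallower candidate, which yields the
truncation behaviour (a perfectly separating first cue produces a depth-1
tree). Paths stop early when the remaining cases lose one class. Re-ranking
is single-level (no look-ahead).

dfan's cue choice is greedy per node. Property testing during development
showed that on small random instances the greedy construction attains the
exhaustive all-cue-orders optimum most of the time but not always (~90% of
random 2–4-binary-cue instances); exhaustive search over cue orders is not
computationally feasible at the pipeline's scale (25 cues, depth 4, hundreds
of refits) and is not what the fan algorithms do. The test suite therefore
checks ifan against an exhaustive prefix-search oracle, dfan against an
independent naive reimplementation of the greedy construction, and dfan's
goal against the exhaustive bound as an inequality.

## Comparator models

**Weighted unconstrained tree (UDT).** CART-style recursive partitioning
delegated to `sklearn.tree.DecisionTreeClassifier` with
`min_samples_split = 20`, `ccp_alpha = 0.00001` and class weights
`{negative: 1, positive: n_neg/n_pos}`. The bespoke contract — the weight
ratio and the two growth parameters — is tested directly. Note that R's
rpart expresses its complexity parameter relative to the root risk while
scikit-learn's `ccp_alpha` is absolute; at `1e-5` both effectively disable
pruning, which is the setting's intent (a deliberately flexible benchmark).

**Base-rate-thresholded logistic regression (LogReg).** Unpenalised
maximum-likelihood fit (`LogisticRegression` with `C = inf`; internally the
design is standardised for optimiser conditioning and the estimates mapped
back, which leaves the ML solution unchanged). The decision cut on the
predicted probability equals the training-set positive fraction; a
probability exactly at the cut counts as positive (again favouring
sensitivity). Ordinal cues enter as numeric codes, binary cues as 0/1. With
no cues the model is intercept-only: every probability equals the base rate,
so every case is called positive (sens 1, spec 0, bacc 0.5). Perfect
separation yields diverging coefficients with a convergence warning but
well-defined predictions.

## Comparison protocol

Each trial splits the imputed cohort uniformly at random into halves of
size ⌈n/2⌉ / ⌊n/2⌋ (197/197 at the study size 394). Every model is fitted on
the training half and evaluated on both halves of the *same* split. Trial
seeds derive from the master seed by a counter
(`SeedSequence([master, trial])`), so "the first k splits" is well defined,
stable across machines, and any trial is reproducible in isolation.
Slow-flagged models (dfan) run only on the first `n_trials_slow` splits,
mirroring the reference protocol's 1000-of-10,000 restriction.

Aggregation: per model and phase, arithmetic mean and standard error
(sd/√trials) of sensitivity, specificity and balanced accuracy. Win rates
use strict inequality on test balanced accuracy over the trials both models
share; exact ties credit neither model. A model failing on one trial (e.g. a
degenerate training half) is recorded and skipped; failing on more than 1%
of its trials aborts the run with diagnostics.

The default test-suite and acceptance-script scale is 200 trials on a
synthetic cohort of 394 — small enough to run comfortably on one CPU,
large enough that the protocol's qualitative behaviour (overfitting
direction, flexibility ordering, sens/spec trade-off) is unambiguous.

## Synthetic cohorts

### Calibrated generator

The outcome is Bernoulli(0.251); cues are drawn conditionally independent
given the outcome (only class-conditional *marginals* are published; no
joint structure is available to calibrate against). Per stratum:

| cue | POD | non-POD | family |
|---|---|---|---|
| age | median 74, IQR 71–77 | median 72, IQR 68–76 | discretised normal (σ = IQR/1.349), clipped at 65 |
| ASA PS 3–4 | 0.566 | 0.312 | categorical (within-band split: mostly 2 below, mostly 3 above — a documented choice; only the band totals are published) |
| CCI | mean 2.14, SD 1.5 | mean 1.43, SD 1.6 | gamma, moment-matched, rounded, clipped at 0 |
| frailty (robust, pre-frail, frail) | 0.184, 0.510, 0.306 | 0.406, 0.491, 0.103 | categorical; the robust shares are the complements of the published pre-frail/frail percentages (whose denominators are 98 and 291, implying a few unrecorded frailty values) |
| surgery site (1, 2, 3) | 2/99, 67/99, 30/99 | 7/295, 122/295, 166/295 | categorical from published counts (the printed non-POD percentages sum to 100.1) |
| anesthesia duration | 360 [220; 495] min | 157 [100; 260] min | log-normal matched on log-median and log-IQR, rounded to minutes |

The remaining cues have no published class-conditional summaries and are
drawn outcome-independently from plausible marginals for an elective
surgical cohort aged ≥ 65 (e.g. ~50% female, hypertension 62%, MMSE
concentrated at 27–30, zero-inflated pack years). They function as realistic
decoys for the tree builders. All draws go through inverse CDFs applied to
uniforms; an optional single-factor Gaussian copula (`latent_corr`) can
induce positive within-patient dependence and defaults off.

**What this supports and what it does not.** Monte-Carlo tests verify the
generator hits its calibration targets (prevalence within ±0.5% at n = 10⁵,
duration medians within ±10 min, level probabilities within 3σ), and the
pipeline reproduces the qualitative published patterns on it: every model's
test performance falls below its training performance, the weighted tree
fits best and generalises worst, and the published pre-operative tree
screens with sensitivity > specificity (≈0.85/0.46 at n = 10⁵ — close to
the published 0.84/0.46, which is partly coincidental given conditional
independence). The generator does **not** reproduce the real cohort's joint
distribution, so the numeric comparison-table values and win rates obtained
on synthetic cohorts are properties of the synthetic world, not replications
of the original results.

### Planted-tree cohorts

For ground-truth recovery tests, cues are drawn first and the outcome is a
known tree's decision, flipped independently with probability
`label_noise < 0.5`. The default plant is a 3-cue binary tree (positive,
negative, both exits) with firing probabilities 0.5/0.5/0.65 plus two
Bernoulli(0.5) decoys; the probabilities are chosen so the three planted
cues have strictly ordered population marginal balanced accuracies
(≈0.88/0.68/0.63) and the decoys sit at 0.5, making the plant identifiable
by marginal ranking. At n = 500 and zero noise both builders refit the plant
exactly (dfan truncating at depth 3 below its cap of 4); with 10% label
noise, refit trees still classify fresh noise-free cohorts essentially
perfectly.

## Frozen published trees

The pre-operative tree (CCI, surgery site, ASA PS, frailty) ships with the
default structure listed in the README. Only node 1 (`CCI > 1` → positive)
and the cue order are anchored in the published text; the node-2 and node-3
exits/thresholds are inferred from the published cohort marginals
(peripheral surgery: 56.3% of non-POD vs 30.3% of POD patients; ASA 3–4:
31.2% vs 56.6%) and are overridable per node. The postoperative tree
(duration of anesthesia → age → CCI) is shipped **without** default
thresholds: its cut points were published only graphically, and inventing
defaults would misrepresent the source. Constructing it requires explicit
thresholds and fails with an explanatory error otherwise.

No claim is made of reproducing the published real-data statistics of either
tree (pre-op sens 0.84 / spec 0.46; post-op 0.81 / 0.72); those require the
original cohort, which is available only on request.

## Numerical and degenerate-input conventions

- Candidate thresholds are the unique observed values; `>` max(u) and
  `<=` with the smallest value are legal (degenerate) candidates.
- Single-class label vectors are fatal for rule search and model fitting;
  in evaluation, undefined ratios are flagged as NaN rather than raised.
- Classification of a record with a missing tree-cue value is fatal:
  imputation must precede classification.
- A constant cue scores goal 0.5 (tie resolved to the all-positive rule).
- All randomness flows through `numpy.random.default_rng` seeds; comparisons
  and generators are bit-reproducible given their seeds.

## Known limitations

- Conditional independence given outcome understates real cue correlations
  (age–frailty, ASA–CCI); fitted synthetic trees are therefore somewhat more
  accurate than trees fitted to comparable real data would be.
- dfan is greedy per node (as the fan construction prescribes); it can miss
  the globally optimal conditional cue order (see above).
- The logistic comparator uses numeric codings for ordinal cues; indicator
  contrasts for surgery site were not explored (the original coding is
  unstated).
- Win-rate and table values on synthetic cohorts are not comparable to the
  published real-data tables; only the qualitative orderings are.
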