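# Methods

## Prediction task

For every hour *t* of a stay at which the patient is not on invasive
mechanical ventilation (IMV), the model answers: will IMV begin inside the
4-hour target window that starts *g* hours from now (*g* ∈ {6, 12, 18, 24})?
A candidate window is emitted only when no hour of the 6-hour feature
window or the gap overlaps active IMV; the label is 1 iff an ONSET hour
falls in [*t*+*g*, *t*+*g*+4). Candidates stop early enough that the
whole target window fits inside the stay — onsets after discharge are
unknowable, so windows whose target extends past the end of the stay are
not emitted rather than labeled negative. One real onset can label up to
four positives (one per stride hour); all reported counts are therefore
window-level, not patient-level.

Hours are half-open bins [h, h+1), 0-based from admission; an event at
exactly time h belongs to bin h. An hour counts as IMV-active iff
[h, h+1) overlaps any ventilation interval. The per-hour state is ONSET
(inactive→active), STAY_ON, WEAN (active→inactive) or STAY_OFF.

## Cohort definition

Inclusion: age > 15 years (strict), length of stay between 12 h and 240 h
(inclusive), and at least one hypoxemic measurement — PaO2 < 60 mmHg or
SpO2 < 90 % — at *any* time during the stay (the definition carries no
time restriction; qualification is stay-level). Stays without a recorded
age are excluded and logged. Outlier handling removes values outside each
feature's open plausibility interval rather than clipping them: clipping
would fabricate plausible-looking measurements.

## Featurization

Each dynamic feature-hour is a triplet: hourly mean value, presence mask
(1 iff ≥ 1 raw measurement fell in the hour), and time since the last
measured hour (tsl). tsl for hours before any measurement is defined as
h + 1 — monotone, bounded, and distinguishable from "measured at
admission". Standardization (per-feature mean/sd over *measured* training
hours; features with undefined sd flagged constant and mapped to 0)
precedes imputation, so the fallback fill value 0 is exactly the
standardized training mean. Imputation carries the last standardized
observation forward and never touches mask or tsl; it is idempotent.

Derived indices (SpO2/FiO2, PaO2/FiO2, ROX = (SpO2/FiO2)/RR) are computed
from raw hourly means *before* standardization — ratios of standardized
values would be physically meaningless — and an index-hour is measured
only when every constituent is measured and strictly positive that hour
(guarding the divisions; an RR of 0 makes the hour unmeasured, logged).

Dynamic features with fewer than `min_count` measured hours in the
training split (default 1000) are excluded together with their mask/tsl
channels: tree models treat rarely measured features as unreliable, and
the counting is done on the training split only. Standardization and
rare-feature exclusion never see test or target-evaluation stays; all
splits are at patient level with no crossover.

## Model

XGBoost, binary logistic objective, `tree_method=hist`, single thread
(bit-reproducibility on one machine). Hyperparameters — depth 3–7,
learning rate 0.05–0.3 (log-uniform), 40–120 rounds, row/column
subsampling, minimum child weight — are drawn by seeded random search
(default 4 draws) and selected by AUC on a patient-level validation
carve-out (default 15 % of training stays; a fraction-of-a-percent
validation set would be too small to rank candidates). Early stopping is
disabled; the round count is part of the searched configuration, which
keeps the selected model fully reproducible from its seed. Class
imbalance is handled by `scale_pos_weight`, defaulting to the training
negative:positive ratio; weighting is preferred over resampling because it
achieves near-identical sensitivity/specificity without synthesizing
samples.

Feature importance is computed from the tree dump as the sum over splits
of squared gain per feature (split count weighted by squared improvement),
normalized to 1, ties broken by manifest order. A helper aggregates
per-column importances (channel × hour) to per-feature totals.

## Transfer adaptation

The adaptation contract is: preserve the source model's strength while
fitting a portion of the target domain. It is realized as margin-continued
boosting — the most standard tree-ensemble transfer mechanism: source
trees are kept verbatim and additional rounds are trained on the target
fit split (70 % of target patients) starting from the source model's raw
margin. The added trees are deliberately *shallow* (depth 2–3, small
learning rates 0.02–0.1, 50–300 rounds, min child weight 2–6): target
cohorts are small, and deep continuations overfit the fit split badly
enough that the search would fall back to the null. The number of rounds,
rate and depth are chosen by seeded random search on a validation
carve-out of the fit split (default 25 %), the null candidate (0 added
rounds = source as-is) is always in the pool, and the winning continuation
is refitted on the full fit portion. Evaluation always uses the remaining
30 % of target patients, untouched by fitting or selection.

`freeze_source_trees=False` switches to an alternative: the source trees'
leaf weights are refreshed on target data (`process_type=update,
updater=refresh`) before continuing — structure preserved, values
re-estimated.

## Evaluation

- AUC is the tie-corrected pairwise statistic (sklearn's implementation;
  tests cross-check an O(n²) pair-counting oracle).
- The operating threshold μ is the smallest observed score whose false
  positive rate is ≤ the target (default 0.2); "probability ≥ μ" counts
  as positive, which makes μ = 0 the all-positive classifier. The
  achieved FPR is always reported — with finely spread scores it typically
  lands at the target, with coarse scores below it.
- F<sub>β</sub> uses the standard convention ((1+β²)PR/(β²P+R); β < 1
  weights precision), with β = 0.5 as the reporting default; MCC is 0
  when any marginal is empty.
- Precision-by-bin partitions [μ, 1] at the fixed edges 0.1 … 1.0,
  discarding edges at or below μ; the last bin is closed at 1; empty bins
  report NaN, not 0; the count-weighted bin mean equals overall precision
  above μ.
- The sensitivity analysis re-splits patients, retrains with the tuned
  configuration held fixed, and forms a t-interval over split AUCs
  (mean ± t<sub>level,n−1</sub>·sd/√n); a split yielding a single-class
  test set is resampled with a logged new seed. The full random search is
  not repeated per split, so the interval isolates split-to-split
  variability of one configured model.

## Feature analysis

The lagged correlation matrix places one variable per (feature,
within-window hour) from the value channel, plus statics and the outcome;
the unlagged variant averages the six in-window hours first. The binary
outcome enters through the plain Pearson formula (point-biserial).
Constant variables are flagged and their correlations set to 0. The DAG
emits u→v only when lag(u) < lag(v) (statics earliest, outcome latest) and
|r| clears the threshold — acyclic by construction. Tier assignment seeds
tiers from the importance ranking (floor 0.01, the display cutoff commonly
used for importance plots) and absorbs unassigned features with |r| ≥ 0.5
to the seed; both cutoffs are configurable since no canonical values
exist; leftovers form one residual tier. The importance-vs-correlation
odds ratio median-splits both rankings (⌈n/2⌉ top / ⌊n/2⌋ bottom) and
applies the Haldane–Anscombe 0.5 correction when a cell is empty.

## Synthetic cohorts: what they emulate, and what they do not

The generator produces what the pipeline needs from real bedside data:
irregular feature-specific sampling (Poisson measurement times),
missingness, a latent severity process driving both observables and
outcome, stay-level class imbalance, hypoxemic-filter eligibility, and a
controllable source→target shift.

Severity is a random walk with per-patient drift: a `p_deteriorate`
fraction (default 0.15) drifts upward (+0.12/h ± 0.03), the rest drift
flat or slowly recover; innovation sd 0.10/h. Onset hazard per hour is
sigmoid(−15 + 6·s): the steep slope makes onset close to a threshold
crossing, so deterioration visible hours earlier is genuinely predictive —
with a mean-reverting severity instead, onset timing becomes noise-driven
and no observer, however good, can anticipate it usefully. The defaults
give ~8 % of generated stays an onset (~25 % of the filtered hypoxemic
cohort, between the two clinical settings the package models), with
window-level positive rates of 2–3 %. Ventilation lasts
lognormal(3.4, 0.8) hours (mean ≈ 41 h), one episode per stay.

Feature loadings are chosen so arterial CO2 is the dominant severity
marker (largest loading-to-noise ratio, and deliberately not a constituent
of any derived index so importance-recovery checks are not confounded);
SpO2 and PaO2 load negatively so deteriorating patients become hypoxemic
and qualify for the cohort; FiO2-set and PEEP-set are informative
*operational* features (clinicians escalate support with severity);
`misc_lab_*` are pure noise. The default target shift removes most of the
CO2 loading ("silent hypoxemia" — deterioration without CO2 retention),
flips the heart-rate loading, strengthens desaturation and tachypnea, and
shifts several baselines; location-only shifts would leave rankings (and
hence AUC) untouched, so the shift deliberately alters feature–outcome
relationships.

Not emulated: pharmacology, interventions feeding back into physiology,
multi-episode ventilation, inter-feature causal structure beyond the
shared severity factor, documentation artifacts, or the marginal
distributions of any real database. Passing tests therefore show that the
pipeline recovers planted structure under realistic sampling and
imbalance — not that the clinical AUCs would be attained on real data.

## Numerical and design choices

- Hour binning by floor(); events at or past floor(LOS) have no bin and do
  not enter the grid.
- Ventilation activity comes from explicit IMV intervals in the input
  (touching intervals merged); inferring IMV from ventilator-setting
  events is out of scope for the default path.
- Sample-level design matrices are float32; column order is
  feature-major, then channel (value, mask, tsl), then window hour, with
  the four statics (age, sex, weight, height) appended raw — the trees
  handle their scales and missingness natively.
- Search and adaptation are reproducible from their seeds at fixed thread
  count; `n_jobs=1` is the default everywhere.
- Study-condition sizes used by the test suite and the acceptance script:
  2000-stay source, 300-stay target, 5 seeds for the transfer and
  null-shift experiments, 10 repeated splits for the AUC interval.

## Known limitations

- The adaptation search can select the null on a genuinely shifted target
  when the target validation carve-out is very small; its selection noise
  shrinks with target size.
- μ is chosen on the same predictions it thresholds (as in the reported
  confusion matrices); a deployment would freeze μ on a validation set.
- Repeated-split CIs treat split AUCs as independent draws; splits share
  patients, so the interval is approximate.
- The hourly grid discards sub-hourly dynamics; multi-rate grids and
  learned imputation are out of scope.
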