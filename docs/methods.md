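# Methods

This note documents the models, the synthetic data-generating process, the
numerical conventions, and the open design choices made in `phenorisk`.

## Problem setting

Adolescents in a 14-day smartphone study contribute *active* data (daily
1–7 self-report items such as mood, sleep quality, loneliness) and
*passive* data (eight phone-sensor categories). Each participant also has
four baseline clinical scores — SDQ (0–40), SCI (0–32), ED-15 (0–6,
mean-style), and a 0–4 suicidal-ideation frequency item — binarized into
high-risk labels with validated cuts (SDQ ≥ 16, SCI ≤ 16, ED-15 > 2.69,
ideation ≥ 1; the SCI text cut "≤16" and the tabulated "<17" coincide for
integer scores, and the ED-15 cut is implemented strictly on the continuous
score). The task is per-user binary risk classification from the user's
daily feature rows, evaluated subject-wise.

## Synthetic cohort generator

No real cohort ships with the package; the generator is a first-class,
tested module that emulates the published study's *statistical anchors*,
not adolescent behaviour per se.

**Latent structure.** One general severity factor `g ~ N(0,1)` plus four
outcome-specific factors; each outcome trait is `0.75·g + 0.66·s_k`. Scale
scores are clipped, discretized affine transforms of `trait + 0.15·noise`,
with the affine cut placed at the normal quantile matching the configured
prevalence targets (defaults: 30.1% SDQ-high, 33% insomnia, 36.9% ideation
and eating-disorder risk, the published proportions). Score spreads
(SDQ ≈ mean 12.4, SD 6; SCI ≈ 19.6, SD 7; ED-15 ≈ 2.2, SD 1.5) sit close
to the published means/SDs.

**Active items.** Each of 14 items is `clip(round(4 + a_eff·(loadings·
factors) + day_state + noise), 1, 7)`. Three shared within-day factors
(affect, drive, rumination) induce the published item-correlation pattern —
the motivation–productivity coupling is calibrated to r ≈ 0.7, and
negative-thinking's user mean correlates with the SDQ total at Spearman
ρ ≈ 0.5 (published anchor 0.48). `day_noise_scale` multiplies both the
shared day factors and the item noise (SD 1.1 by default); `effect_sizes
["active"] = 0` severs all item–trait coupling (null cohorts).

**Passive streams.** GPS follows a two-state day: dwell fixes at the exact
home coordinate and Poisson-count excursions to per-user anchor points,
with the excursion rate decreasing in severity (fixes snap to anchors,
mimicking event-driven significant-change sampling — hence a fully
home-bound day has exactly zero radius of gyration and entropy). Daily
steps are lognormal (median 6000, σ=0.5) decreasing in the
SDQ-specific trait. Non-GPS sensors sample a 96-point 15-minute grid.
Streams deliberately load on *outcome-specific* factors so the modalities
are complementary rather than redundant: nighttime ambient light, screen
brightness, in-app night sessions and nighttime battery usage rise with
the insomnia trait; entertainment-app share and session durations rise
with the ideation trait; nighttime noise and battery drain with the
eating-disorder trait; excursion-driven daytime noise contrast and
mobility with general severity. Measured user-level Spearman correlations
for the nine planted anchors approximate the published magnitudes
(within roughly ±0.1–0.2) and match all published signs.

**Missingness.** Active responses stop after a geometrically distributed
last day, calibrated so the expected fraction still responding on day
`n_days` equals `active_retention_final` (default 14/103, the published
day-14 anchor). Passive enablement is static: a `zero_sensor_fraction`
(default 36/103) of users enable nothing; the rest enable each
platform-compatible sensor by its opt-in rate, ordered as published
(steps/battery most common). Android-only sensors (ambient light, app
usage, noise) and the iOS-only screen-brightness sensor are hard
platform-gated (`ios_fraction` default 78/103). Dropout and opt-in are
independent of the latent traits, so missingness never leaks label
information. `site_shift` translates home locations and sensor baselines
for external-validation cohorts.

**What the generator does *not* emulate** — real GPS geometry, weekday/
weekend structure, timezone/DST, trait-dependent engagement, item-level
questionnaire scoring, and any within-user temporal trend in severity.
Passing tests therefore demonstrate pipeline correctness and calibrated
sensitivity/specificity of the *method*, not clinical validity on real
adolescents.

## Feature engineering

92 passive features in the published per-category counts
(8/36/10/8/15/3/8/4). Conventions:

* Night window `[22:00, 06:00)`, half-open, single local timezone.
* Location grid = lat/lon rounded to 3 decimals (~111 m); entropy in nats;
  Earth radius 6,371,000 m; GPS jump filter removes fixes implying > 200
  km/h from the previous retained fix; home = modal night-window cell over
  the whole study, ties to the earliest-observed cell.
* "Total" of grid-sampled readings is the plain sum of samples (rate fixed
  at 15 min). All SDs are population SDs.
* Two published category lists under-enumerate; the gaps are filled with
  flagged, semantically adjacent fillers (location: max distance from the
  day centroid — named in the running text — and normalized entropy; app
  usage: session-time SDs, first/last app hour, unique categories per
  window).
* Battery: charges = onsets of level increase; drain/hour = total decrease
  over observed hours; nighttime usage = night samples whose level fell.
* Sentinel −1 marks *unavailable* (disabled/gated/absent sensor). It is
  excluded from cumulative medians and normalization statistics and
  re-inserted after scaling, so −1 always means "unavailable" even in
  z-score space. Count-like app-usage night features are observed zeros
  when the day has events; statistic-like ones (mean/median/SD of session
  time) are sentinels when their window is empty.
* Cumulative median: value(user, day *t*) = median of the user's observed
  values on days 1..*t*; a single-day outlier after ≥ 2 stable days leaves
  it unchanged.
* Normalization: continuous columns z-scored with training-row
  means/population SDs computed on observed values only; binary indicators
  (the three step-count cuts) pass through; zero-SD columns are centred
  with a unit divisor and a warning.

## Model

Encoder `input → 128 → 64` and projection head `64 → 64 → 32`, ReLU
between layers, linear outputs; hidden widths and the ReLU activation are
package choices (unstated upstream), exposed in `PretrainConfig`.
Pretraining minimizes the batch-mean triplet margin loss `max(d(a,p) −
d(a,n) + 1, 0)` with non-squared Euclidean distances on the projection
outputs, Adam at 1e−3, 3 epochs of 256-triplet batches. Triplets are
sampled uniformly: an anchor user among users with ≥ 2 rows, a positive
from the same user's other days, a negative from a uniformly drawn other
user — labels are never touched. One epoch is `epoch_scale ·
⌈n_rows/256⌉` batches; the per-epoch triplet count is a free protocol
parameter (`epoch_scale` defaults to 1 and the high-day-noise ablation
uses 8, ≈ 24k triplets).

Fine-tuning freezes the encoder bit-for-bit and trains a `64 → 32 → 1`
head on the rectified embeddings — standardized with training-fold
statistics, so the head's fixed step budget is insensitive to the
embedding scale pretraining produces — with BCE-with-logits, per-sample
weights proportional to inverse class frequency (normalized to average 1), Adam
1e−3, 20 epochs, batch 1024. The no-pretraining ablation trains the same
stack end-to-end under the supervised objective only. Day-level sigmoid
probabilities are averaged per user; the decision threshold is 0.5.

The training stack (MLP forward/backward, Adam, losses) is implemented in
NumPy inside the package and verified against finite differences and
closed-form oracles in the test suite.

## Evaluation protocol

LOSO-CV with everything refit per fold: normalization statistics, the
contrastive encoder (pretraining is per training fold, the stricter
reading of the protocol), class weights and the head. Repetitions re-seed
initialization, batching and triplet sampling; per-repetition seeds derive
from a master seed via `SeedSequence`. Metrics: balanced accuracy (primary),
rank-based AUC, AUC-PR, F1, macro-F1, sensitivity/specificity/precision/
recall, reported mean (SD) over repetitions (SD = 0 for a single
repetition, never dropped). Comparative experiments restrict to users
contributing both modalities. Degenerate folds (single-class training
labels) are skipped with a warning and counted. Paired Wilcoxon and t
tests compare per-repetition balanced accuracies; identical vectors are
reported as no-difference (p = 1). External validation fits the full
pipeline on one cohort and scores a user-disjoint cohort; stratified
reports give per-group accuracy over score bins (SDQ default bins 1–8 /
9–16 / 17–24 / 25–40) and balanced accuracy over subgroups (sex, school,
≤3 vs >3 enabled sensors).

## Interpretability

Associations use per-user feature *medians* across days (the user-level
choice is exposed), Spearman with midrank ties, and Benjamini–Hochberg
adjustment across features within each outcome; group contrasts use Welch
t-tests on standardized user-level values. Attributions use a
model-agnostic permutation-sampling Shapley estimator: marginal output
changes along random feature permutations against sampled background
rows. Because each permutation telescopes, per-row attributions sum
exactly to the model output minus the row's sampled-background baseline;
the estimator is validated against exhaustive 2^d enumeration on small
toys. Passive importances are summed within the eight sensor categories;
active items stay individual.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline at sizes
chosen to keep a complete run in the tens of minutes on one CPU core:
null-calibration cohorts of 60 users × 4 repetitions, signal-recovery
cohorts of 90 users × 2 repetitions per modality, a 10-seed × 30-user
pretraining ablation, and 250–2000-user cohorts for generator calibration
checks. Larger sizes change none of the qualitative behaviour; all
experiment entry points accept arbitrary `n_users`/`repetitions`.

## Known limitations

* The pretraining-vs-none ablation is evaluated on raw daily self-report
  features: after cumulative-median aggregation the rows are already
  user-stable and the two arms coincide to within noise (the aggregation
  and the contrastive objective denoise the same day-level variability),
  and in the combined feature space the user-constant sensor-enablement
  patterns give the contrastive objective a shortcut that confounds the
  comparison.
* With ~10² training rows per fold, the fixed 20-epoch/1024-batch head
  budget yields few optimizer steps; accuracies are correspondingly
  conservative and fold-noisy.
* Sentinel −1 in z-score space is a code, not a magnitude; models treat it
  as an ordinary input value, as in the source protocol.
* The sampling-Shapley baseline is the mean over *sampled* background
  rows; against the full background mean it carries O(1/√permutations)
  noise.
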