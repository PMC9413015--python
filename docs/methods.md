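# Methods

This note documents the models and procedures implemented in `wristpa`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Signal model and units

A record is a tri-axial acceleration stream x(t), y(t), z(t) in
gravitational units (1 g = 9.81 m/s²) at a fixed nominal sample rate
(10–100 Hz), dynamic range ±8 g. At rest the vector norm is 1 g (gravity);
movement adds oscillatory components. Time is float seconds from stream
start; the analysis epoch is one minute, labeled by its start and covering
[start, start + 60 s). Epochs are clock-aligned to the minute grid of the
first full minute; partial epochs are marked unknown (NaN) and excluded
from every accuracy computation.

## The four summary measures

| measure | definition | window | epoch rule |
|---|---|---|---|
| ENMONZ | max(‖a‖ − 1, 0) | per sample | mean |
| MAD | mean(abs(‖a‖ − mean‖a‖)) | 60 s (configurable) | mean |
| AI | max(mean per-axis population variance − σ²ₙ, 0) | 1 s | **sum** |
| ROCAM | ‖aₜ − aₜ₋₁‖, then 1-s running median | per sample | mean |

Decisions where the definitions leave room:

- **MAD window (N).** The windowed mean is what removes gravity, but the
  window length is a convention. The default is the full 1-minute epoch,
  which makes the epoch average the average of a single window and keeps
  the formula and the epoch summarization consistent; shorter windows
  (e.g. the 6 s convention of some laboratories) are configurable.
- **AI variance form.** Population (1/N) variances. The optional device
  noise-variance subtraction σ²ₙ defaults to 0; the clamp keeps values
  non-negative regardless. No square root is applied, so AI carries
  g²-derived units on a larger numeric scale than the other three.
- **ROCAM first sample.** The t = 0 difference is undefined; it is set
  equal to the t = 1 value before median filtering, preserving length. The
  effect is negligible at minute scale.
- **ROCAM median filter.** Window = one second of samples, centered. Even
  window lengths use the lower median; edges shrink the window rather than
  pad. Per-sample (not per-unit-time) differences are used, which is why
  every threshold is tagged with its sample rate: halving the rate roughly
  doubles per-sample differences of a band-limited signal, so cut-points
  learned at one rate are invalid at another. This monotone rate
  dependence is asserted by a dedicated test.

All four measures are rotation invariant (norms, covariance traces,
difference norms), non-negative, and vectorized implementations are tested
against independent loop-based evaluations at 1e-10 relative tolerance.

## Down-sampling

Polyphase resampling with a Kaiser-window linear-phase FIR: cutoff at
0.45 × target rate, stopband from the target Nyquist with ≥ 60 dB
attenuation (the 100 → 10 Hz design lands near 100 dB). The input is
reflect-padded by a filter length so the symmetric filter is effectively
zero-phase and free of zero-padding edge transients; DC gain is exactly 1.
Each target rate is computed independently from the source record, never
cascaded. Up-sampling is refused: information above the source Nyquist
cannot be recovered. The filter order/window are design choices — the
contract asserted by tests is behavioral: DC preserved to 1e-6 g, passband
tone amplitude within 1%, stopband tone below −40 dB, band-limited energy
preserved within 5%.

## Non-wear and sleep segmentation

**Non-wear**: a minute is stationary when all three per-axis standard
deviations are ≤ 13 mg (a widely used stillness ceiling for an off-body
device; configurable). Maximal stationary runs ≥ 60 min are non-wear.
Detection depends only on within-minute deviations, so it is invariant to
axis offsets (device orientation).

**Sleep** is detected in two stages from the rate-of-change measure:
(1) candidate minutes have their 1-minute epoch below 0.06 g — the default
sedentary floor — *and* at least 90% of their within-minute 1-second means
below it (quietness must persist through the minute, since sleep movement
is sparse rather than uniformly small); (2) candidate segments separated
by ≤ 30 min are joined (brief awakenings, posture shifts) and only joined
blocks ≥ 30 min are kept. Joining is provably monotone: widening the gap
never loses sleep minutes. Non-wear minutes are never sleep. The
sub-minute quietness statistic is this package's realization of a
short-segment sleep criterion whose published form is parameterized here;
all four parameters are overridable. Block onset/offset extraction is
provided as the first/last minute of each block.

## Threshold classification

Each measure gets four ordered cuts partitioning (0, ∞) into
sleep/sedentary/light/moderate/vigorous with half-open `lower < x ≤ upper`
bands (upper bounds inclusive). Shipped 10 Hz defaults (g):

| measure | floor | sed/light | light/mod | mod/vig |
|---|---|---|---|---|
| enmonz | ~0 | 0.032 | 0.173 | 0.382 |
| mad | 0.001 | 0.059 | 0.242 | 0.38 |
| ai | 0.010 | 5.308 | 17.010 | 23.628 |
| rocam | 0.06 | 0.175 | 0.400 | 0.483 |

The ENMONZ sedentary band opens at 0, so its sleep floor is an epsilon:
only exact zeros fall below it. Precedence per minute: non-wear mask, then
sleep mask, then value bands; a worn, awake minute at or below the floor
is sleep. Applying a threshold set to epochs derived at a different rate
emits a loud warning rather than an error, since deliberate transfer
experiments are legitimate.

## Threshold learning

- **Initialization.** Per category, a Gaussian KDE whose bandwidth solves
  the diffusion fixed-point equation in the DCT domain (grid 2¹², ≥ 30
  finite values required, constant samples rejected). Each adjacent-pair
  cut starts at the minimum of the summed densities between the two
  category modes; a missing or non-separable pair falls back to its bound
  midpoint with a warning. With no sleep data, the floor is placed at half
  the 5th percentile of sedentary — below essentially all awake values.
- **Refinement.** The objective — pooled minute-wise accuracy over the four
  awake levels, sleep excluded — is piecewise-constant in each cut, so
  golden-section or gradient search is inappropriate. Instead, coordinate
  descent scans each cut's candidates exactly: midpoints of adjacent
  distinct sorted observed values within that cut's bounds and between its
  neighbouring cuts (candidates thinned evenly above 512). Ties break
  toward the smaller cut; sweeps repeat until no improvement beyond 1e-6
  or 5000 evaluations. Accuracy is never below the initialization's, by
  construction. Default bounds per cut: [5th percentile of the lower
  category, 95th percentile of the upper], which mirrors inspecting the
  stratified distributions and prevents a dominant class from swallowing a
  cut.
- **Validation.** Leave-one-participant-out: fit on N−1 participants,
  evaluate on the held-out one; fold confusion matrices are summed into a
  pooled matrix, and per-participant accuracies are also averaged
  (both aggregations are reported because they differ under unequal
  minute counts). Whether the training objective should be pooled or
  per-participant-averaged is itself a convention; pooled is the default,
  per-participant is available on `OptimizerSpec`.

`ThresholdModel(epochs, labels).fit()` wraps this machinery in a
fit/results interface with a `summary()` band table.

## Random-forest fusion

A 500-tree forest combines the four per-measure estimates
(`max_features = sqrt`, i.e. floor(√d) candidate features per split;
d = 20 one-of-k columns in the default estimates-only mode, 24 in `both`
mode, 4 in `measures` mode). All three input modes are implemented;
estimates-only is the default as the computationally simplest. No class
rebalancing by default — threshold precedence already bounds class
dominance — with an optional class-weight switch. The forest only
re-labels worn, awake minutes; segmentation masks take precedence. In the
LOPO harness the forest is trained within each fold, consistent with
out-of-sample reporting. Fixed seeds make predictions bit-reproducible.

## Evaluation statistics

5×5 confusion matrices (true × estimated; non-wear/unknown excluded)
with overall accuracy and per-category correct fractions; matrices add
across disjoint minute sets. Spearman rank correlation (average-rank ties)
between epoch values and the ordinal coding sleep=0 < sedentary=1 <
light=2 < moderate=3 < vigorous=4 — the natural intensity ordering;
|ρ| ≥ 0.3 is flagged as a strong association. Two-sample KS test with the
asymptotic p-value by default (minute counts here are in the thousands)
and the exact computation behind a flag; significance at p < 0.01. Both
statistics are tested against brute-force oracles (rank-then-Pearson;
exhaustive ECDF scan).

## Synthetic data: what it emulates, what it does not

Per category the generator produces gravity (a unit vector random-walking
slowly on the sphere) + per-axis sinusoidal bursts (fresh random phase and
mildly jittered amplitude each minute) + white sensor noise. Defaults are
calibrated so the per-category mean 1-minute ROCAM at 10 Hz sits near the
centre of its default band, with amplitudes 0.030 / 0.153 / 0.268 / 0.313
/ 0.430 g and frequencies 0.5–2.5 Hz from sleep to vigorous. Sleep keeps
~21 mg of per-axis movement — above the 13 mg non-wear stillness ceiling —
so sleep and off-body periods remain distinguishable, as they are in real
data; injected non-wear windows are perfectly still (plus optional noise).
The default day is 480 sleep / 480 sedentary / 330 light / 120 moderate /
30 vigorous minutes, sleep first, vigorous rare, matching the gross
structure of free-living wrist data. Cohorts draw independent per-
participant seeds and a mild (3% log-normal) amplitude jitter, with the
sleep→vigorous amplitude ordering re-imposed after jitter.

Deliberately *not* emulated: gait micro-structure, within-category
intensity drift, heteroscedastic sensor noise, circadian placement of
activity, camera/diary label noise. Consequently, passing recovery tests
shows the pipeline is correct and well-calibrated under its own
assumptions — near-ceiling synthetic accuracies say nothing about accuracy
on real cohorts, where category distributions overlap heavily. Schedule
boundary minutes are flagged so recovery statistics can exclude them.

## Problem sizes and determinism

The test suite and the acceptance script use a three-participant cohort of
24-hour days at 10 Hz (4320 labeled minutes), 20,000-minute four-class
Gaussian problems for optimizer recovery, and 120 s tones for the filter
contract — sizes chosen so the whole suite runs in well under a minute of
compute while leaving every statistic far from its tolerance. All
randomness flows through explicit integer seeds (numpy `SeedSequence`
spawning for cohorts); identical seeds give bit-identical synthetic data
and forest predictions.

## Known limitations

- Reading is limited to delimited text; native binary device formats
  (e.g. .cwa) must be converted upstream.
- The sleep detector's candidate statistic is a documented stand-in for a
  published short-segment criterion whose exact form is parameterized, not
  reproduced; parameters are exposed for later matching.
- Non-integer sample rates (e.g. 12.5 Hz) are untested for the sub-minute
  sleep quietness statistic, which assumes an integer number of samples
  per second.
- Thresholds shipped as defaults apply to 10 Hz wrist data from the
  dominant hand; other placements, rates or devices require re-learning
  via the optimizer.
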