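# Methods

This note documents the models, conventions and numerical choices behind
`eveninghrv`, and what the synthetic cohort does and does not emulate.

## NN-interval filtering

Raw chest-strap RR exports are cleaned in a single left-to-right pass. Beat
*i* is removed when its interval is **below 400 ms or above 1300 ms**
(bounds inclusive on the retained side: exactly 400 or 1300 ms is kept), or
when it deviates from a running reference median *M* by more than
**0.70 · M**, where *M* is the median of the **5 most recently retained**
intervals. Two choices here were genuinely open:

* *Retained vs raw reference.* The deviation reference uses already-accepted
  intervals only, so a burst of artifacts cannot poison the median that
  judges the beats after it. The alternative (median of the raw previous 5)
  is strictly worse at artifact runs and was rejected.
* *Cold start.* The deviation rule is inactive until 5 intervals have been
  retained. A shorter early median would make the first beats' fate depend
  on series length; skipping the rule is reproducible and affects at most a
  few beats per recording.

The filter removes, never interpolates: downstream metrics operate on
irregularly spaced retained beats, which the spectral path handles by
explicit resampling. The filter is idempotent by construction (every
retained beat would be retained again), which the tests verify.

## Segment extraction and questionnaire alignment

An analysis segment is a **240-s window of consecutive retained beats** with
no inter-beat gap above 2000 ms ("breakless" — the threshold is a
convention, exposed in `SegmentSpec`; 2 s ≈ two skipped beats at rest, the
point at which a gap stops looking like normal variability). Candidate
windows start at each retained interval's onset; among candidates whose
start lies within the ±15-min questionnaire tolerance of a grid time, the
one with the smallest |start − grid| wins, ties going to the earlier window.

Questionnaire rows are matched to grid times per participant by minimum-cost
assignment (`scipy.optimize.linear_sum_assignment`) on absolute clock
offset, with matches beyond the tolerance forbidden — each row is used at
most once, and the assignment minimizes the total offset rather than being
greedy. Clock times are local wall-clock at minute resolution; recordings
are assumed not to cross midnight (evening design).

## HRV metric battery

Conventions follow the common HRV-toolkit definitions so that table columns
are comparable across software:

* **Time domain.** `sdnn` is the sd of NN intervals, `rmssd` the root mean
  square of successive differences, `sdsd` their sd, `nni_50`/`nni_20`
  counts of absolute successive differences above 50/20 ms with `pnni_x =
  100·nni_x/(N−1)`, `cvsd = rmssd/mean_nni`, `cvnni = sdnn/mean_nni`, and
  heart-rate statistics from the instantaneous rate 60000/NN. All standard
  deviations are **population (ddof = 0)** by default; `ddof` is a single
  switch (`PipelineConfig.sd_ddof`) because both conventions circulate.
* **Frequency domain.** The interval series is resampled at **4 Hz by cubic
  spline** (comfortably above twice the 0.40-Hz HF upper edge),
  mean-removed, and analysed with **Welch: 120-s Hann segments, 50 %
  overlap** — inside a 240-s window that is two full segments plus one
  straddling, a deliberate compromise between frequency resolution
  (1/120 Hz, fine enough to separate LF from VLF) and variance reduction.
  Band powers integrate the density by trapezoid over VLF 0.003–0.04, LF
  0.04–0.15, HF 0.15–0.40 Hz. `total_power` is defined as **VLF+LF+HF
  only**: a 4-min window is shorter than one cycle below the VLF floor, so
  power below 0.003 Hz is not estimable and is excluded rather than
  reported. `lfnu`/`hfnu` normalize to LF+HF; `lf_hf_ratio = lf/hf` is NaN
  (never ±inf) when HF is zero, and NaNs propagate as missing through the
  statistics stage.
* **Poincaré descriptors.** sd1² = var(Δ)/2, sd2² = 2·var(NN) − var(Δ)/2
  (clamped at 0), transverse/longitudinal axes T = 4·sd1, L = 4·sd2, with
  csi = L/T, cvi = log10(L·T), modified_csi = L²/T; degenerate axes give
  NaN.
* **Sample entropy.** m = 2, r = 0.2·sd (the community-standard parameters;
  nothing in a 4-min segment motivates deviating), Chebyshev distance,
  self-matches excluded, both template counts taken over the N−m templates
  that admit an (m+1)-extension. The implementation is vectorized but
  numerically identical to the O(N²) double loop used as the test oracle.

A note on the Parseval check: the integral of a *single* Welch estimate over
the full grid scatters around the realized tachogram variance by roughly
±10 % when only ~9 half-overlapping segments are averaged — that is
estimator variance, not a scaling error. The calibration tests therefore
check the identity on the mean over 10 seeds (tolerance 5 %).

## Statistical design

Observations are binned per scale — KSS ≤ 4 low, 5–6 medium, ≥ 7 high;
SSS ≤ 2 low, 3 medium, ≥ 4 high — and **medium is excluded** from group
comparisons. Three analyses run per metric: a pooled low-vs-high
independent t-test (classic pooled-variance form; Welch is a switch), a
per-time-point two-sided Mann-Whitney U test, and a per-time-point Pearson
correlation against the raw score with all observations included. The
Mann-Whitney implementation uses the **exact null distribution when the
combined sample is ≤ 20 and tie-free**, otherwise the tie-corrected normal
approximation with continuity correction; the reported U is min-oriented
(min of the two one-sided statistics), the convention small-sample tables
use. p-values are two-sided and reported **raw** — the design reads
0.05 ≤ p < 0.10 as a trend tier, and a Benjamini–Hochberg adjustment is
available but off by default so the tiers keep their meaning. Within-subject
correlation across the five time points is deliberately not modelled
(independent tests per stratum); that is a known limitation of the design,
not an oversight of the implementation.

## Condition classification

A record's condition is the quadrant of (lfnu, hfnu) relative to reference
medians: (above, below) → stressed, (below, above) → drowsy. The framework
leaves the other two quadrants open; the default maps (above, above) →
awake and (below, below) → fatigued — an interpretation, exposed in
`SignatureTable.quadrant_assignment`. Since lfnu + hfnu = 100, those two
quadrants are unreachable when the reference medians themselves sum to 100
(as cohort medians of complementary quantities nearly do); the classifier
stays total anyway because references may be user-supplied per metric.
Exact ties on either axis fall back to *awake* with a boundary flag — the
least-committal label, and flagged so it can be audited. The default
reference is the **cohort median at the earliest grid time** (the 8 p.m.
biological-evening anchor); a per-participant policy exists for longitudinal
use. Auxiliary signature metrics (sdnn, cvi, modified_csi, sampen,
lf_hf_ratio) never override the quadrant: they fill direction flags and a
concordance score, because the framework treats them as correlates of the
conditions, not criteria.

## Synthetic cohort: what it emulates, and what it does not

The generator exists because evening home-recording datasets are typically
private. Defaults mirror the emulated study design: **32 participants × 5
time points** (20:00–22:00 every 30 min), recording from 19:45 in
contiguous 30-min blocks per time point, questionnaire completion jittered
around each grid time (sd 300 s, capped inside the ±15-min tolerance).

The tachogram of each block is `mean_rr` plus one **narrowband random-phase
harmonic process per band** (24 equal-amplitude cosines with frequencies
drawn uniformly from sub-bands kept away from the analysis-band edges —
VLF 0.008–0.032, LF 0.06–0.13, HF 0.18–0.34 Hz — total variance equal to
the programmed band power) plus white per-beat noise. Beats are placed
iteratively, each interval read off the tachogram at the previous beat
time. This construction makes band powers analytically controllable, which
is the property the parameter-recovery tests need; an
integrate-to-threshold pacemaker model would be more physiological but its
band powers are only approximately controllable. Consequences: the series
is stationary within a block, has no respiratory-frequency drift, no
ectopy-induced turbulence, no circadian trend within blocks — so passing
recovery tests demonstrates the *pipeline's* correctness on data with known
spectra, not robustness to every property of real recordings.

State presets (awake / stressed / drowsy / fatigued) encode the condition
signatures at magnitudes typical of seated adults: alert total power a few
thousand ms², stressed with LF ≈ 9 × HF, drowsy with HF > LF and a
~3-fold total-power collapse. Sensor artifacts are injected at **0.3
spikes + 0.1 ectopic events per minute** (a clean chest strap worn at
home): spikes replace an interval with a value outside 400–1300 ms, ectopic
events split one interval into a premature short beat plus its complement
(cumulative time preserved). The ground-truth mask lists only injected
beats that violate the physiological bounds by construction, so the mask is
provably a subset of what the filter must remove; the ectopic complement
interval is a legitimate-looking beat and is intentionally not masked.

Sleepiness scores come from a latent trajectory `3.6 + 1.1·(hours past
8 p.m.) + state offset + N(0, 0.9)`, clipped to the KSS range (SSS is an
affine rescale): an awake participant sits near KSS 4 at 20:00 and drifts
toward 6 by 22:00, while stressed/drowsy cells (+3.2) emit high scores.
The offsets are chosen so that binning produces usably sized low/high
groups at every time point, and the schedule draws a growing
high-sleepiness fraction (25 % → 70 % across the evening) that is
*stressed* at 20:00 and *drowsy* afterwards, mirroring the biological-
evening narrative. Any monotone coupling would satisfy the design; this one
is the simplest with interpretable units. Determinism: all randomness flows
from `numpy.random.SeedSequence` children of the cohort seed, so a fixed
config is byte-identical across runs.

## Problem sizes in the validation suite

The calibration and power checks run on ensembles sized for stable
estimates: type-I error from 500 label-randomized replicates drawn from a
pool of 150 independently generated awake-state segments (the empirical
rejection rate is compared against the *exact size* of the exact
Mann-Whitney test at n = 10 vs 8, 0.0434, within a 99 % binomial band —
the exact test is discrete, so its true size sits below the nominal 0.05);
power from 200 awake-vs-drowsy draws; spectral recovery from 20 seeds;
classifier accuracy from 20 eight-participant cohorts. The full 32 × 5
design runs once end-to-end to verify the observation count arithmetic.

## Known limitations

* The generator's stationary-within-block spectra cannot test robustness to
  nonstationarity, respiration coupling, or movement noise.
* Welch band powers on 240-s windows estimate VLF from ~1–10 cycles; VLF
  values carry large variance by nature and the recovery guarantees are
  stated for the LF/HF ratio only.
* The classifier is rule-based by design; no probabilistic calibration of
  the four labels is attempted.
* Statistics treat observations as independent across time points within
  participant.
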