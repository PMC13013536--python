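# Methods

This note documents the analysis model implemented in `poca`, the
parameters that matter, the numerical choices made where the design was
open, what the synthetic generator does and does not emulate, and the
known limitations.

## Signal model and pre-processing

A recording is an N_chan-channel matrix y⁽ᶜ⁾ sampled at the acquisition
rate, with time t = 0 at the first sample and an optional stimulation
window [stim_onset, stim_offset].  Locomotor-band activity in these
preparations lies between 0.15 and 1.5 Hz, so every recording is first
brought to a common working rate (`working_fs`, default 500 Hz; FIR
decimation for integer ratios, polyphase FIR otherwise — never
upsampling) and low-pass filtered at `lp_cutoff` (default 1.5 Hz) with a
4th-order Butterworth applied forward–backward.  Zero-phase filtering is
non-negotiable here: every downstream feature is anchored to peak
timestamps, which a causal filter would delay by a rhythm-scale lag.  The
0.15 Hz band floor is *not* applied as a high-pass; it enters only through
the FreqCK feature and the window lengths.  Edge transients are reduced by
odd-reflection padding of about three cutoff periods; the first and last
couple of seconds of phase and filter output remain edge-affected, and
phase-sensitive tests evaluate only the central portion of a trace.

## Instantaneous phase and synchronicity

Each channel is mean-removed and transformed to its analytic signal; the
instantaneous phase ϕ⁽ᶜ⁾(t) is its argument.  Mean removal guards the
phase against the large DC depolarization; the slow depolarization trend
itself is not detrended further (it is mostly ≤ the band floor, and the
low-pass has already confined the trace to the analysis band).

A sample of channel c is *synchronous* when its circular phase distance —
folded into [0°, 180°], so +350° and −10° are the same offset — to the
other channels is strictly below `sync_threshold_deg` (45°).  The
quantifier over "other channels" is configurable.  The default is
**all**: with the standard four-root montage the homologous and diagonal
roots form two synergy groups (lL2/rL5 vs rL2/lL5) whose members stay
mutually in phase even during locomotion, so requiring synchronicity with
*every* other channel is what actually distinguishes the alternating
locomotor state; under the existential reading the synchronicity signal
would be identically true for this montage.  `sync_quantifier: any`
remains available for montages without in-phase pairs.  Synchronicity
needs at least two channels; single-channel recordings run in a degraded
mode with SynIndex/nSynCK marked unavailable (NaN/False, flagged).

## Peak features

Candidates are the local maxima of the filtered trace; a plateau bounded
by lower samples yields one candidate at its first sample (a determinism
choice — any fixed convention works, but it must be fixed).

**Dynamic prominence.**  Within ±`window_s` (default 6.67 s = 1/0.15 Hz)
around a peak, the nearest *strictly* higher candidate on each side bounds
that side's search interval (the window edge if none; the recording edge
truncates the window).  The lowest sample of each interval is its minimum;
the higher of the two minima is the reference level; Pro = peak amplitude −
reference.  Equal-height peaks do not terminate the search — strict
inequality avoids zero-width intervals.  Wid spans the two crossings of
(amplitude − Pro/2), each linearly interpolated between samples and
searched only inside its interval; a side that never reaches the half
level is clamped at the interval end and flagged.  Computing prominence in
a local window rather than globally is what keeps the feature meaningful
on a non-stationary depolarizing trace.

**Depolarization level.**  The slow envelope is a centered moving average
over `dep_smooth_s` (10 s); Dep = max of the envelope after stimulation
onset minus its median over the baseline window [0, stim_onset), floored
at 10⁻⁶ of the signal range so Pro2Dep stays finite.  This estimator is a
package definition (no canonical formula exists for "depolarization
level"); both the window and the statistic are config-exposed.  Without a
stimulation window Dep is undefined and Pro2Dep is emitted as 0, flagged.

**Relative and regional features.**  Pro2Base divides by the mean Pro of
baseline-period candidates (fallback: 10th percentile of all Pro in the
channel, flagged, when stimulation starts before the first candidate).
LocDev is a *ratio* — Pro over the mean Pro of up to four nearest-in-time
neighbors, two per side, fewer at edges — chosen over a difference because
a ratio is scale-free across channels with very different gains; a single
candidate gets LocDev = 1.  The cycle frequency behind FreqCK is
1/mean(intervals to the previous and next candidate) (one-sided at edges);
a lone candidate fails FreqCK.  An alternative 1/(2·Wid) estimator was
rejected: the frequency of an oscillation *in a rhythm* is its cycle
period, not its pulse width.  SynIndex counts synchronous samples in a
centered `synindex_window_s` (0.4 s) window, truncated at edges with the
denominator equal to the samples actually in range.  StimCK is strictly
"after onset"; with no stimulation it is False for every peak (nothing is
post-onset).

## Classifiers

Features are min-max normalized to [0, 1] **within each channel**
(booleans map to {0,1}; a constant feature maps to 0).  A channel
presented at predict time is normalized by its own range — the only
defensible convention when new recordings arrive with unseen gains.

* *Thresholding* scans τ over the sorted unique normalized values plus a
  −∞ sentinel, maximizing training F1; ties break toward the smallest τ,
  and prediction uses strict ">".  The scan is exactly optimal over the
  decision family, which the tests verify against an exhaustive oracle.
* *RBF-SVM* uses C = 1 and γ = 1/(N_fea·mean feature variance) by default
  (both config-exposed; no values are canonical for this problem).  The
  fitted expansion (support vectors, αᵢcᵢ, b, γ) is stored explicitly;
  applying it by direct summation reproduces the solver's predictions,
  and serialized models predict through that expansion.
* *2-means* runs Lloyd's algorithm (10 restarts, fixed seed, tol 10⁻⁶);
  the cluster whose members have the higher mean **raw** prominence is the
  locomotor class, and prediction uses the strict nearest-centroid rule
  (an equidistant point is non-locomotor).

Neither libsvm nor k-means++ is row-order invariant by construction, so
training rows are brought to a canonical lexicographic order before the
solvers run; fitted models are then pure functions of the training *set*.
No class weighting is applied by default (the realistic ~1:3 class
imbalance is handled by selecting on F1 rather than accuracy).

## Rhythm characterization

Predicted locomotor peaks with consecutive gaps strictly below
`merge_gap_s` form one episode.  The default merge gap is 6.67 s = 1/0.15
Hz, consistent with the prominence window (2.5 s is selectable).  Dur sums
per-episode spans by default (`dur_mode: span` gives first-to-last peak).
mPer/PerCV use within-episode consecutive intervals only, so episode gaps
never pollute the period statistics.  AUC integrates (trapezoid rule) the
filtered trace above the baseline-window median across episodes, negative
parts clipped — under this definition AUC ≈ Dep × Dur on a clean episode,
which matches the magnitude relation seen in real locomotor data, as does
Duty = mWid/mPer (≈ 0.4–0.5).  CVs use the sample (n−1) standard
deviation.  Zero locomotor peaks yield NaN features (undefined, never 0);
one peak leaves the period-based features undefined.

## Evaluation statistics

SEN, PRE, ACC, F1 follow the usual confusion-count definitions with
zero-denominator conventions SEN = PRE = 0 and F1 = 0 when TP = 0, which
keep aggregation total.  Aggregation reports mean ± sd over
recording-channels (and per recording where requested): the channel is
the natural unit because classification and normalization are
per-channel.  Agreement between method-derived and reference rhythm
features uses ICC(2,1) — two-way random effects, absolute agreement,
single rater — computed from the two-way mean squares; it is the standard
form for method-vs-reference comparisons, and is cross-checked in the
tests against an independent implementation to 10⁻⁹.  Distribution shift
between datasets uses KL(P‖Q) = ΣP log(P/Q) estimated on a shared
equal-width 100-bin histogram over the pooled range with ε = 10⁻¹⁰
smoothing and renormalization: bounded, reproducible, and zero for
identical samples to within the smoothing.  Feature diagnostics apply a
chi-square test (no continuity correction) to the boolean checks, a
Student's t-test to the continuous features, and a correlation matrix
that uses Spearman when both variables are binary and Pearson otherwise.

## Synthetic recordings

The generator emulates a stimulation trial: a common-phase baseline
sinusoid (0.3 Hz, amplitude 0.2) across all channels; at stim onset
(20 s) a logistic depolarization rise over 5 s to amplitude 1.0; a
locomotor sinusoid (0.4 Hz, amplitude 1.0) gated over a 30 s episode with
2 s raised-cosine ramps and per-channel phase offsets (lL2 0°, rL2 180°,
lL5 180°, rL5 0° — left-right and flexor-extensor alternation); baseline
attenuated ×0.3 under the episode so non-locomotor activity coexists with
locomotor activity; exponential repolarization (τ = 5 s); additive white
Gaussian noise (sd 0.02 = 10% of the baseline amplitude).  These defaults
are the package's study conditions: 120 s recordings, ~160 detected peaks,
and a true/false peak ratio ≈ 0.39, inside the realistic 0.2–0.6 range
for such preparations.  Ground truth lists every analytic crest time —
baseline crests as non-locomotor, locomotor crests (where the gate is at
least half amplitude, i.e. actually expressed) as locomotor — and
detected candidates inherit labels by greedy nearest-distance one-to-one
matching within 0.25 locomotor periods.

What the generator does *not* emulate: non-sinusoidal cycle shapes,
bursting or spike-level structure, drifting periods, movement or
stimulation artifacts, inter-channel gain differences, and non-Gaussian
electrode noise.  Tests passing on these simulations therefore establish
the *correctness of the computations* (detection, features, classifiers,
rhythm arithmetic) under the stated conditions — not field performance on
recorded data, whose variability is far richer.  The near-perfect
held-out F1 on the benchmark reflects the clean class separation the
generator produces by design.

## Problem sizes

The test suite and the acceptance script run on ten 120 s, four-channel
recordings at 2 kHz (decimated to 500 Hz), a five/five train/test split,
plus one noise-free recording; the brute-force prominence cross-check
uses 100 random band-limited signals of up to 5,000 samples.  These sizes
were chosen so the whole suite completes in well under a minute while
every oscillation regime (baseline, ramp, episode, repolarization) is
exercised.

## Known limitations

* "Depolarization level", LocDev, the FreqCK frequency estimator and the
  AUC baseline are package definitions, config-exposed, since no
  canonical formulas exist; results for these features depend on those
  choices.
* The per-channel self-normalization at predict time means a channel with
  *no* locomotor activity still maps its largest peaks near 1, which can
  inflate false positives on locomotion-free recordings; thresholding on
  an absolute-scale feature (Pro2Dep) mitigates this.
* Single-channel recordings lose all synchronicity information.
* The feature-subset search enumerates all non-empty subsets of a
  user-chosen pool (capped by a budget); for the full 12-feature pool
  that is 4,095 fits and is rarely worth running exhaustively.
* Exit codes of the CLI follow the click convention (2 = usage error,
  1 = domain error), not 1 = user / 2 = internal.
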