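# Methods

This note records the models, conventions, and numerical choices behind
`somnophot`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and where the design was genuinely
open.

## Signal conventions

All times are seconds from recording start; intervals are half-open
`[onset, onset + duration)`. Channels are uniformly sampled and may
have different rates (1 kHz photometry and EEG/EMG next to 1 Hz
amperometric lactate in the acquisition this emulates; the test suite
runs at 200 Hz / 50 Hz because every analysis window is specified in
seconds and nothing downstream depends on the rate).

FRET ratios are mVenus/CFP for the ATP sensor and CFP/mVenus for the
FRET lactate sensor; the ratio convention is stored on the trace.
Display traces use a 100-point moving average and quantitative
parameters a 500-point moving average, both defined at 1 kHz and scaled
with the sampling rate (0.1 s and 0.5 s windows). The moving average is
centered with truncated edge windows: it preserves length, is
idempotent on constants, and is symmetric around event onsets, which is
why the centered (rather than causal) form was chosen.

Baseline normalization uses the mean of the already-filtered trace over
the 5 s before the anchor (one 4-s epoch for sub-state onsets):
ΔR/R = (R − R₀)/R₀, ΔF/F analogously, percent-of-baseline for lactate.
In delta modes the normalized trace averages exactly zero over its own
baseline window — an algebraic identity the tests assert at 1e-12.

AUC is the trapezoidal integral at native sampling with exact
piecewise-linear handling of off-grid window and exclusion boundaries.
The stimulation convention integrates the 30-s light window minus 1 s
of each light exposure; because the default window ends at 30 s, the
yellow-light exclusion [30, 31) only matters when a caller extends the
window — both readings of the convention therefore coincide here, and
the effective default window is [1, 30). Signed-AUC splits insert exact
zero crossings before clipping so that positive + negative equals the
total integral to rounding error. Extrema are located by argmax/argmin
with earliest-sample tie-breaking; the biphasic mode searches the
trough before the global maximum and then re-searches the peak after
the trough, so trough time < peak time by construction; flat traces
and boundary troughs raise a warning rather than an error. Peak-search
windows (unspecified in the emulated protocol) default to [1, 120] s
for stimulation-aligned fluorescence, [30, 400] s for the late lactate
phase, and the full snippet for transitions; all are config-overridable.

## Sleep scoring

Features per 4-s epoch: delta (0.5–4 Hz) and theta (6–9 Hz) band power
from a single-segment Hann Welch periodogram, total power from 0.5 Hz
to Nyquist, and the RMS of 10–100 Hz band-passed EMG. The published
protocols this emulates cite "standard criteria" without printing them,
so the scorer implements the conventional decision tree: EMG above
threshold ⇒ wake; otherwise theta/delta above threshold ⇒ REM; else
NREM. The EMG threshold is calibrated per recording by an Otsu split of
the bimodal log EMG-RMS distribution; the theta/delta threshold
defaults to 2. An isolated single REM epoch flanked by wake is
relabeled wake. Epochs with non-finite features are flagged unscorable
and inherit the previous label for transition analysis.

Epoch labels expand to 1-s labels by repetition. An optional boundary
refinement moves a wake onset earlier within the preceding epoch to the
first second whose EMG metric crosses the wake threshold; whether the
original 4-s→1-s rescoring adjusted boundaries from signal content or
merely resampled labels is not documented, so both behaviors are
provided and the plain expansion is the default.

Sub-state onsets (active-awake within wake, micro-awakenings within
NREM) use a per-second EMG RMS threshold of mean + k·SD over all
parent-state seconds, k = 10. The source phrasing "mean greater than 10
times the standard deviation" is ambiguous; the additive form is the
default and the k·SD-only reading is available via
`threshold_rule="k_sd"`. Distinct onsets must be separated by an 8-s
(two-epoch) refractory gap — no merging rule is documented, this is the
package's choice. Threshold estimation requires ≥ 60 s of parent state.

Transitions at 1-s resolution require the new state to persist a
minimum bout (30 s for spontaneous NREM→wake awakenings, 0 otherwise)
and are flagged evoked when a stimulation onset lies in [t − 35, t] s
(1-s blue light + 30-s stimulation window + slack).

## Sessions and groups

A stimulation session is valid with ≥ 3 events (the protocol's "3 to 7
per session" lower bound, read inclusively; a strict > 3 is available
via `min_events`); a transition session is a 30-min measurement with
≥ 1 event. Invalid sessions are returned flagged, never silently
dropped, and group n counts valid sessions only. Session metrics are
computed on the 500-point-smoothed session-mean trace; group traces are
mean ± SEM across session means. Default snippet windows: stimulation
[−10, +120] s (fluorescence) and [−60, +400] s (lactate), transitions
[−30, +60] s, sub-state onsets [−8, +20] s. Recordings longer than 30
min are treated as one transition session by default (tiling into
30-min sessions was considered and not enabled by default).

## Nonparametric battery

Exact p values are full enumerations: 2ⁿ sign assignments for the
signed-rank test (n ≤ 15 after zero removal; ties mid-ranked; zeros
dropped by default, Pratt's method by flag), all C(N, n_a) group
assignments for Mann-Whitney (N ≤ 16; valid with ties through
mid-ranks), and all products of within-block rank permutations for
Friedman (k = 3, n ≤ 8, on request). The cutoffs keep each call under a
second. Above them, tie-corrected normal / chi-square approximations
without continuity correction are used (so Kruskal-Wallis at k = 2
matches the Mann-Whitney normal approximation exactly). Kruskal-Wallis
delegates to the standard tie-corrected implementation in scipy.

Steel-Dwass: for each pair, the rank-sum z from the pair's own pooled
ranks; √2·|z| referred to the studentized-range distribution with k
groups and infinite df. The df=∞ tail is evaluated from its closed-form
one-dimensional integral on a fixed 2001-point grid (absolute accuracy
≈ 1e-9, cross-checked against scipy's studentized range at large df).
Steel: each treatment-vs-control |z| referred to the maximum of k−1
equicorrelated (ρ = 0.5, the balanced-design correlation induced by the
shared control) standard normals, integrated by seeded Monte-Carlo with
10⁵ draws by default (SE of an adjusted p ≈ √(p(1−p)/n)); tests verify
the Monte-Carlo tail against multivariate-normal CDF quadrature.

A known small-sample property, measured rather than hidden: with k = 3
groups of n = 10 the rank-sum statistic is integer-valued, and the
asymptotic Steel-Dwass procedure rejects any pair only at
|W − 105| ≥ 32 versus the continuous cutoff 31.04, making the measured
family-wise error ≈ 0.039 at α = 0.05 (converging to ≈ 0.05 by
n = 20–40). The procedure is therefore slightly conservative — it never
exceeds its nominal level — at the smallest group sizes.

Multiple endpoints (AUC, peak, peak time) are tested separately without
cross-endpoint correction, mirroring common reporting practice.

## Synthetic-data generator

The generator's purpose is statistical, not biophysical: it produces
data with the structure the analysis assumes, plus ground truth for
parameter-recovery testing. It deliberately does not model the
serotonin–astrocyte–neuron signaling cascade (no kinetic equations are
available), hemodynamic or motion artifacts, or real EEG
nonstationarity.

- **Hypnogram**: semi-Markov chain; wake ↔ NREM, REM entered only from
  NREM (p = 0.25) and exiting to wake. Bout durations are shifted
  exponentials (20-s minimum dwell, mean preserved at the configured
  state mean: wake 150 s, NREM 180 s, REM 75 s — light-phase mouse
  architecture). The minimum dwell keeps bouts resolvable at the 4-s
  epoch scale.
- **EEG**: sum of delta-, theta-, and broadband-filtered unit-variance
  noises weighted per second by √(relative band power) per state
  (wake 1.5/1.0/1.0, NREM 6.0/1.0/1.0, REM 0.5/3.0/0.8), scaled to
  ~20 µV. These weights produce the NREM > wake > REM delta/theta
  ordering in ≥ 95% of epochs.
- **EMG**: white noise with per-second amplitude drawn from the state's
  (mean, sd) in µV — wake (30, 8), NREM (8, 2), REM atonia (4, 1).
  Injected bursts multiply the state mean for a configured duration and
  are logged as ground truth.
- **Stimulation protocol**: 1-s blue light opening the step-function
  opsin, 1-s yellow closing it 30 s later; 3–7 per session (drawn or
  configured) at ≥ 5-min intervals (≥ 7 min for lactate protocols);
  onsets gated on ≥ 20 s of established target state read from the true
  hypnogram (the in-vivo gating was an online visual judgment; an
  optional gating-error probability, default 0, models misjudgment).
  Control sessions use yellow light in place of blue and evoke no
  response. With probability 0.8 a blue stimulation delivered in sleep
  inserts a wake bout 5–15 s after onset, emulating
  stimulation-induced awakening; physiology is synthesized from the
  post-insertion labels.
- **Sensor responses**: difference-of-exponentials kernels (normalized
  to peak amplitude; closed-form peak time) conditioned on the state at
  stimulation onset. Defaults for the ATP-sensor-like ΔR/R response:
  wake 0.5%, NREM 1.0%, REM 1.5%, latency 1 s, rise 1.5 s, decay 20 s.
  The FRET lactate sensor uses a biphasic kernel (trough depth 1%,
  decay 6 s, followed by a delayed positive component); amperometric
  lactate uses a bimodal kernel in percent (fast early component plus a
  slow component delayed 60 s, peaking ≈ 106 s after onset, inside the
  30–400 s late window). FRET responses split 60% / −40% across
  numerator and denominator channels (an arbitrary but recorded
  anti-correlation); channels carry photobleaching (numerator tau 4 h,
  denominator 1.2× slower, so the ratio drifts slowly), a slow
  random-walk drift, and Gaussian noise whose ratio-scale SD is 0.2% by
  default. State-dependent baseline offsets (wake +0.6%, REM +0.4%,
  NREM 0, smoothed with a 3-s time constant) give transitions a
  realistic signal change for the transition-aligned designs.
- **Determinism**: all randomness derives from one seed through
  CRC-keyed sub-streams per component, so identical configs give
  bit-identical recordings and the hypnogram is invariant to, e.g.,
  adding EMG bursts.

What passing tests on these data do show: the scoring rules, alignment
bookkeeping, normalization identities, integration, extrema logic,
session rules, and statistical procedures are correct, and injected
effects of realistic size are recovered at the stated noise levels.
What they do not show: robustness to artifacts, nonstationary spectra,
scorer disagreement, or sensor nonlinearity — none of which the
generator emulates.

## Problem sizes and defaults used in validation

The test suite and `scripts/acceptance.py` use 200 Hz (or 100 Hz)
EEG/EMG and 50 Hz (or 25 Hz) photometry with 28–120 min sessions;
parameter-recovery experiments use single-state hypnograms with
stimulation-response amplitudes at the generator defaults and zero
state-baseline offsets (so the injected kernel is the only
stimulation-locked signal), 5 stimulations per session for amplitude
recovery and 3 per session in the replicate-experiment power runs, and
the analysis peak window [1, 30] s. The state-comparison pipeline
design enriches REM dwell (150 s mean, entry probability 0.7) for
REM-targeted sessions so a session can host ≥ 3 REM-gated
stimulations; in vivo the equivalent is simply recording until enough
REM stimulations accrue.

## File formats

The native container is one HDF5 file (channels with rate/units/kind
attributes, an event table, JSON metadata) with lossless round trips.
EEG/EMG export to EDF uses a hand-written minimal writer (1-s records,
16-bit samples against the per-signal physical range), with the
documented quantization-only loss of one step in
(phys_max − phys_min)/65535; round trips are verified through an
independent EDF reader. Events export to plain CSV with a JSON
attributes column. EDF export requires an integer sampling rate and a
single uniform rate per file.

## Known limitations

- The scorer is threshold-based; it has no learned model and no
  artifact rejection, and its accuracy guarantee is only demonstrated
  on the generator's stationary spectra.
- Steel/Steel-Dwass use the asymptotic references (slightly
  conservative below n ≈ 15 per group, as quantified above); exact
  permutation references for the post-hocs are not implemented.
- The generator's evoked-awakening model inserts wake bouts with a
  fixed probability and 5–15 s latency; it does not model
  stimulation-intensity dependence.
- Mouse-level pooling of multiple sessions is by simple means; no
  mixed-effects modeling is offered (the analyses this package
  reproduces are session-level nonparametrics).
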