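# Methods

## Stimulus coding

The speller multiplexes 32 targets onto one 63-bit maximal-length
sequence (m-sequence) flashed at a 60 Hz refresh; target *k* uses the
base code delayed by `bit_lag * k = 2k` bits.  Because 63 is odd, the 32
even shifts 0, 2, …, 62 are distinct modulo 63, so the attended target is
identified by the cyclic offset of the evoked response.  The LFSR
polynomial of the originally deployed code is not recoverable; any
primitive degree-6 polynomial yields the same two-valued autocorrelation,
so the generator defaults to taps {6, 5} with initial state 1 and both
are configurable and recorded with the session.  The generator verifies
maximal period at run time and rejects non-primitive taps.

The shift direction is a pure convention.  This package fixes *delay*
("target k's code is the base code delayed by 2k bits",
`np.roll(bits, +2k)`) and uses it identically in code generation, the
simulator and template shifting; classification only requires
consistency.  One boundary consequence: delaying a target-31 trial by one
further target step lands on shift 64 ≡ 1 (mod 63), which is not on the
even-shift lattice, so shift equivariance of the classifier is exact for
targets 0–30 and has no wrap-around successor at 31.

Trial timing defaults: 1.05 s stimulation (63 bits / 60 Hz), 0.85 s
pause, 150 ms feedback highlight; the nominal selection period is 1.9 s.
Reported information transfer rates always take the trial duration as an
explicit argument — published per-subject ITRs imply slightly varying
measured durations, so no duration is silently assumed in reports.

## Synthetic EEG

The forward model is deliberately minimal: one latent source emits a
fixed waveform spanning one code period, delayed by a cortical latency
(default 36 ms, the published cross-correlation delay of the response),
mapped to the scalp by a unit-norm mixing vector concentrated over
parieto-occipital channels with its maximum at P4, plus additive noise.
Target *k*'s trial is the target-0 trial delayed by 2k bits — exactly,
in the noiseless case, which many tests exploit.

* **Kernel.** Default: a sum of three damped sinusoids (7.5 / 13 / 21 Hz,
  amplitudes 5 / 3.5 / 2 µV, 0.35 s decay).  The true single-trial
  waveform is not recoverable from published scalp averages, so the
  kernel is a configurable array; an alternative constructor convolves
  the ±1 code impulse train with a short damped oscillation, giving a
  broadband code-locked response with near-delta autocorrelation.
* **Mixing.** Relative weights from a fixed table (P4 = 1.0 down to a
  0.08 leak on frontal channels), normalized to unit norm.  The montage
  is the 30-channel 10-20 set used for recording (reference Oz and ground
  FCz are therefore absent).
* **Noise.** White Gaussian, default 3 µV per sample, with an optional
  1/f fraction.  The amplifier's 0.5–60 Hz Chebyshev characteristic is
  not applied by default: tests are more transparent on white noise.
* **Latency.** Applied as a circular fractional delay (FFT phase ramp;
  integer shifts use exact rolls).  The classifier never compensates
  latency — templates absorb it, as in the online system.
* **Drift.** Slow nonstationarity is a per-trial latency increment and/or
  multiplicative gain on the response.  The closed-loop studies use
  +0.1 ms latency per trial, i.e. about two code bits across a 192-trial
  session — enough to pull a frozen classifier off its templates while
  remaining slow relative to single-trial SNR.
* **ErrP epochs.** Error feedback plants two deflections with a
  fronto-central scalp profile (maximal between Fz and Cz): −3 µV around
  310 ms (22 ms width) and +5 µV around 420 ms (35 ms width), scaled by
  `amplitude_scale`; correct feedback plants nothing.  Epoch noise is
  6 µV white, which the 1–16 Hz analysis bandwidth reduces to roughly
  1.3 µV — a detector trained on 200 epochs/class at scale 1 lands in the
  middling sensitivity range, matching the flavour of online detection,
  and becomes near-perfect at scale 2–3.

What the simulator does **not** emulate: volume-conducted correlated
noise, eye blinks/EOG artifacts (only synthetic large-norm artifact
trials appear, in robustness tests), the non-target complementary
flickers, latency jitter within a trial, and any realistic head
geometry.  Passing tests therefore demonstrate correctness of the
*pipeline* under the signal structure the method assumes, not expected
performance on recorded EEG.

## Decoding pipeline

* **Best channel.** Leave-one-out cross-validation on the label-aligned
  training trials: per channel, each trial is classified by Pearson
  correlation against the 32 circular shifts of the remaining trials'
  average; the channel with the highest LOO accuracy wins, ties to the
  lowest index.  The correlation classifier (not the OCSVM) is used here;
  channel selection is recomputed at every retrain, with a flag to freeze
  it.
* **CCA.** With a univariate reference (the tiled best-channel average),
  the canonical pair reduces to `w ∝ Cxx⁻¹ cxy` on centered data.  A
  trace-scaled ridge of 1e-8 guards degenerate synthetic inputs (a
  warning is logged if the covariance is rank-deficient); weights are
  unit-norm with the sign fixed so the canonical correlation is
  nonnegative, because Euclidean template matching is sign-sensitive.
* **Template.** The one-class SVM with linear kernel (LibSVM via
  scikit-learn) yields dual weights on the capped simplex
  (Σα = 1, 0 ≤ αᵢ ≤ 1/(νn)); the template is the weighted mean Σαᵢxᵢ.
  Any weight on a trial far from the bulk incurs a quadratic norm
  penalty, so artifact-scale outliers are excluded or capped — the
  "robust averaging" role of the OCSVM.  This robustness is a
  large-deviation property: for contamination at the scale of the noise
  shell no reweighting scheme dominates the plain mean, and the tests
  plant artifacts roughly 9× the clean-trial norm (the blink/movement
  regime).  Default ν = 0.5, configurable; one training trial returns
  that trial.  The template's overall scale is slightly shrunk relative
  to the mean (the dual minimizes the weighted-mean norm), which leaves
  the argmin-distance classification invariant since all 32 shifted
  templates share it.
* **Classification.** Minimum Euclidean distance over the 32 shifted
  templates on the full 630-sample window, computed via one FFT circular
  cross-correlation; ties to the lowest index.  Trial energy is not
  normalized before the distance (nothing suggests it was); a
  correlation-based classifier with plain averaging is retained as the
  baseline comparator and for channel selection.

## Adaptation

The classifier state is a multiset training buffer (trials re-shifted to
the target-0 frame with the label they were added under), the spatial
filter and the template set; a retrain rebuilds everything from exactly
the buffer and increments a generation counter.  Retraining uses all
accumulated trials — no forgetting window is described, though one is
exposed for drift experiments.  The online system's parallel adaptation
loop is abstracted into a deferred mode measured in trials: trials
arriving during a retrain fold into the next one, classification always
uses the latest completed generation, and the final buffer equals the
synchronous buffer.  Co-adaptive calibration starts from a standard
normal random template (the distribution is this package's choice) and a
uniform unit-norm spatial filter; with a single buffered trial no LOO
channel selection is possible, so the previous (or initial) filter is
kept and the template is that filtered trial.

During 2-target ErrP calibration, classification is restricted to the
pair's two templates; full 32-target classification resumes afterwards
(the circular-shift design makes a 2-target calibration sufficient for
all targets).  The 2-target design's failure mode is reproduced
faithfully: with a detector that never fires, self-training can lock
into the swapped label mapping and stay below 50 % for the whole run.

## ErrP detection

Preprocessing follows the published order exactly: common-average
reference over all EEG channels, linear detrend, 1–16 Hz bandpass,
resample to 32 Hz, window 300–990 ms, channels Fz, Cz, CPz, Pz, POz.
Numerical choices where the text is silent: the bandpass is a zero-phase
4th-order Butterworth (filtfilt), resampling is polyphase after
filtering, and the window is half-open [300, 990) ms, which at 32 Hz
gives 22 samples per channel and 110 features (the printed endpoints are
compatible with 22 or 23; the convention is asserted in tests and
configurable).  The classifier is an RBF-kernel SVM at the historical
LibSVM defaults (cost 1, gamma = 1/n_features).  Training with a single
class returns a degenerate always-no-error detector with a logged
warning — the situation of a subject whose BCI never erred.  Closed-loop
studies may replace the trained detector by an oracle parameterized by
(sensitivity, specificity) to decouple adaptation behaviour from
detector quality.

## Evaluation conventions

Wolpaw bits per selection use the 0·log 0 = 0 limits and are defined as
0 for P ≤ 1/N: the raw formula turns positive again below chance, but
the published accounting prints 0 for the below-chance calibration run,
and below-chance "information" has no communication meaning.  Free
spelling counts error-free letters per minute; with a perfectly
perceived and perfectly classified backspace, trials = written +
2·deleted.  Table reproduction rounds percentages and rates to two
decimals, half-up.  Aggregation is either per-column means (session
averages) or pooled from summed counts and times (overall letters per
minute); both are provided because the published tables use both.

## Problem sizes in tests and studies

Unit and property tests run a reduced geometry — 120 Hz sampling
(2 samples per code bit, 126-sample trials) and an 8-channel posterior +
frontal montage — where one full retrain costs milliseconds; the shift
structure, latency and mixing are identical to the 600 Hz/30-channel
default, which the noiseless round-trip checks still use.  The
adaptation-ordering study runs 20 seeds of 64 calibration + 128 test
trials per regime at noise 4.5 µV with 0.1 ms/trial latency drift and a
(0.70, 0.98) oracle detector; the 2-target calibration studies run 64
trials per seed (50 seeds for the lock-in search).  These sizes were
chosen to make the qualitative contrasts (regime ordering, veto benefit
below ~85 % base accuracy, lock-in existence) statistically stable.

## Serialization and I/O

Codes, layouts, spatial filters and template sets serialize to JSON;
session logs stream to CSV/JSON-lines via pandas; trial sets export to a
compressed NPZ container (data, labels, fs, channel names) with JSON
metadata.  Import of real recordings (EDF/BrainVision) goes through MNE
when installed; the package itself never requires it.

## Known limitations

* The synthetic generator's simplicity means absolute accuracies and
  ITRs are functions of chosen noise levels, not predictions for real
  subjects; only orderings and structural properties transfer.
* The OCSVM template's robustness does not extend to small-offset
  contamination (see above); ν only bounds the weight cap.
* Latency drift is the only nonstationarity studied in depth;
  gain drift is implemented but exercised lightly.
* The ErrP detector is never adapted online, and classifier states are
  not transferred across simulated subjects.
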