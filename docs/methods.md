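# Methods

## Problem setting

The package reproduces, at desk scale, an on-demand cueing system for
freezing of gait (FoG) in Parkinson's disease: a wearable module samples 20
sensor channels at 40 Hz, classifies every sample as FoG / not-FoG in real
time, and triggers rhythmic vibratory stimulation while freezing persists.
Patient recordings cannot be redistributed, so the pipeline is exercised end
to end on synthetic recordings that match the statistical shape of the
clinical datasets (recordings of 9 k–100 k samples, FoG prevalence 1.5–15.4%,
4–86 discrete episodes per recording).

## Synthetic gait generator

`fogcue.simulate` tiles a recording with walking, standing, turning and
freezing episodes, then renders 20 channels in four groups (ACC 6, GYRO 6,
CF 4, MA 4):

* **walk** — a 1 Hz locomotor fundamental plus 2nd/3rd harmonics with fixed
  per-channel amplitudes and phases (1 Hz matches the cueing rhythm used for
  stimulation, i.e. approximate step rate), plus white Gaussian noise with
  per-group standard deviations (ACC/GYRO 0.30, CF 0.10, MA 0.20 in
  arbitrary sensor units, against walk amplitudes of order 1);
* **stand** — noise only;
* **turn** — walk plus a slow 0.1–0.3 Hz offset drift on gyroscope and angle
  channels;
* **fog** — the locomotor component attenuated to 10% and a low-amplitude
  3–8 Hz trembling band added on the IMU channels, with doubled noise
  variance on the muscle-activity channels.

Trembling-in-place is the documented surrogate for the raw signal morphology
of real freezes, which is not characterized in the source material; it is a
modeling assumption, chosen because the trembling band is the classical
spectral signature of FoG in the literature on freeze indices. Episode
scheduling draws FoG durations uniformly from 2–6 s and rescales them so the
prevalence target is met exactly (episode count wins when count and
prevalence conflict); freezes are separated by at least 1 s of other
activity. Defaults (500 s, 12 episodes, 8% prevalence) describe a mid-sized
personal training session inside the observed clinical ranges.

What passing tests on this generator show: that the windowing, training,
streaming and evaluation machinery is correct and that the classifier can
learn a spectrally distinct freeze signature from strongly imbalanced labels.
What they do not show: performance on real patient data, where freeze onsets
are gradual, morphology varies across patients and days, and labels are
uncertain near boundaries.

## Windowing

The model input for sample *t* concatenates the current sample and its PS
predecessors, newest first (length 20·(PS+1); 800 at PS = 39). Batch and
rolling-buffer construction are bit-identical; this is asserted, not assumed,
because the deployed detector is only trustworthy if online preprocessing is
the same arithmetic the model was trained on. No window is emitted until the
buffer holds PS+1 samples — the first PS samples of a stream yield score 0
and cannot trigger a cue — rather than padding with fabricated history; at
40 Hz the warm-up is at most 2.5 s for PS ≤ 100. The complementary filter
used for the angle channels defaults to α = 0.98.

## Classifier

Normalization layer (learned γ scale and β offset per input feature, batch
moments during training, running moments at inference; momentum 0.99,
ε = 1e-3) → reshape to (time, channels) → 1-D convolution along time
(32 filters, kernel 5, same padding, ReLU; the conv block holds
32·(PS+1) = 1280 features at PS = 39) → two simple tanh RNN layers (64, 32
units) → dense sigmoid scalar. The recurrent scan runs oldest → newest so
the final hidden state — the one the output layer reads — is anchored on the
sample being classified; scanning in the stored (newest-first) order
measurably blurs detection at episode boundaries.

The normalization layer is realized as feature-wise standardization with
learned affine parameters because the deployed model must normalize
dynamically inside the network (dataset-wide static moments go stale as data
accumulate). Which normalization family the original embedded model used is
not recoverable; this choice fixes the behaviour contract (inference uses
learned statistics only).

Training: weighted binary cross-entropy from logits, inverse-frequency class
weights (FoG is a few percent of samples; unweighted training collapses to
the majority class), Adam at 1e-3 with global gradient-norm clipping at 1.0
(BPTT through the tanh recurrences occasionally explodes, and one unclipped
step derails the fit), batch 128, 10 epochs, chronological 60/40
train/test split (gait samples are strongly autocorrelated; a shuffled split
would leak). Everything — parameters, activations, gradients, Adam moments —
is float32, matching the single-precision arithmetic of the embedded target.
All randomness (init, shuffling) derives from `random_state`.

The exact convolutional and recurrent stack sizes are design choices: one
conv layer with 32 filters and two simple RNN layers of 64 and 32 units form
the minimal architecture consistent with the printed shape arithmetic
(800 → 20×40 → 1280 → … → 1). The "flatten" between conv and RNN is
interpreted as a sequence view of (PS+1 time steps × 32 filters); feeding a
length-1280 scalar sequence to an RNN would be computationally implausible
on the target hardware.

PS is a per-patient hyperparameter tuned over {15, 30, 40, 60, 100} by
held-out F1, ties broken toward the smaller (cheaper) value.

## Streaming detector

Detection is strict (`score > threshold`); threshold default 0.9,
configurable per patient. The `FoG_condition` countdown is set to 3 on
detection and decremented once per 40 samples since the last detection, so
the cue persists exactly 120 samples after an isolated detection; the
decrement timer restarts at each detection. Cue on/off transitions are logged
as JSON-lines commands (a stand-in for the RF commands to the vibration
actuators, which are out of scope along with all hardware concerns).

Offline/online identity is guaranteed by construction: batch prediction and
the streaming driver score the same window sequence through one shared
fixed-chunk (512-row) forward routine, so no BLAS kernel-selection difference
can creep in between the paths. Buffer updates remain strictly per-sample;
amortizing the model calls changes no value, since each window's score
depends only on that window.

## Evaluation

Sample-level: accuracy, precision, sensitivity, specificity, F1 from the
confusion counts; ratios with zero denominators are reported as 0 with an
`undefined` flag so extremely imbalanced recordings still produce a full row.
Event-level: an episode counts as detected if at least one thresholded
detection falls inside it; detection delay is the offset of the first such
detection from episode onset (samples, and ms at 25 ms/sample); a
false-positive event is a maximal run of detections overlapping no labeled
episode. Delay is measured on thresholded detections, not raw scores — the
literal reading of "time to detect". The ablation harness drops excluded
sensor groups before windowing (the window shrinks accordingly) and retrains
per combination.

## Stimulation statistics

Unpooled two-proportion z-test on FoG sample rates with and without
stimulation; z = (r₂−r₁)/SE so that a reduction is negative, two-sided
p = 2·Φ(−|z|), reduction (r₁−r₂)/r₁·100 reported to the nearest percent.
Sample-level Bernoulli independence is optimistic (within-episode samples are
autocorrelated), and the comparison is observational — the test quantifies
the rate change, not a causal effect. A pooled-null Monte-Carlo binomial
simulation (`exact_binomial_check`, add-one corrected) cross-checks the
normal approximation; it agrees within a small factor for |z| ≤ 4 and cannot
resolve the far tail (an empirical p from 10⁴ draws is floored at ~10⁻⁴).

## Problem sizes and numerical choices

The test suite and the acceptance script train on 20 000-sample recordings
(500 s at 40 Hz, ~12 000 training windows of 800 features), which this
implementation fits in roughly 10–15 s per model on one CPU; three
independent seeds bound the stochastic detection-recovery checks. Model
containers store a JSON header plus raw float32 arrays and round-trip
bitwise. Recording CSVs write floats with 9 significant digits, which
round-trips every float32 value exactly. Indexing is 0-based, episode
intervals half-open.

## Known limitations

* The generator's freeze signature is cleanly band-separated; real freezes
  are not, so absolute detection numbers here overstate clinical
  performance (the synthetic episode-recovery check is a scaled-down
  stand-in, not a clinical claim).
* Simple RNN cells; GRU/LSTM variants, multiclass activity heads, wavelet
  front-ends, quantization and embedded export are out of scope.
* Muscle-activity channels are statistical noise models, not physiological
  EMG.
* The two-proportion test inherits the with/without session pairing as
  given; no crossover design, no multiple-testing correction across
  patients.
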