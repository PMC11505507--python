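# fogcue

Freezing of gait (FoG) is an episodic inability to start or continue walking
that affects most people with advanced Parkinson's disease. Wearable systems
that detect a freeze within a fraction of a second can deliver an immediate
sensory cue — here, rhythmic vibration — that helps the patient resume
walking. `fogcue` is a desk-scale implementation of such a detection-and-
cueing pipeline: it simulates labeled multi-channel gait recordings, trains a
compact personalized classifier, replays it through the 40 Hz online loop
with a cue state machine, evaluates detection quality at the sample and
episode level, and quantifies the stimulation effect with a two-proportion
z-test.

## The method

Gait is sampled at 40 Hz from 20 sensor channels (two below-knee IMUs: 6
accelerometer + 6 gyroscope axes, 4 complementary-filter angles, 4
muscle-activity envelopes). The classifier input for sample *t* is the
past-samples (PS) window

> v = [u₁,ₜ … u₂₀,ₜ, u₁,ₜ₋₁ … u₂₀,ₜ₋₁, …, u₂₀,ₜ₋PS],

a single-precision vector of length 20·(PS+1) — 800 values at the canonical
PS = 39. Offline, all windows are built in one pass; online, a rolling buffer
shifts one position per 25 ms tick. The two paths are bit-identical.

The network is deliberately tiny (it must fit an embedded CPU):
a normalization layer with learned scale/offset (β, γ) and running moments,
a reshape to 20 channels × (PS+1) time steps, a 1-D convolution along time
(32 filters, kernel 5, same padding; the conv block flattens to
32·(PS+1) = 1280 features at PS = 39), two simple tanh RNN layers (64 and 32
units) scanning oldest → newest, and a sigmoid output neuron giving a FoG
score in [0, 1]. It is trained with weighted binary cross-entropy and Adam
(gradient-norm clipping) in float32 end to end, implemented directly on NumPy.

Online, a score strictly above the threshold (default 0.9; per-patient values
of 0.2–0.4 are supported) sets the `FoG_condition` countdown to 3; each full
second without a detection decrements it, so an isolated detection keeps the
vibratory cue active for exactly 3 s (120 samples). The stimulation effect is
tested per patient by comparing FoG sample rates r₁ (no stimulation) and r₂
(with stimulation) via the unpooled two-proportion statistic
SE = √(r₁(1−r₁)/n₁ + r₂(1−r₂)/n₂), z = (r₂−r₁)/SE, with a two-sided normal
p-value and percent reduction (r₁−r₂)/r₁·100.

## Worked example

```bash
fogcue simulate --duration 500 --prevalence 0.08 --episodes 12 --seed 11 --out rec.csv
# wrote 20000 samples x 20 channels to rec.csv
fogcue train --recording rec.csv --ps 39 --seed 11 --out model.fog
# trained ps=39 model on 11976 windows; final epoch loss 0.0016; saved to model.fog
fogcue stream --recording rec.csv --model model.fog --threshold 0.9 --trace-out trace.csv
# episodes detected: 12/12; fp events: 5; mean delay: 3.33 samples (83 ms)
```

The first command writes a 500 s synthetic recording (20 000 samples, 12
freezing episodes, 8% FoG prevalence). The second trains the classifier on
the chronological first 60% of windows. The third replays the whole recording
through the online loop: every labeled freezing episode triggered the cue,
five false-positive detection runs occurred, and the first detection came on
average 3.33 samples (83 ms) after episode onset.

The stimulation-effect table from the packaged per-patient counts:

```bash
fogcue stimstats
#  patient  fog_prob_without  fog_prob_with  reduction_pct        z             p
#        7          0.061814       0.042375          31.45    -6.67      2.64e-11
#        8          0.045658       0.025796          43.50    -7.77      7.62e-15
#        9          0.154251       0.065330          57.65   -22.22     2.01e-109
```

Each row compares the FoG sample rate without stimulation against the rate
while on-demand cueing was active: stimulation is associated with a 31–58%
reduction in the fraction of time frozen, significant for every patient.

Other commands: `fogcue tune-ps` (personalize the PS hyperparameter),
`fogcue evaluate` (sample-level metrics on the held-out split),
`fogcue ablate` (sensor-group importance study). The same functionality is
available as a library (`fogcue.FogClassifier`, an sklearn-compatible
estimator, plus `generate_recording`, `run_stream`, `event_report`,
`two_proportion_test`, …).

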