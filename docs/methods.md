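# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## The detection problem

A wearer poses 28 facial activities per session round — two of them jaw
clenches ("clench_short", "clench_long") — over three sessions recorded on
separate days with a 16-channel around-the-ear montage (labels L1–L8,
R1–R8) at 250 Hz. After epoching, the task is binary: does a given 1-second
epoch contain a clench? The positive class is rare (≈ 5 % of epochs under
the default protocol), and the evaluation is deliberately cross-session:
train on two sessions, test on the third. Cross-session transfer is the
regime a practical wearable detector must survive — electrode placement,
impedances and background activity all drift between days, and the
synthetic generator re-randomizes trial order per session to reflect that.

## Synthetic sessions

`earpipe.synthdata` generates each session as a sum of four components, all
seeded and byte-reproducible:

- **EEG background** — white noise spectrally shaped to power ∝ 1/f (flat
  below 1 Hz to avoid the DC singularity), scaled to 5 µV RMS, plus a 10 Hz
  alpha sinusoid (2 µV, random phase per channel). Amplitudes sit in the
  5–15 µV range expected from ear electrodes at rest.
- **EMG bursts** — for each annotated activity, band-limited (20–100 Hz
  Butterworth) unit-RMS noise multiplied by a raised-cosine envelope with
  50 ms ramps (rectangular gating would splatter energy across the
  spectrum) and by that activity's row of an (activity × channel) gain
  matrix. The default gains are random per activity/channel in the 3–8 µV
  range; clench rows are rescaled so their summed channel gain is
  `bruxism_scale` (default 3.0) times the median non-clench row sum. The
  rescaling-by-sum construction guarantees the learnability invariant
  (clench rows strictly above the median activity) for any scale > 1, which
  makes the gain sweep well-defined at scales close to 1. The 20 Hz lower
  edge reflects that surface-EMG energy is predominantly above 20 Hz; the
  100 Hz upper edge is clipped below the 125 Hz Nyquist limit.
- **Line noise** — a common-phase 50 Hz sinusoid whose amplitude envelope is
  a 2 µV baseline plus 20 µV during scheduled burst intervals (emulating
  contact with mains-powered equipment). It enters every recording channel
  at gain 1 and the designated open electrode (default L7, "covered with
  tape") at gain 20; the open channel carries *no* physiological signal.
- **Baseline wander** — noise low-passed below 0.5 Hz, 5 µV RMS, independent
  per channel.

**Protocol timing.** Activity durations are 2 s (4 s for the long clench)
with 2 s rest before each trial, so one round of 28 activities lasts 114 s
and the default 29 trials per activity yields ≈ 3,306 one-second epochs per
session — the scale of a real multi-session study — with clench samples
≈ 5 % of the session, comfortably inside the < 15 % imbalance regime the
pipeline is designed for. Tests and the acceptance script run the same
generator at 2–4 trials per activity (≈ 230–460 epochs/session), which
preserves every statistical property being checked while keeping runs fast;
the acceptance output records the problem sizes actually used.

**What the generator does not emulate.** No volume conduction or dipole
forward model (spatial patterns are random gains, not physiology); no
electrode-impedance drift within a session; no movement artifacts or
accelerometer channels; no ERP or sleep structure; short and long clenches
differ only in duration, not intensity. Consequently, a perfect F1 on
high-SNR synthetic data shows the chain is correct and leak-free — it does
not predict real-world accuracy, where cross-session variability is richer.
The gain sweep (`bruxism_scale` → 1) is the in-package way to probe graceful
degradation.

## Adaptive line-noise removal

`nlms_clean` implements textbook NLMS: zero-initialized weights over a
0.25 s tapped delay line (63 taps at 250 Hz), normalized step μ (default 1),
regularizer ε = 1e−8, no leakage. The first `n_taps` samples pass through
untouched because the regressor window is undefined there. A `rolling` mode
resets the weights every 2 s so slow drifts are not learned and subtracted
along with the line component.

**Step-size trade-off.** Adaptive cancellation has an irreducible
misadjustment: in steady state the excess broadband error is approximately
μ/(2−μ) times the power of whatever the reference cannot predict. μ = 1
converges within ~0.1 s and tracks amplitude bursts almost instantly — the
right default when the interference is large and non-stationary — but it
inflates the pass band by ~3 dB when the physiological signal dominates.
At μ = 0.1 the misadjustment falls below 0.5 dB while a 50 Hz line component
is still attenuated by ≳ 25 dB after the ~1 s convergence window. The
quantitative spectral-preservation checks therefore run at μ = 0.1 and skip
the first second; the attenuation property is additionally asserted at the
μ = 1 default. For the same reason no universal "cleaning never inflates
energy" bound exists: the 5 % energy bound in the property tests is asserted
where it actually holds, i.e. interference at least 4× the signal RMS and
μ ≤ 1.5.

The notch comparison (`compare_line_noise_removal`) contrasts raw,
FIR-notch-filtered (251 taps, 49–51 Hz stop band) and NLMS-cleaned PSDs,
summarized as the 50 Hz bin power and the mean PSD over 45–55 Hz. The
qualitative signature: both methods suppress the 50 Hz bin by ≥ 20 dB, but
the notch's 49–51 Hz mean collapses (the band hole) while NLMS leaves the
neighborhood intact — provided the underlying signal actually has power
there, which is why the comparison fixtures use broadband content.

**Welch PSD** uses 1 s Hann windows with 0.5 s overlap, density scaling.

## Preprocessing, epoching, features

Filtering follows the online-detector discipline: epochs are cut first
(non-overlapping 1 s windows anchored at sample 0, trailing partial window
dropped), then each epoch channel is mean-centered, band-passed 5–62 Hz
(order-4 Butterworth) and notch-filtered at 50 Hz (second-order IIR,
Q = 30). Both filters are applied forward–backward: zero-phase application
costs nothing offline and avoids shifting burst energy relative to the
epoch grid; a `filter_mode="session"` switch filters whole channels before
epoching instead, for cases where per-epoch edge effects matter.

Label timing uses a +350 ms shift of both annotation onset and offset
(reaction-time compensation — the wearer starts the activity after the
cue). The shift direction and "both ends" choice are configurable
(`shift_applies_to`), since delaying only the onset is also defensible. The
interval→sample convention is half-open with ceiling start:
sample i is labeled iff i/fs ∈ [onset+shift, offset+shift), so an
annotation [1.0, 2.0] s shifted by 0.35 s at 250 Hz labels samples
338–587 exactly. An epoch is positive iff its labeled-sample fraction is
≥ 0.5, inclusive (125 of 250 samples counts; 124 does not).

Feature conventions, fixed for oracle equivalence:

- variances are population-normalized (divide by n);
- a constant signal defines Hjorth (0, 0, 0) and both fractal dimensions 1;
- Petrosian uses log base 10 with N_δ counted between nearest nonzero
  first-difference values (exact zeros carry no direction, so plateaus do
  not create measure-zero ambiguity);
- Higuchi uses k_max = 10, a standard choice for 250-sample epochs
  (the construction needs n > 2·k_max), with FD the least-squares slope of
  ln L(k) against ln(1/k);
- `abs_sum` is not normalized by epoch length (epochs are constant-length,
  so it equals a scaled mean anyway).

Feature columns are channel-major in the fixed order (activity, complexity,
mobility, abs_max, abs_sum, higuchi_fd, petrosian_fd): 16 × 7 = 112.

## Training and evaluation

- **SMOTE**: synthetic minority rows x + u·(x_nn − x), u ~ U(0,1), x_nn one
  of the k = 5 nearest minority neighbors (Euclidean); k is reduced with a
  log message when the minority class is small. Classes are balanced to a
  1:1 ratio by default; originals are preserved verbatim.
- **z-standardization** is fitted on training rows only; constant columns
  map to 0 with a warning.
- **Classifier**: AdaBoost (SAMME weighting) over depth-1 decision trees,
  deterministic given its seed.
- **Cross-validation**: stratified 5-fold on the pooled training sessions,
  selecting `n_estimators` from {50, 100, 200} by mean F1. SMOTE and
  scaling are fitted *inside* each training fold — oversampling before the
  split would leak synthetic copies of validation rows into training, which
  is the canonical SMOTE mistake. The final model refits SMOTE + scaler +
  ensemble on all training rows. Decision threshold is the ensemble's 0.5
  vote; no threshold tuning.
- **Metrics**: precision, recall, F1, MCC with every 0/0 defined as 0.
  MCC is the headline metric because it uses all four confusion cells and
  is stable under the ~5–12 % positive prevalence here.

Leakage hygiene is tested directly: injecting an extreme outlier into the
held-out session must leave training-fitted scaler parameters and training
predictions bit-identical (the "canary").

## Validation experiments

`earpipe.experiments` packages the three study-level checks:

- **Held-out evaluation** (train S1+S2, test S3) at default SNR, compared
  with a 200-replicate label-permutation null of the F1 — the fitted
  detector must beat the null's 95th percentile.
- **Permutation sanity**: scoring the predictions against shuffled test
  labels must give MCC ≈ 0.
- **EMG-gain sweep**: median held-out F1 over 5 seeded replicates at clench
  gain scales (1.2, 2.0, 3.2) must be non-decreasing.

## Known limitations

- NLMS assumes the reference carries the interference and nothing else; a
  leaky or signal-bearing reference would subtract physiology.
- Per-epoch zero-phase filtering on 250 samples has edge effects within
  ~0.1 s of the window boundaries; the session-level filter mode avoids
  this at the cost of the online analogy.
- The synthetic spatial gain patterns make the problem easier than real
  cross-session transfer; absolute synthetic scores should not be compared
  with scores on recorded data.
- Only binary epoch labels are produced; the 28-class structure is kept
  solely as per-epoch metadata (`activity_of_epoch`).
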