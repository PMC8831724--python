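# Methods

This note documents the models, parameter choices, and numerical
conventions behind `somnoscore`, and what the synthetic benchmark does and
does not establish about real recordings.

## Data model

A recording is a continuous single-channel EEG trace in µV (assumed
band-limited to 0.5–48 Hz by the acquisition front end and sampled at
128 Hz) plus a motion-magnitude trace in G, derived at ingest as the
Euclidean norm of the three accelerometer axes.  Scoring operates on a
grid of 8-s epochs anchored at the first sample; trailing partial epochs
are discarded.  The sampling rate times the epoch length must be integral,
so an epoch holds a whole number of samples (1024 by default).

Each epoch is assigned to the light or dark phase by its *start* time
(half-open convention): light iff `start_offset + epoch_start <
light_phase_s`.  The default schedule is 12 h of light followed by 9 h of
analyzed dark (21 h total); epochs past the analyzed window are excluded
from phase-resolved outputs.  Anchoring the grid at the recording start
rather than at clock boundaries is a deliberate choice — it keeps the grid
independent of acquisition metadata; recordings are expected to start at
lights-on (`start_offset_s = 0`) unless stated otherwise.

## Clipping repair

Contact losses pin the EEG at the ADC rail.  The detector flags every
maximal run of at least `min_run = 4` consecutive samples with |x| ≥
0.99 × rail (31.25 ms at 128 Hz — long enough to ignore single-sample
spikes), merges runs separated by ≤ 32 samples, and pads each merged run
by 16 samples per side, since the onset and offset of a contact loss are
already distorted.  All four constants are configurable; they are
detection-policy choices, not physical constants.

The replacement is colored Gaussian noise: white noise is drawn, its rFFT
multiplied by √PSD of the target spectrum, inverse-transformed, and
rescaled so the sample variance equals the variance implied by the target
PSD (the trapezoidal integral over frequency).  The target PSD is the mean
of single Hanning-windowed periodograms of the two 512-sample (4-s) clean
flanks of the interval — one flank when only one exists, and the PSD of
all non-faulty signal as a logged fallback when neither does.  Four
seconds balances stationarity of the context against spectral resolution
(0.25 Hz).  The replacement is spliced with 16-sample raised-cosine
crossfades; because the crossfade lies inside the padded region, it blends
synthesized noise with *clean* signal and cannot reintroduce rail values.
Repair is idempotent (re-detection on the output finds nothing), conserves
every sample outside flagged intervals bit-exactly, and derives one child
seed per interval from the master seed, so editing one interval never
perturbs the noise in another.

## Features

Band decomposition uses discrete-Fourier masking: all rFFT bins outside
[low, high) are zeroed (the top band is closed at 48 Hz so the five bands
tile 0.5–48 Hz exactly, each bin counted once) and the spectrum
inverse-transformed.  Masking was preferred over IIR/FIR filtering because
it is deterministic, has no design ambiguity, and makes band variances add
up to the variance of the band-limited epoch to machine precision.  "Mean
amplitude" is the mean absolute value of the band-limited signal (the mean
rectified value); SDs are population SDs (ddof 0).

The Petrosian fractal dimension uses the log₁₀ form with N_δ = sign
changes of the first difference, *dropping zero differences* before
counting — variants exist in the literature, so the convention is pinned
here.  Constant or strictly monotone epochs give PFD = 1 exactly; values
slightly above 1 are expected for noisy signals under this form and the
sanity bound is (0, 1.1).

Movement duration per epoch subtracts the epoch median from the magnitude
(removing the gravity offset), rectifies, smooths with a 0.25-s moving
average, thresholds, and counts supra-threshold time.  The threshold
default is 0.1 G; `movement_threshold_from_baseline` derives it from a
recording as 3× the median across epochs of the smoothed excursion SD,
which is robust because most epochs contain no bursts.  Wake epochs with
more than 1 s of movement are *active*, the rest *quiet*; non-wake epochs
never carry a substage, even when motion is present.

## Staging

The classifier is a random forest: 100 trees, unlimited depth, √p feature
subsampling, trained on the 12-feature vectors with epoch-level labels.
Prediction ties across classes are broken by the fixed order WAKE < NREM <
REM rather than alphabetically, for documented determinism.  Feature
columns are matched by name, so a permuted but complete feature table is
accepted; missing columns raise.

Cross-validation uses stratified shuffled folds split at the epoch level
(k = 10 by default).  Epoch-level splitting measures in-distribution
epoch accuracy; because adjacent epochs are correlated in real data, it is
optimistic about generalization across recordings — for that question,
split folds by recording instead.  When k exceeds the smallest class count
(e.g. leave-one-out), plain shuffled k-fold is used.

The transparent rule-based scorer (high motion → wake; delta amplitude
dominant → NREM; theta dominant → REM; otherwise wake) uses a dominance
ratio of 1.5 by default: under the generator's default templates the
NREM delta/theta *amplitude* ratio is √(0.60/0.15) = 2.0, so a ratio
threshold of exactly 2 would flip a coin on every NREM epoch; 1.5 leaves
headroom on both sides.

## Spectra

Per-epoch spectra are single Hanning-windowed periodograms of the
mean-removed epoch, one-sided, scaled so the bin powers sum to the power
of the windowed epoch divided by the window's mean square — i.e. the total
equals the epoch variance, window gain corrected.  An 8-s epoch at 128 Hz
gives exactly 0.125 Hz bins.  Band power is the bin sum over the band
mask; relative power is each bin's share of the 0.5–48 Hz total and is
interpreted as a *ratio*, not a z-standardization across epochs.  Epochs
with zero total power are undefined and excluded from aggregation with a
log message.  Aggregation is the plain arithmetic mean of relative-power
vectors (and of total power) over the epochs matching a key; consequently
the whole-session mean equals the epoch-count-weighted mean of per-stage
means.  Epochs dominated by repaired samples are *included* — repair, not
rejection, is the artifact policy — and can be excluded upstream by
filtering on the repair report if desired.

## Architecture

Episodes are maximal runs of one stage label; there is no minimum episode
length (a single 8-s epoch qualifies), consistent with scoring that cannot
see sub-epoch micro-arousals.  Per-hour values divide totals by the
covered time of the scope, so partial hours are weighted by coverage.
Episodes straddling a phase boundary count toward the phase containing
their first epoch; durations, by contrast, are split by epoch membership.
Tables are per-recording; averaging across animals (and SEMs) is left to
the caller.

## Synthetic generator

The generator is the package's study condition, not a tuning knob.  Stages
follow a first-order Markov chain at the 8-s step with default transition
matrix

|      | WAKE | NREM | REM  |
|------|------|------|------|
| WAKE | 0.94 | 0.055| 0.005|
| NREM | 0.04 | 0.93 | 0.03 |
| REM  | 0.10 | 0.05 | 0.85 |

giving mean bout lengths of roughly 2 min (wake, NREM) and 1 min (REM),
typical of the polycyclic sleep of adult rats.  During the dark phase the
wake-persistence entry is raised by 0.04 (the other wake-row entries
rescaled), the simplest mechanism that reproduces more waking in the dark.
EEG epochs are sums of per-band Fourier-masked Gaussian noise with
relative band weights per stage — NREM (0.60, 0.15, 0.10, 0.10, 0.05)
across delta…gamma at 120 µV RMS, REM (0.10, 0.60, 0.10, 0.10, 0.10) at
60 µV, wake (0.20, 0.25, 0.15, 0.20, 0.20) at 60 µV — with a lognormal
per-epoch amplitude jitter (σ = 0.15) so amplitudes are not degenerate.
Epochs are crossfaded over 0.125 s.  Motion is a 1 G gravity baseline plus
0.02 G sensor noise; active-wake epochs receive one 1.5–3.5 s burst of
0.3 G (kept under half the epoch so the median stays on baseline), quiet
wake at most one sub-0.5-s burst, REM occasional 0.05 G twitches.
Clipping is injected as rail-pinned runs of 0.5–2.5 s at an expected 2% of
samples, with the exact mask returned as ground truth.

What the generator does *not* emulate: 1/f background spectra, spindles
and other transient events, stage-transition dynamics beyond first order,
EMG contamination, inter-animal variability, or drifting electrode
quality.  Because the stage signatures are well separated by construction,
the benchmark's near-perfect cross-validated accuracy demonstrates that
the feature/classifier chain is implemented correctly and is learnable at
the stated scale — not that real recordings would score at that level.

## Problem sizes and determinism

The default benchmark is one 21-h recording (9,450 epochs, ≈9.7 M
samples); the test suite additionally uses minutes-long recordings and
200-seed Monte-Carlo ensembles for spectral-match properties.  Every
random draw flows from an explicit seed through `numpy`'s `SeedSequence`
spawning, so all generator outputs, repairs, and trained models are
bit-reproducible; derived seeds stay below 2³¹.
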