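# Methods

## Problem and pipeline

`pedalbci` detects the intention to start a self-initiated pedaling
movement from multichannel EEG. The physiological signal is
event-related desynchronization/synchronization (ERD/ERS): the power of
the sensorimotor mu (8–12 Hz) and beta (13–30 Hz) rhythms drops starting
about 2 s before movement onset and rebounds about 2 s after it. Because
the spatial location and frequency band of this modulation differ
strongly across individuals, the pipeline does not fix one model: it
evaluates a grid of 8 electrode configurations × 5 feature-extraction
algorithms (× 2 window types × 2 analysis modes) and selects a
personalized combination per subject using a composite metric, the
weighted discriminator (WD).

The processing chain per session:

1. **Onset detection.** The two gyroscope-X traces of each leg (20 Hz)
   are averaged; the *real start* of a cycle is the first IMU sample at
   or after the cue where both rectified leg averages exceed a threshold
   (default 10 deg/s — the threshold exists in the protocol but has no
   published value). Cycles with onset < 3 s after the cue, or no
   crossing, are discarded and excluded everywhere downstream.
2. **Class windows.** Start class = [onset−2, onset+2) (4 s type) or
   [onset−2, onset) (2 s type); rest class = an equally long window
   ending 0.5 s before the start window.
3. **Epoching.** 1 s epochs stepped by 200 ms: 16 per 4 s window, 6 per
   2 s window. Intervals are half-open, epoch starts sit on the 2 ms
   sample grid, fractional boundaries round inward.
4. **Preprocessing (per epoch).** 50 Hz IIR notch → 4th-order
   Butterworth high-pass at 0.2 Hz → common average reference (CAR) over
   all 32 recorded channels. Both filters are applied forward–backward
   (zero phase) so no group delay shifts ERD timing; epochs are filtered
   independently, accepting edge transients.
5. **Channel selection.** One of eight sensorimotor configurations
   (motor, premotor, left/right, ± medial; 4–9 electrodes). Memberships
   live in an editable `montages.tsv`-style table; the defaults are in
   `pedalbci.montage`.
6. **Features.** Per electrode: A = mean PSD 18–28 Hz (1 value); B =
   Euclidean norm of the 0–50 Hz magnitude spectrum at 1 Hz resolution,
   51 bins (1 value); C = mean PSD of 1–4, 8–12, 13–28 Hz (3 values);
   D = mean PSD over a fitted per-electrode optimal frequency ± 1 Hz
   (1 value); E = sums of 1 Hz magnitude bins over 8–12, (12,24],
   (24,30] Hz (3 values).
7. **Classification.** RBF-kernel SVM on z-scored features (C = 1,
   γ = scikit-learn's `scale`; the protocol states neither). *Offline*:
   leave-one-trial-out over 16 trials; per test class window the epoch
   predictions are reduced by majority vote with ties → 0 (rest);
   TPR/FP-min/Acc are averaged over the folds. *Pseudo-online*: train on
   the first 10 trials, classify every 200 ms-stepped epoch of each test
   cycle in temporal order; a detection fires after 5 consecutive
   positive epochs, timestamped at the 5th epoch's end, and the
   consecutive counter resets after firing. A detection inside a start
   window is true (at most one credited per window), otherwise a false
   positive.
8. **Metrics.** TPR = true detections / true events; FP/min = false
   detections / rest time in minutes; Acc = true detections / total
   detections (0 when there are none — the ratio is otherwise 0/0);
   FPR = FP/min × duration of one false positive in minutes (the window
   length offline, 1 s = 5 × 200 ms pseudo-online);
   **WD = 0.4·TPR + 0.6·Acc − 1.0·FPR ∈ [−1, 1]**. Offline rest time is
   the summed duration of the test rest windows; pseudo-online rest time
   is the test stream duration minus the union of start windows.

## Model selection

Per subject: (1) keep the two algorithms with the highest WD averaged
over the eight configurations; (2) among their 16 cells preselect the
maximum WD and every cell within 0.01 of it; (3) pick the preselected
cell with the fewest electrodes, break ties by higher WD, then uniformly
at random (seeded generator, recorded in the audit trail). Comparisons
use unrounded WD. The uniform procedures average the per-algorithm
E.C.-averaged WD, or the chosen algorithm's per-configuration WD, across
subjects and take the argmax (ties → first column / lowest id).
Personalized and uniform models are compared by a two-sided Wilcoxon
signed-rank test on per-test-trial WD pairs (exact distribution for
n ≤ 25 retained pairs, normal approximation above; zero differences
dropped, identical samples give p = 1).

## Synthetic data generator

There is no public recording with this protocol, so the generator
produces sessions with the protocol's timing and the ERD/ERS statistics
the pipeline assumes. Per cycle: 10 s rest, cue, a volitional wait drawn
uniform [3, 4.5] s (the protocol only bounds it below at 3 s), pedaling
drawn uniform [4.5, 5.5] s. EEG (500 Hz, µV) per channel = 1/f Gaussian
background (2 µV RMS) + mu and beta sinusoids (6 and 4 µV) with random
phase and a slowly varying envelope (±20%, ~0.5 s timescale) + a common
50 Hz line component (1 µV). On a subject's affected channels, the
oscillator in the affected band has its envelope multiplied by
(1 − `erd_depth`) from 2 s before onset until 2 s after it, then by
(1 + `ers_gain`) for the following `ers_duration`. Placing the rebound
*after* the start window keeps the 4 s window a pure-ERD segment, which
matches the physiological timing of the beta rebound and is what makes
the window placement meaningful. IMU traces are Gaussian noise
(1 deg/s) at rest plus an antiphase 50 deg/s, 1 Hz oscillation on the
two legs while pedaling.

Cohorts cycle through five archetypes differing in site and band (left
motor/mu, right motor/beta, midline/mu, left central-parietal/mu, right
central-parietal/beta), so different electrode configurations are
optimal for different subjects; the central-parietal sources are only
covered by the medial configurations (E.C. 5/7), which is what makes a
single uniform configuration genuinely suboptimal for a heterogeneous
cohort. Default modulation for cohort subjects is `erd_depth` 0.7,
`ers_gain` 0.6 — deep but within the range reported for executed
movement; the single-subject default is 0.5. A fixed seed yields a
byte-identical session (one master seed spawns independent substreams
for timing, noise, rhythms and IMU).

What the generator does **not** emulate: volume conduction and channel
correlation, eye/muscle artifacts, slow cortical potentials
(Bereitschaftspotential), non-stationary baselines, or realistic ERD
spectra (the modulation is a single narrowband oscillator). Passing the
end-to-end tests therefore shows the pipeline recovers planted
band-power structure under 1/f noise and envelope variability — not that
it would reach the same numbers on real EEG.

## Numerical choices

* PSD estimator: raw periodogram of the 1 s epoch (boxcar window, native
  1 Hz resolution); algorithm D's 0.5 Hz grid comes from zero-padding to
  2 s. A pure tone therefore leaks into the two adjacent 0.5 Hz bins,
  which bounds D's frequency resolution at ± 0.5 Hz.
* Algorithm D normalization: the *class-mean* spectrum per channel is
  normalized to unit sum over 8–28 Hz (normalizing per-epoch spectra is
  the other reading of the procedure; class-mean is cheaper and
  equivalent in expectation for stationary epochs). Ties in the argmax
  resolve to the lowest grid frequency.
* Band edges are inclusive except where two of algorithm E's bands share
  an edge (12 and 24 Hz belong to the lower band).
* Notch quality factor defaults to 10: within a 1 s epoch a Q = 30 notch
  attenuates a 50 Hz tone by only ~17–20 dB because its ring-in
  transient spans the window; Q = 10 reaches ~27 dB and its 5 Hz
  bandwidth touches no feature band. The high-pass filtfilt padding is
  extended to the epoch length to keep the passband flat at the edges.
* The voting-queue counter resets after a detection fires (the
  alternative — requiring a 0 to re-arm — would make one sustained
  activation produce a single detection ever; resetting matches the
  1 s-per-false-positive accounting of the FPR).
* Offline WD is computed from fold-averaged TPR/FP-min/Acc, matching how
  the reference tables relate to their starred WD entries.
* Table comparisons round half away from zero at 2 decimals.

## Problem sizes used by the test suite

The high-SNR recovery check runs the full protocol (16 trials × 5
cycles) for 5 seeds. The personalization-benefit experiment runs 10
cohorts of 5 subjects with a 16 × 2-cycle protocol — the full 8 × 5 grid
(40 trained models) per subject, 30 paired per-trial WD values per
cohort — a size chosen so the whole experiment stays desk-scale while
keeping 6 test trials per subject; with 2 cycles per trial the per-trial
WD is noisier than at the full 5, making the significance requirement
harder, not easier.

## Known limitations

* Figure-level electrode memberships of the eight configurations are
  approximations consistent with the published selection outcomes; users
  with the true layouts can override them via a montage table.
* SVM hyperparameters are fixed, not tuned per subject; the selection
  procedure personalizes only the algorithm and configuration.
* Algorithm D's normalized class-difference criterion can lock onto an
  *unmodulated* spectral peak when a spectrum holds exactly two narrow
  peaks of comparable normalized weight (the normalized difference is
  zero-sum over the band). On synthetic beta-band subjects this makes D
  underperform — which the personalized selection routes around, but it
  is a genuine sensitivity of the method.
* True real-time operation (drivers, latency) is out of scope;
  pseudo-online processing is strictly causal but runs on recorded data.
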