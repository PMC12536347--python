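# Methods

This note documents the models, numerical choices and limitations behind
`cogload`, in the order the pipeline runs.

## Synthetic sessions and the latent load state

The generator exists so that every downstream stage — synchronisation,
filtering, windowing, the feature bank, label construction and the two
cross-validation regimes — can be exercised and calibrated without recorded
data. A session is an ordered list of task blocks `(activity, duration,
latent_load)` with `latent_load ∈ [0, 1]`. The default protocol mirrors a
typical mixed session: eyes-closed baselines (1 min) bracketing relaxation
(10 min, load 0), a game (6 min, 0.1), a load task (8 min, 1.0), reading
(10 min, 0.75) and summarising (8 min, 0.9) — ≈44 min, of which 42 windows
carry a classifiable activity.

A single `effect_size` parameter scales how strongly the latent load `l`
shifts physiology (all slopes per unit `effect_size × l`):

| signal | baseline | load response | rationale |
|---|---|---|---|
| heart rate | 65 bpm | +15 bpm | sympathetic activation |
| inter-beat jitter SD | 45 ms | −15 ms (floor 5 ms) | vagal withdrawal lowers HRV |
| EEG β (all), θ (prefrontal) amplitude | 8 / 10 µV | ×(1 + 0.6·e·l) | workload raises frontal θ and β power |
| SCR rate | 1 /min | +4 /min | arousal raises SCR frequency |
| skin temperature | 33 °C | −0.4 °C | peripheral vasoconstriction |

With `effect_size = 0` every modality is statistically independent of the
load, which is the basis of the permutation-null calibration below.

Mechanics: EEG band components are unit-variance FIR-bandpass-filtered white
noise per canonical band, scaled by per-band amplitudes, so expected band
power is proportional to the squared amplitude without modelling neural
dynamics; a 50 Hz sinusoid with seeded random phase (5 µV) is added to the
EEG only — the other rates cannot carry it. PPG is a train of Gaussian
systolic pulses (σ = 60 ms) whose beat times integrate the instantaneous
rate with Gaussian inter-beat jitter; planted beat times are returned as
ground truth. EDA is a flat tonic level plus bi-exponential SCRs (τ_rise = 1 s,
τ_decay = 4 s, 0.3 µS) at Poisson event times; generated sessions carry no
session-long tonic drift, because task blocks keep a fixed order and any
monotone drift — once z-scored per participant — becomes a clean time ramp
that lets elapsed time impersonate the load signal (the EDA synthesiser
still exposes a drift-slope parameter for planted-truth recovery tests).
Questionnaire responses are `round(1 + 4·l + N(0, σ))` clipped to 1..5 with
σ = 0.5 by default — ordinal rounding is the simplest model consistent with
a 5-point scale. Both devices record one 3 s shake burst at the true session
start; the burst is band-limited to 2–8 Hz (a hand shake's natural band) so
the 50 Hz gyroscope and 32 Hz accelerometer sample the same waveform. The
wristband clocks are then offset by 2.5 s to emulate unsynchronised devices.
A single master seed spawns per-modality child streams, so output is
reproducible and modalities stay independent.

What the generator does **not** emulate: EEG microstates and artifacts, PPG
waveform morphology beyond a peaked pulse, motion artifacts, clock drift,
circadian structure, or any realistic coupling between questionnaire
response style and physiology. Passing tests therefore demonstrate that the
pipeline recovers structure it was told to plant and stays at chance when
none exists — not that real recordings would classify at any particular
accuracy.

## Synchronisation

Both motion channels are reduced to motion-energy envelopes (rectified,
0.25 s odd-length moving average, resampled to a common 32 Hz grid using
each device's claimed timestamps) and cross-correlated within ±30 s. The
offset is the lag of the normalised correlation peak, refined by fitting a
parabola through the three samples around it. A peak correlation below 0.5
raises an error rather than guessing. On the generator's planted 2.5 s
offset the estimate is accurate to ~1–3 ms, well inside the 1/32 s grid.

## Filtering and windowing

A zero-phase second-order IIR notch (50 Hz, Q = 30, applied forward-backward)
removes line interference on channels with rates above 100 Hz; lower-rate
channels pass through untouched by contract. No other artifact rejection is
performed. Windows are non-overlapping 60 s slices cut inside each protocol
block; trailing remainders are dropped and windows never straddle blocks, so
each window carries exactly one questionnaire response. Window coverage is
checked with half-sample tolerance per channel so that sub-sample sync
residuals do not silently drop a block's first window.

## Feature bank

**Band power** is the single-segment rectangular-window periodogram of the
mean-removed series, summed over the frequency bins strictly inside the band
and multiplied by the bin width. On a 60 s window the bin width is 1/60 Hz;
a sinusoid of amplitude A at an in-band frequency contributes ≈ A²/2 and
white noise contributes power proportional to band width. The DC bin is
always excluded.

**Indices** live in a registry keyed by name. The cited literature knows
several variants; the shipped, pinned defaults are EI = β/(α+θ) and
BB = θ/α on the all-channel mean projection, CLI = prefrontal θ / temporal
α, and asymmetry = ln(α_right) − ln(α_left) per region (AF8 vs AF7, TP10 vs
TP9) with ASA their mean. Zero denominator powers yield NaN markers; the
window is kept and the value treated as missing downstream.

**Wavelet statistics** use PyWavelets' multilevel DWT at level 8; the nine
retained arrays are cA8 and cD8…cD1. STD uses the population convention;
skewness and kurtosis are the standardised 3rd/4th central moments (kurtosis
not excess-adjusted) and are defined as 0 for a constant array;
RelativeWaveletEnergy is an array's squared norm over the nine arrays'
summed squared norms; ZeroCrossing counts strict sign changes (exact zeros
never count). The five source signals are the four notch-filtered channels
plus their mean — 5 × 2 wavelets × 9 arrays × 8 statistics = 720 names, and
with the 10 regional band powers and 6 indices the EEG bank is 736.

**Beat detection** band-passes the PPG at 0.5–8 Hz (zero-phase Butterworth)
and keeps local maxima above 0.5 × the rolling 75th-percentile amplitude
(10 s neighbourhood) with a 330 ms refractory period; NN intervals outside
273–2000 ms are discarded. **HRV**: SDNN uses the sample (n−1) convention;
LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) are Welch band powers of the NN
series cubically interpolated at 4 Hz. On a 60 s window the LF lower edge is
marginal (< 2 LF cycles); the value is still computed, flagged
`short_window`, and fewer than 30 intervals mark the spectral fields missing
entirely.

**EDA decomposition**: the tonic level is a rolling 10th-percentile baseline
(20 s neighbourhood) smoothed by a zero-phase 0.05 Hz low-pass; the phasic
series is the residual, so tonic + phasic reconstructs the input exactly. A
plain linear low-pass was rejected because SCR pulses are unipolar: their DC
content leaks into the tonic estimate (~0.12 µS RMSE against a planted ramp,
vs ~0.01 µS for the robust baseline). SCR peaks are local maxima ≥ 0.01 µS
separated by ≥ 1 s.

Features that cannot be computed (flat PPG, too-short EDA) are NaN markers,
never silent zeros; imputation happens later inside the training fold.

## Labels, feature sets, selection

The 5-class problem uses the workload response verbatim; 3-class merges
{1,2} and {4,5} around the neutral 3; the binary problem keeps only the
poles and excludes response-3 windows, since "low vs high" names no place
for the midpoint. Stress responses are carried but not used as targets.

The reduced sets are pinned manifests: Both-Modalities (12 wavelet + 8
wristband features), headband-only (12 wavelet + 5 band powers + EI,
prefrontal asymmetry, CLI), wristband-only (all 18). The twelve wavelet
members are, per channel, the haar cD1 Kurtosis, cD7 MEAN and cD8
ZeroCrossing — the coefficient/statistic families that carry load
information most stably — and the manifest (version 1.0) is the single
source of truth, exportable as JSON. Data-driven top-k selection ranks by
mean absolute Spearman correlation with ties broken lexicographically. In
the generalised evaluation it runs fold-internally (`select_top_k`),
recomputing correlations on each fold's training participants only;
selecting on the whole table first remains possible (pass the pre-selected
set) but overfits, which is why it is not the default path.

## Cross-validated evaluation

Feature columns are z-scored per participant up front (constant columns
become 0), matching a per-participant normalisation design; min-max scaling
and median imputation are fitted on training rows only within each fold,
with test values clipped to [0, 1], so no fold statistics leak. The
generalised regime holds out each participant once; the personalised regime
runs stratified 5-fold CV inside each participant (falling back to
leave-one-window-out when k equals the window count, skipping participants
whose class support cannot stratify). Folds whose training set misses a
class are scored anyway — with a majority-vote fallback when only one class
remains — and flagged `degenerate`.

Weighted F1 is implemented from the confusion matrix (classes taken from the
truths; undefined per-class F1 counts as 0) and cross-checked in the tests
against an independent implementation. The best configuration per family is
the one with the highest mean weighted F1; ties break towards the smaller
summed hyperparameter magnitude, then lexicographically. The KNN grid
samples `leaf_size` at {1, 10, 20, 30, 40, 50} by default because leaf size
changes lookup speed, never predictions; the full 1..50 range is a flag
away. Invalid logistic solver/penalty pairs are pruned. All stochastic
components (MLP initialisation, fold shuffling, permutation nulls) take
explicit seeds.

## Calibration and problem sizes

The acceptance script and the heaviest tests run a 10-participant synthetic
population (one ≈44 min session each, ~42 usable windows per participant) —
the same population shape the analysis targets — with logistic regression on
the Both-Modalities set. Three properties are checked end to end: with
`effect_size = 0` the binary LOO-CV mean weighted F1 falls inside the 95%
band of a 50-permutation label-shuffle null; with `effect_size = 2` it
reaches ≥ 0.80 (in practice it saturates at 1.0 — the planted effects are
individually strong); and the score is non-decreasing across effect sizes
{0, 0.5, 1, 2}.

## Limitations

Real-data scores cannot be checked without actual recordings; the
`validate-real-data` entry point will run the identical evaluation on a
dataset in the supported layout, but nothing in the test surface depends
on it. The generator's separability is tunable, not
realistic: synthetic F1 values say nothing about achievable real-data F1.
Clock drift (non-constant offset), streaming ingestion and artifact
rejection beyond the notch are out of scope.
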