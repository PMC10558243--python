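# Methods

`engdecode` decodes the state of the lower urinary tract — empty bladder
(*baseline*), filled bladder (*full*), and urine leakage (*micturition*) —
from multi-channel electroneurogram (ENG) recordings of the pudendal nerve,
as acquired with a transversal intrafascicular multichannel electrode (TIME)
whose 32 active sites (AS) each yield one signal channel. This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Synthetic session generator

No public recordings exist for this preparation, so the package ships a
generator whose sessions exercise every pipeline stage.

**Spiking model.** Each functional channel carries a homogeneous Poisson
process with an absolute refractory dead time of 4 ms (the same refractory
used by the spike-detection QC). Inter-spike intervals are drawn as
`refractory + Exp(rate')` with `rate' = rate / (1 − rate·refractory)`, so the
configured `rate` is the *achieved* mean firing rate: expected event counts
equal `rate × duration` for any admissible rate (`rate < 1/refractory`).
With `refractory = 0` the process is exactly Poisson, which is what the
count-recovery tests assert.

**State dependence.** The published work does not quantify how pudendal
afferent rates change across bladder states, only that the states are
discriminable; the per-state rates and amplitudes are therefore free
generator parameters, chosen once as defaults: 5 / 40 / 80 Hz per channel and
30 / 35 / 40 µV spike peaks for baseline / full / micturition, over 4 µV RMS
broadband noise and a 1 µV 50 Hz line component. These place single-window
SNR in a regime where the three classes are clearly separable by a trained
model but raw amplitudes overlap — "easy" in the sense of the recovery tests,
not trivial. Both knobs (rate and amplitude) scale separability, so tests can
construct chance-level, hard and easy datasets. An optional per-state noise
level (`state_noise_sd`) lets tests build classes that differ in variance
only; dead channels always use the state-independent noise level.

**Waveform.** Spikes are rendered as a biphasic difference-of-Gaussians,
~1 ms wide, a broad low positive lobe followed by a narrow dominant trough,
with lobe areas cancelling so the template has no net low-frequency content;
~87% of its energy lies in the 1–6 kHz analysis band and survives the
band-pass. Events whose waveform crosses the end of a segment are truncated
at the boundary, not dropped (the truncation count is logged).

**Sessions.** Three equal-duration segments in protocol order baseline → full
→ micturition (60 s each by default) at 24 414 Hz; 5 of 32 channels default
to "dead" (the implanted arrays showed 4–7 nonfunctioning sites), carrying
noise but no spikes — they stay in the analysis deliberately, as in the
original worst-case design. Optional physiological traces at 1526 Hz contain
a monotone 0→150 ml volume ramp during filling and a pressure trace peaking
at micturition. All randomness derives from one `SeedSequence`, so a config
is bit-reproducible.

What the generator does **not** emulate: non-stationary noise, movement and
stimulation artifacts, electrode drift, correlated multi-unit activity,
overlapping spike waveforms across fibres, or any real urodynamics. Passing
the recovery tests therefore shows the pipeline is correct and leak-free on
data satisfying its assumptions — it does not predict in-vivo accuracy.

## Preprocessing

Channels are filtered independently with a Butterworth band-pass, cutoffs
1–6 kHz, order 4. "Order" is the prototype low-pass order handed to the
design routine (`scipy.signal.butter`, SOS form); the realised band-pass has
8 poles. This convention is recorded in `FilterSpec.order_convention` because
the alternative reading (4 poles total) exists; the contract tests pin the
realised magnitude response, not the pole count. The filter is applied
forward–backward (zero phase) so window boundaries and labels never shift;
a causal single-pass variant is available behind `zero_phase=False` for
streaming parity. After filtering, signals are undersampled by plain
decimation (factor 2). No separate anti-alias filter is needed: the band-pass
upper edge (6 kHz) sits below the post-decimation Nyquist (6103.5 Hz), and an
acceptance test asserts that ≤ 1% of post-chain spectral energy lies above
6 kHz.

Spike detection is quality control, not a feature source. The threshold is
`k × MAD/0.6745` (k = 4.5, negative polarity by default — extracellular
somatic spikes are trough-dominant); supra-threshold local extrema are
accepted greedily in time order with a 4 ms refractory (earlier event wins).
The threshold rule is this package's choice; only the refractory period is
inherited from the source protocol.

## Framing and features

Each class interval is split **on the raw timeline** into a training part and
a chronologically later test part (test fraction 0.1, the 1:10 ratio), before
any windowing — this ordering is what guarantees train/test disjointness at
the sample level, because overlapping windows can otherwise straddle the
boundary. Training signal is cut into 0.55 s windows with 0.11 s (20%)
overlap; test signal into 0.55 s windows without overlap. Window counts
follow `floor((L − w)/(w − o)) + 1`; the trailing remainder is discarded.

Nine features per window per channel: MEAN, VAR (population variance), SKEW
and KUR (third and fourth standardised moments, KUR excess), MAV (mean
absolute value), WL (waveform length Σ|Δx|), MAX, AMP (peak-to-peak) and POW
(mean squared sample). Naming notes: MAV is read as mean absolute value (the
standard myoelectric feature; MAX already covers the maximum), AMP as
peak-to-peak, and WL ("wavelength" in some figure captions) as waveform
length — the classic EMG definitions behind those abbreviations. Population
(biased) moments keep the features consistent with the standardisation step;
POW is a per-sample mean so it is window-length invariant. Windows with
numerically zero variance (dead or saturated channels) get SKEW = KUR = 0
instead of NaN; the degeneracy guard is relative (`var ≤ 1e-18 × mean(x²)`).

Per-channel blocks are concatenated channel-major (ch00_MEAN … ch31_POW, 288
columns at 32 channels). Standardisation removes the per-column training
mean and divides by the training sd floored at 1e-12; applying it to a table
not tagged as training data, or re-fitting a fitted scaler, raises a contract
error. Row shuffling is a seeded permutation that keeps labels and window
provenance aligned.

## Classification and evaluation

Four families with fixed grids: RF (trees {50,100,200,300} × depth
{5,10,20,30}, `max_features="sqrt"`), SVM (kernel {sigmoid, rbf},
regularisation {1e-3, 1e-2, 1e-1, 1} used directly as sklearn's `C`; note C
is an *inverse* penalty strength, recorded in the grid metadata), k-NN
(k ∈ {3,5,7,9,11}, Euclidean distance on standardised features) and MLP
(five four-layer layouts from 128–512 units, adam, learning rate 1e-3,
max 200 epochs, early stopping with patience 20 on an internal validation
split — the full training protocol is not specified by the source, so these
are this package's choices).

**Nested cross-validation.** Outer folds (10 by default) are contiguous
temporal blocks, stratified per class: each class's time-ordered windows are
cut into 10 contiguous blocks and fold k holds out block k of every class.
Temporal rather than random folds respect the serial correlation of
overlapping windows and match the inner scheme, which slides a contiguous
validation block along the time dimension of the outer-training rows
(3 inner folds by default; the inner fold count is a free parameter). For
each grid point the mean inner BA is computed; the best grid point is refit
on the whole outer-training set and scored once on the held-out block.
Standardisation and shuffling happen **inside** each fold, fitted on that
fold's training rows only; an audit hook exposes the fitted scaler so tests
can verify this. All model and shuffle seeds derive from one master seed.
When a table was built with training overlap, windows adjacent to a fold
boundary can share up to 20% of their samples with the neighbouring fold;
the held-out *session* test split never shares any.

**Balanced accuracy.** BA = (Recall_B + Recall_F + Recall_M)/3, with recall
= TP/(TP+FN) per class. The division by the number of classes keeps
BA ∈ [0, 1] and matches every reported percentage; a confusion-matrix row
with no true instances is an error naming the class. Confusion matrices are
3×3 integer arrays, rows = true class, columns = predicted, in the fixed
order (baseline, full, micturition).

**Importance.** For RF, per-column Gini importance (mean decrease in
impurity, normalised to sum 1, averaged over outer folds) is aggregated two
ways: channel-averaged per-feature scores (mean over channels of that
feature's columns) and per-AS weights (sum of a channel's nine columns).
Under a variance-only class separation, VAR and POW carry the most efficient
signal and rank at the top together with MAV/WL (all four are monotone in
the noise scale; VAR and POW have the largest discriminability per window),
while dead channels receive near-zero weight.

## Window-length sweep

Twenty lengths, linearly spaced 0.05–1.0 s inclusive (step 0.05 — the count
and range are given, the spacing is this package's choice), training overlap
always 20% of the length, test windows non-overlapping. Each length is scored
by cross-validated RF with one fixed configuration (100 trees, depth 20 by
default): folds are contiguous spans of the raw timeline cut per class
interval and the signal is re-windowed inside each fold, so no samples are
shared between fold train and test at any length. A grid search per length is
deliberately not run. Lengths at which some fold cannot produce one window
per class are flagged unusable, not fatal. The trade-off rule returns the
smallest usable length whose cross-session mean BA is within 2 percentage
points (configurable) of the best — a formalisation of "highest BA at the
smallest window" motivated by decision latency in eventual real-time use.

## Problem sizes and determinism

The default synthetic session (32 channels × 3 × 60 s at 24 414 Hz) yields
366 training and 30 test windows at the 0.55 s framing; the acceptance
checks run the full four-family nested CV at this scale, and the sweep and
importance checks at reduced channel counts / segment durations (6–32
channels, 12–21 s per state), sizes chosen to keep the whole suite
comfortably runnable on a laptop-class single core. The chance-level
(label-permuted) run uses 2 inner folds, since hyperparameter selection is
irrelevant under permuted labels. Every reported number is reproducible from
a config and a seed; reports contain no timestamps.

## Known limitations

- Single-session analysis: no cross-animal or cross-session transfer, no
  session concatenation.
- The synthetic benchmark bounds correctness, not in-vivo performance (see
  generator caveats above).
- MLP early stopping scores its internal validation split with plain
  accuracy (sklearn behaviour), not BA; folds here are class-balanced, so
  the two nearly coincide.
- Frequency-domain features, artifact rejection, spike sorting and
  probability calibration are out of scope.
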