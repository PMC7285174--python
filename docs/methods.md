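# Methods

## Problem and model

An AED shock-advisory system must decide from a short single-lead ECG strip
whether the rhythm is shockable (coarse ventricular fibrillation, rapid
ventricular tachycardia) or nonshockable (normal sinus rhythm, other
organised rhythms, asystole). `shocknet` implements this decision as an
end-to-end fully-convolutional 1D network over the raw ECG window — no
filtering, feature extraction or normalization precedes the network, and the
native amplitude resolution of 2.5 µV/LSB is preserved because absolute
amplitude is itself diagnostic (asystole is *defined* by peak-to-peak
< 100 µV).

The network is a stack of N convolutional blocks (Conv1D with valid padding
→ ReLU → max-pool of size MP = 2 → dropout α = 0.3 during training),
followed by global max pooling and a single sigmoid unit emitting
p ∈ [0: shockable, 1: nonshockable]. Valid padding shrinks the time axis:
conv_len = L − K + 1, pooled_len = ⌈conv_len / MP⌉. Global max pooling makes
the trainable-parameter count independent of the window length:

    params = Σᵢ Fᵢ (Kᵢ F_{i−1} + 1) + (F_N + 1),   F₀ = 1,

generalised for comparative architectures with dense hidden layers (a layer
of width h after width u adds h(u+1)).

### Pooling convention

Max pooling uses *ceil* semantics: a trailing window shorter than MP is
pooled over its own elements (the same-padding pooling convention of the
major deep-learning frameworks). This is a load-bearing choice: the deepest
reference architectures (six and seven blocks at a 625-sample input) end in
a length-1 feature map in their final block, which only exists if short
remainder windows are kept. Under floor semantics those architectures would
be infeasible. A kernel exactly spanning its input (conv length 1) is
therefore feasible; an input shorter than the kernel is not.

### Decision threshold

The sigmoid output is *not* thresholded at 0.5 for reporting. The operating
point is the ROC point maximizing Se + Sp (equivalently balanced accuracy
BAC = (Se + Sp)/2), with Se measured on shockable cases (classified
shockable when p < t) and Sp on nonshockable cases. Ties are broken toward
higher Se. The sweep covers every distinct score plus ±∞ sentinels, so the
selected BAC is never below the 0.5-threshold BAC.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), binary cross-entropy, batch size 256, up to 400
epochs with early stopping after 150 epochs without improvement, kernel
initialization uniform in ±0.05, biases zero. The learning rate decays per
epoch as LR_t = LR/(1 + DR·t) with DR = LR/epochs (the reciprocal "decay"
convention of classic Keras Adam; the protocol names only the framework
default, so the convention is fixed here and documented). The monitored
metric is plain accuracy at threshold 0.5, computed after each epoch on the
training set — which is class-balanced by replicating every shockable strip
four times, so accuracy tracks balanced accuracy closely. Whether the
original protocol monitored training data or an internal split is not
stated; training-set monitoring is the default and a `monitor="validation"`
switch accepts an explicit monitored split. The checkpoint is the epoch with
maximal monitored accuracy (earliest epoch on ties).

Training arithmetic runs in float32 (the customary network precision;
single-threaded runs are bit-reproducible given the seed), while the public
single-operation entry points (`conv1d_block`, `maxpool`, `forward`) follow
their input dtype and default to float64 so they can be validated against
high-precision brute-force oracles. The convolution is implemented as one
GEMM over a tap-major patch tensor assembled from contiguous slice copies,
with a per-run workspace that reuses the large scratch buffers across
batches; gradients for max-pool and global-max-pool route to argmax
positions, and dropout is the inverted convention (identity at inference).

## Hyperparameter search

Configurations are drawn from the fixed grid
F ∈ {5, 10, 15, 20, 25, 30, 40, 50}, K ∈ {5, 10, 15, 20, 25, 30, 40, 50,
60, 70, 85, 100}, with extra-large options F₁ ∈ {75, 100, 125, 150, 200},
K₁ ∈ {125, 150, 200} at depth 1 only (so shallow models reach comparable
parameter counts). Both the {Fᵢ} and {Kᵢ} vectors must be non-strictly
monotone from first to last block — non-strict because the reference optima
themselves contain repeats (e.g. F = {15, 15, 15, 10}).

Monotone vectors are sampled *uniformly over all monotone vectors* via
multiset unranking (stars-and-bars bijection, choosing the direction with
probability proportional to the number of vectors in each direction,
counting constants once). This is distribution-identical to iid grid draws
rejected until monotone — every monotone vector has the same iid probability
— but has no failure mode; naive joint rejection would need ~10⁵ draws per
accepted vector at depth 7. Shape feasibility at the chosen input length is
then handled by rejection with a 50,000-draw budget: at depth 7 and a
625-sample input only ~0.2 % of monotone kernel vectors survive the
valid-padding shrink, and re-drawing is cheap because rejected candidates
are never trained. Duplicate configurations across a session are allowed
(the record store keeps every trained model).

## Statistical optimization (median of the top-ranked models)

Rather than promoting the single best random-search model:

1. **Top-rank selection.** Per depth, keep records with validation BAC at or
   above a cutoff. The reference cutoffs (96.5 % at N = 1, 98.9 % at N = 2,
   99.1 % at N = 3, 99.3 % at N ≥ 4) were chosen by inspecting BAC
   histograms, which cannot be automated faithfully; they are configuration
   values with those defaults, and scaled-down runs may instead derive
   per-depth cutoffs from a BAC quantile (`quantile_cutoffs`, default top
   20 %). Records exactly at the cutoff are included.
2. **Median-HP prediction.** The per-position median of the selected
   records' Fᵢ and Kᵢ (linear interpolation between order statistics,
   rounded half-up to an integer) predicts one configuration per depth. The
   median is deliberately *not* snapped back to the search grid — an
   off-grid prediction such as F₁ = 113 from six top models is legitimate.
   The exact interpolation used by the original statistics tool is unknown;
   this convention is documented, not claimed identical. Feasibility of the
   predicted configuration is verified, naming the violating block if not.
3. **Learning-rate sweep.** Each predicted configuration retrains at
   LR ∈ {0.01, 0.005, 0.001, 0.0005, 0.0001, 0.00005, 0.00001}, ten
   independent runs each; the run with maximal validation BAC is the best
   model, and per-LR min/quartile/max summaries describe the run-to-run
   variance.

Supporting analyses: per-HP median/quartile distributions within BAC bins
(0.25-point bins by default; quartiles suppressed in bins with fewer than 4
records), and predictor importance from a regression tree of BAC on
{Fᵢ, Kᵢ, Params} per depth. The tree is CART with squared-error impurity
(max depth 5, minimum leaf 5 — common CART controls, exposed as arguments),
and importance accumulates each node's impurity improvement for the primary
splitter *plus* a surrogate share λ·gain for every other predictor, with
λ = (agreement − majority)/(1 − majority) counted when positive. Surrogate
credit is what lets collinear predictors — notably the parameter count,
which is a deterministic function of the Fᵢ and Kᵢ — register importance
despite never splitting. Scores are normalized so the per-depth maximum
is 1; a constant response yields an all-zero row with a warning.

## Synthetic rhythm simulator

The generator emulates the *statistical structure* of an annotated
cardiac-arrest corpus, not ECG physiology. Classes are defined exactly by
the annotation scheme's measurable criteria, and the waveform models are the
simplest ones meeting them:

| class | model | defining criterion |
|---|---|---|
| VF | 3–5 drifting 3–8 Hz sinusoids, random phase walk | p-p > 200 µV |
| fine VF | same | p-p ∈ [100, 200] µV (excluded) |
| VT | regular wide biphasic complexes | rate > 150 bpm |
| slow VT | same | rate < 150 bpm (excluded) |
| NSR | Gaussian-bump P-QRS-T, 3 % RR jitter | 50–100 bpm |
| ONR | uniform mix of AF-like / bradycardia / PVC variants | — |
| ASYS | 4 Hz-lowpass colored noise | p-p < 100 µV, > 4 s |
| artifact | baseline wander + EMG noise (excluded; never trains) | — |

Strips are 10 s at 250 Hz. The composite signal (waveform + 30 Hz-lowpass
Gaussian noise, 10 µV rms by default) is rescaled so its pre-quantization
peak-to-peak amplitude equals the requested value exactly, then quantized to
the 2.5 µV lattice (perturbing p-p by at most one LSB, absorbed by the class
margins). The 3–8 Hz band for "coarse" VF is a package choice — the
annotation scheme constrains only amplitude. Each strip is fully determined
by an integer seed; dataset generation derives per-strip seeds from the
master seed and strip index, draws per-strip amplitudes/rates inside the
class-validity margins, tags ~30 % of strips as defibrillator-acquired
(band-limited to 1–30 Hz by a zero-phase 4th-order Butterworth band-pass,
> 20 dB out-of-band attenuation), and assigns every strip a unique patient
id so train/validation leakage is assertable.

What passing tests on this simulator do **not** show: robustness to real
OHCA artifact (chest compressions, pad motion), to pacemaker spikes, to
genuine morphological variety within classes, or the headline accuracies of
the original study — those require the proprietary defibrillator corpora
and the public Holter sets. The simulator makes the two classes honestly
separable by the same amplitude/rate cues a trained network should find, so
it exercises the machinery (shapes, training, ranking, median prediction)
end to end.

Downsampling 250 → 125 Hz is plain decimation (every second sample) with no
anti-alias filter: both acquisition paths are band-limited well below the
62.5 Hz post-decimation Nyquist by construction. Analysis windows are the
*initial* L₁ seconds of each strip (no shift), emulating an analysis started
immediately.

## Problem sizes used by the bundled test/acceptance runs

The scaled-down study conditions are the package's own: a 600-strip training
corpus and 300-strip validation corpus (class proportions scaled from the
emulated corpus composition, ~30 % defibrillator-like) for end-to-end
training of the best 5-block configuration at 5 s windows; and 240-strip
corpora at 2 s windows for the 30-model random search at depths {2, 3} with
20-epoch training budgets, whose median-HP prediction is compared against
the top quartile of the search records. Seeds are fixed; the sweep and
search layers derive per-model seeds from a master seed via
`numpy.random.SeedSequence`.

## Known limitations

- The numpy implementation is single-core and tuned for small networks
  (≤ ~20 k parameters); it is a reference implementation, not a production
  training stack.
- The simulator's ONR variants cover three archetypes with uniform weights
  (the annotation scheme lists variants without frequencies); real "other
  nonshockable" rhythms are far more diverse.
- Reported percentages follow the 0.1-point table resolution of the domain's
  reporting convention; internal computations are full precision.
- The WFDB/PhysioNet reader is not included; the strip archive (CSV header +
  integer-count sample matrix, bit-exact round trip) is the single ingestion
  format.
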