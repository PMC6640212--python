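# Methods

## Model

The simulator implements feed-forward convolutional spiking networks with
non-leaky integrate-and-fire neurons that emit at most one spike per
stimulus. Time is discretized into `T_max` bins; a stimulus is a 4-D binary
spike-wave tensor `(T_max, F, H, W)` in accumulative format (an entry is 1
from the neuron's first spike bin onward). The accumulative redundancy
allows every time-step to be processed by a single tensor operation, and
the convolution of an accumulative wave directly yields accumulated
membrane potentials per step. The non-redundant dual — one first-spike time
per neuron, with a sentinel for "never spikes" — is used wherever spike
times are compared (pooling commutation, plasticity, winner selection).

Assumptions baked into the model:

- no leak, no refractoriness beyond the single-spike limit, no delays;
- convolution is valid-mode, stride 1, cross-correlation (no kernel flip),
  with padding provided as an explicit separate operator;
- firing is strict (`potential > threshold`), and the separate
  "thresholded potentials" operator zeroes entries strictly below the
  threshold;
- the decision layer uses an infinite threshold: spikes exist only at the
  final step for neurons with nonzero accumulated potential, and the
  decision is the class of the feature holding the global maximum
  potential.

With non-negative synaptic weights the accumulative potentials are
monotone in time and every firing operator provably returns a valid
accumulative wave; with signed weights (possible for user-supplied
kernels) monotonicity of potentials — and hence the single-spike reading
of `fire` — is not guaranteed. The shipped presets use non-negative
weight ranges throughout.

## Pooling size rule

The pooling output size is `floor((H + 2 D_h) / R_h)` per axis — the
window extent is deliberately absent from the numerator, and windows that
would run past the padded border are truncated. A conventional formula
would subtract the window size before dividing; the truncation rule is
what makes the printed size always realizable when the stride does not
divide the input. With the default stride = window and divisible sizes the
two conventions coincide (all preset geometries are in this regime).

## Competition

Winners are selected iteratively: earliest first-spike step, ties broken
by the largest final potential, remaining ties by lowest
`(feature, row, col)` — the last rung exists purely for determinism.
After each pick, the winner's whole feature map is suppressed (so
successive winners learn distinct features) together with the Chebyshev
neighbourhood of radius `r` across all feature maps. The feature-map
suppression is stronger than the radius rule alone and is isolated behind
a switch (`suppress_feature_map`). A radius of zero is read as an empty
spatial neighbourhood: nothing but the winner itself leaves the candidate
pool, and the corresponding lateral-inhibition mask is all ones.

## Plasticity

STDP updates only the winners' receptive fields, mapped by
valid-convolution geometry: a winner at `(f, r, c)` owns kernel slice `f`
and reads input rows `[r, r + K_h)` x cols `[c, c + K_w)` of the layer's
actual (padded) input. Simultaneous pre/post spikes potentiate
(`T_j <= T_i`); a silent pre-synapse counts as `T_j = infinity` and is
depressed. `T_i` is the winner's first step with nonzero thresholded
potential; under the infinite threshold it is `T_max - 1`. One plasticity
invocation is applied per stimulus (no accumulation across stimuli).
Learning rates are plain scalars; no adaptive schedules are implemented.
Reward-modulated STDP is realized as a pair of rules with opposite-sign
learning rates applied under correct/wrong decisions; silent stimuli
trigger no plasticity.

## Encoding front-end

Difference-of-Gaussians kernels are differences of two unit-mass isotropic
Gaussians; Gabor kernels are even-symmetric (cosine-phase). Both are
mean-subtracted so uniform regions give zero response, which is what makes
the filter clip threshold meaningful. Local normalization divides each
value by its square-neighbourhood mean (edge-replicated at borders, with a
floor of `1e-12` on the mean to protect dark regions). Intensity lateral
inhibition visits pixels in descending input order, per feature map; a
pixel that has been suppressed below its input value loses its right to
suppress others — one concrete reading of "each salient point suppresses
its surround", chosen for determinism.

Rank-order latency coding sorts the nonzero responses in descending order
(row-major on ties) and splits them into `T_max` near-equal bins, the
first `count mod T_max` bins taking one extra element; bin `k` spikes at
step `k` and zero responses never spike. Binning over nonzero responses
only (rather than all pixels) keeps "no drive" and "weak drive"
distinguishable.

## Synthetic dataset

The generator emulates the statistics the front-end cares about: each
class is an oriented soft-edged bar (angles evenly spaced over a half
turn) with +/-2 px positional jitter and additive Gaussian noise
(sigma = 0.05 by default) on a 24 x 24 canvas. The class signal is carried
entirely by edge orientation — exactly the cue a DoG front-end plus STDP
feature learning can extract. What it does **not** emulate: stroke-shape
variability, scale changes, clutter, or within-class style variation of
real handwritten digits; a passing end-to-end test therefore demonstrates
that the coding/plasticity machinery works, not that the preset would
reach any particular accuracy on a real dataset.

## Preset network and chosen parameters

`S1 -> C1 -> S2 -> C2 -> S3 -> C3` on a `(15, 6, 24, 24)` input: 5x5
kernels (pad 2) into 16 maps, 2x2 pool; 3x3 (pad 1) into 32 maps, 3x3
pool; 5x5 (pad 2) into `10 x n_classes` decision features read out by
global max potential through a block decision map. Paper-grounded choices:
six DoG channels, normal weight initialization (mean 0.8, std 0.05),
R-STDP weight range `[0.2, 0.8]` with the stabilizer off, the
infinite-threshold decision layer, and `floor(kernel/2)` padding so no
information is lost at borders. Package-chosen values (with rationale):

- firing thresholds 40 (S1) and 60 (S2): roughly two thirds of the
  maximal attainable potential at initialization, putting the C2 code at
  ~50% occupancy — low enough to be discriminative, high enough that no
  stimulus goes silent;
- encoder: window 7, three DoG scales in both polarities, clip threshold
  0.01, normalization region 9, `T_max = 15`;
- STDP rates 0.004/-0.003 for S1/S2 (gentle, since these stages mostly
  need to keep their initialization's diversity over 2 epochs each);
  R-STDP rates 0.02/-0.015 with anti-rates -0.02/0.0025 — reward and
  punishment asymmetric in the depression term so that punished features
  recover slowly rather than being erased;
- training schedule 2 + 2 unsupervised epochs, up to 20 R-STDP epochs,
  200 training / 60 held-out samples. These sizes keep the full pipeline
  around two minutes on one CPU core while leaving a wide margin on the
  learning criterion (training accuracy typically reaches 1.0 within two
  epochs).

## Pattern-selectivity experiment

One convolutional layer (four features, kernel covering the whole 8x8
input, `T_max = 10`) sees 400 presentations; on a random half, 20 fixed
afferents fire with fixed latencies inside the first 4 steps, and on every
presentation 12 random afferents fire at random times. The firing
threshold (13) sits just below the pattern's total drive, so the winner's
first spike falls at the pattern's end — every pattern afferent then
satisfies `T_j <= T_i` and is potentiated, while noise-only presentations
stay sub-threshold and trigger no plasticity. Rates 0.1/-0.075 with the
stabilizer on `[0, 1]`. The reported score is the best cosine similarity
between a feature's weights and the pattern's binary indicator; the
operating point was chosen so the measure targets the full pattern (a
threshold crossed mid-pattern would systematically depress the pattern's
late afferents and cap the cosine well below 1 regardless of convergence).

## Numerical choices

- `NO_SPIKE` is stored as -1 in integer spike-time grids (outside the
  valid bin range) and treated as +infinity in comparisons; inside waves
  the all-zero column is the encoding.
- Waves are `uint8`; potentials and weights are `float64`.
- Text tensor files store floats with shortest round-tripping decimal
  representation, so read-after-write is bit-exact; integer-valued files
  load as `int64`.
- All randomness flows through `numpy.random.Generator`; every entry
  point takes a seed or generator, and derived seeds are spawned via
  `SeedSequence`.
- Degenerate inputs: empty winner lists are no-ops for plasticity; a
  pooling spec whose stride exceeds the padded input (output size zero)
  is rejected; equal center/surround widths for DoG kernels are rejected.

## Known limitations

Batch processing and convolution stride > 1 are unsupported (the
accumulative time dimension occupies the batch axis); neurons are
non-leaky and strictly single-spike; no eligibility traces or delayed
reward; no error backpropagation. The visualization of learned features is
limited to dumping weight tensors as text. The IDX adapter reads
user-supplied raster files only; nothing is downloaded.
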