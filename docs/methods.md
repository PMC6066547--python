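# Methods

This note records the models implemented in `rivalmix`, the parameters that
matter, and the design choices made where more than one reasonable convention
exists. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stimulus construction

Mixtures require equal-size sources, so images are standardized by a
center-crop to the largest centered square followed by bicubic resampling to
a common side (default 224 px, the canonical classifier input; the tests and
the acceptance script use 64 px to keep run times in seconds). The crop and
the interpolation filter are configuration values, not claims about how any
particular dataset was prepared.

*50/50 mixtures* average RGB values pixel-wise and round half-up; the
deviation from the exact mean is at most 0.5 intensity steps and the
operation is exactly symmetric in its arguments.

*Phase/magnitude hybrids* operate per RGB channel: each channel is Fourier
transformed (unnormalized forward, 1/(HW) inverse), the magnitude spectrum of
one source is combined with the phase spectrum of the other, and the real
part of the inverse transform is clamped to [0, 255] and quantized.
Clamping rather than rescaling is deliberate: rescaling would change the
stimulus's luminance and contrast in a pair-dependent way. The
pre-quantization result conserves the magnitude source's spectrum to
floating-point precision, which the tests assert. Per-channel operation was
chosen over a luminance/chrominance split to treat the three channels
symmetrically.

Average mixtures enumerate unordered pairs (the operation is symmetric);
phase/magnitude mixtures enumerate ordered pairs, since the two roles
differ. A seeded perfect matching ("unique pairing") is provided for
designs where each image may appear only once.

## Image parameters

Six retained parameters and the extended set of twelve. All intensity-domain
quantities are computed on the weighted-intensity (luma) image
0.299R + 0.587G + 0.114B in float, before any quantization:

| parameter | definition | default/units |
|---|---|---|
| luminance | mean luma | [0, 255] |
| global_contrast | population std of luma | intensity |
| gradient | Σ squared forward differences (both axes) | intensity² |
| horizontal/vertical_gradient | per-axis terms of the above | intensity² |
| low/high_frequencies | Σ \|DFT\| over radial frequency ≤ 0.25 / ≥ 0.75 of Nyquist | intensity |
| colorfulness | Σ √(I² + Q²) over pixels (NTSC YIQ) | intensity |
| saturation | mean of 255·(max−min)/max over RGB; 0 at black pixels | [0, 255] |
| avg_red/green/blue | per-channel means | [0, 255] |
| local_contrast | mean within-block luma std, non-overlapping tiles (default 8 px, remainders dropped) | intensity |

Choices that were genuinely open: the gradient operator is first-order
forward differences (closest to a bare ∇ symbol; Sobel would smuggle in a
smoothing kernel); the spectral bands are radial in the 2-D frequency plane
with per-axis frequencies normalized to Nyquist = 1, DC included in the low
band; colorfulness is kept as a pixel sum while luminance/saturation are
means — for same-size image pairs the ratio-based dominance model is
unaffected by the sum-vs-mean convention. The dominance analysis only ever
consumes parameter *ratios*, which is why these conventions are safe to fix
once.

`select_least_correlated` reduces the twelve to k features by greedy forward
selection on absolute Pearson correlation (seeded by the least-correlated
pair, lexicographic tie-breaks, constant columns flagged and excluded). The
greedy rule is deterministic and reproduces the intended behavior — one
representative per cluster of highly correlated features — on the synthetic
copy-pair benchmark in the tests.

## Choice model

A perceiver maps an image to K logits. The top-N rule declares source i
"chosen" when top-N(mixture) ∩ top-N(source i) ≠ ∅; N defaults to 5 with
N = 2 exposed. Ties in the probability ordering break by ascending category
index — irrelevant for real outputs, deterministic for synthetic fixtures.

Stochasticity is modeled by adding i.i.d. N(0, σ²) noise to the logits
before the softmax. Fresh noise is drawn for every trial in every iteration,
and by default all three distributions (mixture and both sources) are
re-noised; a mixture-only switch exists because the alternative reading is
defensible. Scenario probabilities are the across-iteration mean of
proportions computed on a without-replacement sample of trials (defaults: 90
trials, 100 iterations), with the across-iteration standard error. The σ
sweep (default grid 0–5) selects the σ minimizing total-variation distance
between the (none, one, both) vector and a reference, ties toward smaller σ;
total variation was chosen because the matching criterion is otherwise
underdetermined.

## Dominance model

Only trials where exactly one source was chosen enter the dominance fits.
The model is a logistic regression on x = log feature ratios with **no
intercept**: exchanging the two images negates x and must map P to 1 − P,
which an intercept would break. The implemented sign convention is the
standard logistic P = 1/(1 + exp(−Σβx)), so β > 0 means the image with the
larger parameter tends to win; predictability is reported as |β|.

Multi-parameter fits carry a ridge penalty (subsets are enumerated
explicitly, so a sparsity penalty would be redundant); the strength is chosen
by k-fold cross-validated log-loss on a logarithmic grid over [1e−4, 1e2]
with λ = 0 allowed — the unpenalized case is the single-parameter fit.
Standard errors come from the inverse Fisher information at the estimate
(sandwich form when λ > 0). Complete separation at λ = 0 is detected
(unbounded coefficients) and flagged, with a fallback to the smallest
positive λ on the grid. Features are floored at 1e−8 of the pair's scale so
zero-valued parameters produce finite ratios; a pair with both values zero
contributes log-ratio 0.

Model choice is ŷ = 1 iff P ≥ 0.5 (the measure-zero tie resolves to 1,
fixed for determinism), and the reported score is *agreement*: the fraction
of trials where the model's choice matches the observed winner. Subset
scoring enumerates all subsets up to the requested size; for each subset the
ridge strength is selected once on the full data and agreement is then
measured by k-fold cross-validation (mean over folds, SE across folds). The
single-selection-then-CV shortcut slightly optimistic-biases the absolute
level but leaves subset rankings intact, which is what the analysis uses.

Dominance curves bin the single-winner trials into equal-width bins on the
log-ratio axis (default 9 bins over the observed range, empty bins omitted)
and attach exact Clopper–Pearson binomial intervals computed from the beta
quantile characterization.

## Layer analysis

For each layer, the Pearson correlation between two images' activations: per
channel map (flattened spatially) and averaged over channels for
convolutional-style layers, over the whole unit vector for flat layers.
Whole-layer flattening is implemented as an alternative mode and recorded in
output metadata. Zero-variance maps contribute correlation 0 and stay in the
average, so layer means are comparable across images. Winner/loser profiles
aggregate the same trials for both references (identical trial counts by
construction); outcome-grouped profiles split phase/magnitude trials by
which source won and report each group against both references. Groups of
size one report an undefined (NaN) standard error rather than a fabricated
zero.

## Mock perceiver

The mock perceiver is a seeded hierarchy of block-mean downsampling (factor
2), random channel-mixing linear filters, and ReLU, ended by a random linear
projection of the flattened last layer to a 64-dimensional embedding and a
cosine-similarity head against K seeded unit templates scaled to logits
(scale 20). Two details matter. First, the embedding projects the
*spatially centered* activations: without centering, the shared DC response
dominates every embedding and all inputs collapse onto the same top
categories. Second, the head is cosine-based, which gives controllable
overlap structure — mixtures of two sources land between their embeddings,
producing a realistic mix of one/both outcomes. The mock has no trained
knowledge; it exists so the pipeline's logic is testable bit-for-bit without
weights. Adapters for pretrained networks plug in through the same
two-method contract but are deliberately not shipped.

## Synthetic generators and what they do (not) show

Textures are 1/f^α Gaussian noise fields affinely mapped to target luminance
and contrast, then colorized along a fixed hue/saturation direction whose
luma projection is normalized out — so luminance, contrast, and saturation
are hit essentially exactly (within 2% pre-clipping, asserted by the
generator), and the spectral slope α steers gradient and band energies.
Banks sample parameters log-uniformly (wide, symmetric ratio coverage);
jointly infeasible draws (would clip > 1% of pixels) are rejection-sampled.
Choice trials draw feature log-ratios from N(0, spread²) and winners from
the logistic model with known β. Activation fixtures use
mix = α·winner + √(1−α²)·noise per layer, giving an analytically known
mixture-winner correlation of exactly α. Report tables are multinomial draws
per participant; defaults for the emulation (one-image share ≈ 70%, 100
participants × 30 trials) mirror the scale of a crowdsourced brief-exposure
experiment.

These generators validate the *machinery*: round trips (generate → analyze →
recover the generating parameters) pass within stated statistical
tolerances. They do not emulate natural-image category structure, semantic
content, or trained feature hierarchies — so passing tests demonstrate
correctness of the analysis, not that any particular trained network or
human population behaves like the mock. Which parameters win for the mock
perceiver (contrast- and spectrum-driven, by construction of its embedding)
should not be read as a claim about any trained system.

## Problem sizes and numerics

Default analysis sizes were chosen so every stage is exercised at
statistically meaningful scale while a full pipeline run stays in the
tens-of-seconds range: 60-image banks at 64 px (1770 pairwise mixtures),
2000-pair recovery simulations, 90-trial/100-iteration scenario resampling,
activation fixtures of width 10⁴ × 50 trials. Coefficient recovery at these
sizes is accurate to a few hundredths (asserted at 3·SE); the null
false-positive rate of the |β| > 1.96·SE criterion is verified at 5% ± 2%.

Numerical conventions: softmax is max-stabilized; logistic fits run lbfgs to
tol 1e−10; correlations of constant vectors are defined as 0; dominance-curve
bin edges span the observed range exactly, with boundary values clipped into
the end bins. All randomness flows through explicit `numpy` generators; every
public generator and the pipeline are bit-reproducible given their seeds.

## Known limitations

- The mock perceiver's dominance structure is an artifact of its embedding
  geometry; it is a test harness, not a model of trained vision.
- The ridge-strength-then-CV subset scoring shortcut (above) trades a small
  optimistic bias for a large speedup.
- Human data enter only as pre-coded scenario tables; free-text report
  encoding is out of scope.
- No contrast-energy equalization between mixture sources, and no dynamic
  (time-varying) rivalry of any kind.
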