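# Methods

This note documents the models, fitting procedure, evaluation metrics, and
synthetic-data design implemented in `popencode`, together with the
numerical choices made where the design was genuinely open.

## Signal chain

Sound waveforms are converted to a log-compressed spectrogram by a fixed
(never fitted) second-order gammatone filterbank: `F = 18` channels with
center frequencies log-spaced from 200 Hz to 20 kHz inclusive
(≈ 1/3 octave per channel), envelope = squared filter output averaged
within 10 ms bins (100 Hz frame rate), then compressed as
`log10(1 + p / eps)` with `eps` set to `1e-5` of the maximum power.  This
floor convention maps silence exactly to 0 and keeps all values
nonnegative and finite; a `halfwave` envelope switch exists because the
envelope extraction before downsampling is not uniquely determined by the
problem.  Spike trains are binned at the same 10 ms resolution into
neuron × time × repeat rasters in spikes/s; the PSTH is the repeat mean.

## Architectures

All models map the spectrogram to per-neuron firing rates through a stack
of shared layers plus a per-neuron readout:

| model      | shared core                                        | readout |
|------------|----------------------------------------------------|---------|
| LN         | rank-D factorized filter (Gaussian spectral × FIR) | sum + double exp |
| single-CNN | 1-D conv bank (Gaussian spectral, offset ReLU)     | dense + double exp |
| pop-LN     | linear 1-D conv bank (no activation)               | dense + double exp per neuron |
| 1D-CNN     | 1-D conv bank + hidden dense (ReLU)                | dense + double exp per neuron |
| 1Dx2-CNN   | two 1-D conv layers (150 ms, 100 ms) + hidden dense| dense + double exp per neuron |
| 2D-CNN     | three stacked 3×8 2-D conv layers + hidden dense   | dense + double exp per neuron |

Choices the architecture description leaves open, resolved here:

* Gaussian spectral weights are unnormalized (`g_j = exp(-(j-μ)²/2σ²)`);
  the component amplitude lives in the temporal taps.  μ may drift
  slightly outside the channel range to fit edge-tuned units; σ is floored
  at 0.25 channels.
* Temporal convolutions are causal with zero padding, and every stimulus
  snippet is convolved independently — no bleed across snippet boundaries.
* 2-D convolutions are causal in time and "same"-padded in frequency so
  array shapes are preserved; layers deeper than the first 1-D layer use
  unconstrained dense channel weights (the Gaussian constraint applies
  only to the spectrogram-facing layer).
* The output nonlinearity is the double exponential
  `r = b + a·exp(−exp(k(y−s)))` with per-neuron baseline `b`, amplitude
  `a`, threshold `s` and gain `k`.  The inner exponent is clipped at ±60
  so extreme drives saturate instead of overflowing.  As written the
  function is decreasing in `y` for `k > 0`; fitted gains are free in
  sign, and initialization favors `k < 0` (rate increasing with drive).

Parameter counting: a Gaussian spectral unit counts 2 values, an FIR unit
its tap count, a dense unit its fan-in, an offset ReLU 1 per unit, a
double exponential 4 per output neuron.  The default reporting convention
excludes the activation offsets of the spectrogram-facing convolutional
layer (so a 70-unit, 15-tap first layer counts 70·2 + 70·15 = 1,190); the
breakdown always reports both conventions, and `count_offsets='all'`
matches the length of an instantiated parameter vector exactly.

## Fitting

The whole numerical stack — forward passes, analytic backward passes, and
full-batch Adam — is implemented in numpy and is deterministic given
(seed, config, data).  Gradients of every layer are verified against
central finite differences in the test suite.  Optimizer defaults:
learning rate 1e-3, MSE loss averaged over neurons and time, batch = the
whole fit split (the datasets involved are far too small for mini-batching
to matter), patience 30 epochs, relative improvement tolerance 1e-6.
An optional float32 mode roughly halves fit time and is used for the
desk-scale protocol runs; results remain seed-deterministic.

Initialization distributions (per role): Gaussian spectral centers are
stratified — unit c draws uniformly from the c-th band of the channel
axis, so the deterministic mean initialization tiles the spectrum like a
filterbank; widths are uniform in [0.5, F/4] channels; FIR taps are
zero-mean Gaussian apart from a small positive lag-0 mean; dense weights
are Gaussian around the uniform average 1/fan-in with He-style spread
√(2/fan-in); output-nonlinearity baselines and amplitudes are scaled to
each neuron's response statistics, with gain mean −1 (rate increasing
with drive).  The stratification matters: a perfectly symmetric mean
initialization leaves identical units identical under full-batch gradient
descent, silently collapsing a multi-unit layer to rank 1.

Stage 1 fits the population model under `n_init` initializations
(`n_init−1` random draws + one set to the distribution means) with the
three-step heuristic: (A) fit the shared core with the output layer
replaced by a temporary per-neuron linear readout (weights + offset, no
output nonlinearity) — this keeps the population MSE objective defined
for a "model without its output layer"; (B) freeze the core and fit the
real output layer, whose frozen-core features are precomputed once per
epoch loop; (C) from the initialization with the best early-stop-split
MSE, fit everything jointly.  Early stopping always holds out 20% of the
estimation snippets (split by whole snippets, seeded) and restores the
best-epoch weights.  A NaN loss triggers one restart at half the learning
rate; initializations that still diverge are logged and excluded.

Stage 2 refits the output layer one neuron at a time against the frozen
core's precomputed features.  Because the readout loss is nonconvex (the
double exponential can start saturated, where its gradients vanish), each
neuron is fit from its stage-1 warm start (when the neuron was part of
stage 1) plus fresh draws up to `n_init`, keeping the early-stop winner;
fresh draws place the threshold inside the actual drive distribution of
the candidate readout and scale the gain to its spread.  Stage-2
initialization of the output nonlinearity is response-informed (baseline
and amplitude scaled to each neuron's response mean/spread) — without
this, rates of tens of spikes/s take thousands of epochs to reach from
unit-scale inits.

## Evaluation

* **TTRC** — mean Pearson correlation over all unordered repeat pairs of
  the validation raster; pairs with a zero-variance trial are excluded.
* **R_norm** — mean single-trial correlation between prediction and
  repeats, divided by √TTRC.  For repeats `r_i = s + noise` with
  signal-variance fraction `q`, a perfect prediction gives
  `⟨corr(r_i, p)⟩ = √q` while TTRC estimates `q`, so this normalization
  makes 1 the noise-limited ceiling; on noise-free data it reduces
  exactly to the raw correlation.  Values above 1 (sampling noise) are
  reported unclamped; neurons with TTRC ≤ 0.05 are flagged undefined and
  excluded from medians, since the correction is unstable there.
* **SNR** — per-neuron signal-variance fraction from the repeat-wise
  variance decomposition `max(0, (var(PSTH) − var_noise/M) / var_total)`.
  This is a surrogate definition (the quantity is otherwise unspecified);
  it is monotone in the same signal fraction TTRC estimates, which is all
  the SNR-matched subsetting requires.
* **Above-chance test** — jackknifed t-test over 20 contiguous
  time-segments of the validation PSTH, two-sided against zero (paired
  variant: against a second model's folds).  Auditory-responsive neurons
  are those above chance for all models in a reference set.
* **Population comparisons** — two-sided Wilcoxon signed-rank (paired) or
  Mann-Whitney U (unpaired), via scipy; exact small-sample computation
  below n = 25 (no ties arise with continuous scores).
* **Model equivalence** — plain Pearson correlation between two models'
  predicted validation PSTHs.

## Synthetic data

The generator produces the dataset geometry the pipeline expects without
any recorded data: estimation snippets with a single repeat, a disjoint
validation set with 20 repeats, neurons grouped into sites.  Stimuli are
1 s spectrogram snippets of 1/f-shaped (temporal and spectral) Gaussian
noise, rectified to a nonnegative floor with a 100 ms silent tail per
snippet.  The ground-truth population is itself a 1D-CNN whose
convolutional bank spans a `subspace_dim`-dimensional shared subspace;
hidden and readout weights are random, and each neuron's output
nonlinearity is calibrated on an internal probe ensemble (threshold at
the median drive, gain ∝ 1/spread) so every neuron is well modulated.
Trial noise is Gaussian, scaled per neuron so the signal-variance
fraction matches a target SNR drawn uniformly from (0.3, 0.9) by default
(Poisson spiking is available instead); rates are clipped at zero.  An
`orthogonal_site` option gives one site a private convolutional/hidden
block, producing a control population whose held-out tuning cannot be
reached from the other sites' subspace.

Default desk-scale fixture: N = 60 neurons, 3 sites, 120 estimation
snippets of 1 s, 12 validation snippets × 20 repeats, F = 18 at 100 Hz —
sized so every protocol runs in minutes on one CPU.  What these fixtures
do **not** emulate: acoustic structure of natural sounds, adaptation or
other across-snippet dynamics, correlated (non-independent) trial noise,
and non-stationary recording artifacts — so passing protocol tests here
demonstrates correctness of the pipeline and the qualitative behavior of
the protocols under their own assumptions, not performance on real
recordings.

## Protocols

Held-out: all neurons of one site are excluded from stage 1; stage 2 then
fits only their readouts.  Matched control: an equal number of off-site
neurons — greedy nearest-neighbor matched on single-neuron LN baseline
scores, visited in descending score order (deterministic) — are excluded
instead.  Cross-population: stage 1 on one population, stage-2 readouts
on another that shares the stimulus.  SNR matching keeps, per shared
histogram bin (20 equal-width bins over the pooled range), the
`min(count_A, count_B)` highest-SNR neurons of each side.  Subsampling
draws a snippet subset (uniform, seeded, identical across arms) and
compares a pre-trained core (stage 1 on full data minus the held-out
site) against a standard fit (both stages on the subsample), scoring the
held-out site's neurons; curves are normalized to the standard arm's
full-data median when fraction 1.0 is run.

Protocol runs at desk scale use a scaled-down exemplar (16 convolutional
units per layer and 20 hidden units against a 10-dimensional true
subspace) with two initializations, 500 epochs and the float32 optimizer.
Fit quality is the main driver of protocol fidelity: under-converged or
under-sized cores show a spurious held-out deficit simply because the
control arm's core is tailored to its training neurons, and the deficit
shrinks toward zero as both arms approach the data-limited ceiling.  A
residual in-sample advantage of order 0.01 R_norm can remain at this
population size (60 neurons); it is far smaller than the
orthogonal-subspace control's deficit but can still reach significance in
a paired rank test, which should be kept in mind when reading desk-scale
p-values.

## Known limitations

* Population fits at few initializations occasionally land in clearly
  inferior local minima (the multi-initialization heuristic exists for
  exactly this reason); protocol comparisons therefore use the same
  budget in every arm so basin variance affects both sides equally.
* The SNR definition is a surrogate (see above).
* The gammatone frontend fixes filter order and bandwidth; no cochlear
  parameters are fit.
* Stage-2 per-neuron refits share the early-stop split with stage 1
  rather than re-drawing it, so a pathological split affects both stages
  the same way.
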