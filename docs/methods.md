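# Methods

## Model

The generator is a feedforward chain — Poisson input layer → hidden LIF
layer → output LIF layer → synaptic filter → linear readout — with an
optional Poisson perturbation layer coupled into the output layer's
synaptic current. All simulation is clock-driven at Δt = 1 ms (the readout
is strided to the 250 Hz EEG rate, i.e. every 4th step; both are
configurable, with the constraint that 1000/(Δt·f_EEG) is an integer).

**Neurons.** The LIF map uses the exact-decay discrete form
`I[n+1] = αI[n] + drive[n]`, `u[n+1] = βu[n] + I[n] − ϑS[n]` with
α = exp(−Δt/τ_s), β = exp(−Δt/τ_m). Defaults: τ_m = 10 ms, τ_s = 5 ms,
ϑ = 1 mV, u_rest = 0, R = 1 (dimensionless substitution, so currents are
unitless). Spikes are detected on the *pre-update* potential with the tie
`u = ϑ` counting as a spike, and reset subtracts ϑ (reset-by-subtraction),
so non-unit thresholds behave correctly. QIF and EIF variants advance the
membrane by explicit Euler on their continuous equations with the same
reset; the EIF exponential is clamped at a configurable ceiling (30 mV) so
it saturates rather than overflows, while QIF divergence raises an error
naming the offending step. The subthreshold QIF limit toward leaky decay
is a₀·u_c → 1 (linearizing the quadratic force), not a₀ → 0, which would
remove the restoring force entirely; the test suite checks the correct
limit.

**Synaptic filter.** Output spikes are smoothed by the cascade
ṙ = −r/τ_d + h, ḣ = −h/τ_r + (1/τ_r τ_d)·Σδ with τ_r = 3 ms, τ_d = 2 ms.
Because the cascade is linear and time-invariant we integrate it with the
exact one-step (matrix-exponential) discretization rather than forward
Euler: at Δt = 1 ms with τ_d = 2 ms, forward Euler distorts the impulse
peak by ~30%, while the exact update reproduces the analytic
difference-of-exponentials kernel to machine precision at every sample
point. The kernel has unit area, so a neuron firing at rate f contributes
a mean filter output of ≈ f per ms.

**Readout and sampling.** `EEG_c[t] = Σ_j W_cj · r_j[4t]`. No anti-alias
filter is applied before striding: the filter kernel itself is the
low-pass, and the band of interest (≤ 20 Hz) is far below the 125 Hz
Nyquist of the EEG rate.

## Training

One frozen 10 Hz Poisson raster per class drives the network; every epoch
runs all classes, sums the squared reconstruction errors, and applies one
Adam update to W_ih, W_ho and W_read (perturbation weights are never
trained, and training refuses to run with a perturbation layer attached).

**Surrogate gradient.** The forward spike stays the hard Heaviside; its
backward pseudo-derivative is `slope · σ′(slope · (u − ϑ))` with slope 10
by default (at the threshold this factor is slope/4). The reset term is
treated as a constant in the hard backward pass — a standard
stabilization; the fully sigmoid-relaxed mode used by the
finite-difference audit differentiates the reset path exactly, and the
audit agrees with central differences to ≤ 1e-4 relative error.

**Reduction convention.** Gradients use the *summed* squared error over
channels, samples and classes. With the reference Adam hyperparameters
(lr 5·10⁻⁴, ε = 0.8), mean-reduced gradients would be dwarfed by ε and the
effective step would collapse to ~lr·g/ε ≈ 10⁻⁶ per epoch for every
signal scale we consider realistic; under sum reduction the large ε
instead acts as a trust region that damps weakly-driven parameters. The
loss *recorded* per epoch and class remains the mean squared error, which
is also what `mse_loss` computes.

**Optimizer defaults** (all configurable in `TrainConfig`): learning rate
5·10⁻⁴, betas (0.9, 0.999), ε 0.8, weight decay 0, 1000 epochs, early
stop when the summed per-class mean MSE falls below 10⁻³ × the mean
template variance. Classes are trained jointly in one update; an
alternating per-class mode is available behind a flag. Training is fully
deterministic given the weight seed and input rasters.

**Initialization.** Spiking weights are zero-mean Gaussians with std
1/√fan_in; the readout uses 0.1/√n_output so the initial EEG output is
small relative to the templates. At these scales the hidden layer fires at
a few tens of Hz initially, enough for surrogate gradients to flow.

## Perturbation and generation

The perturbation layer holds `n` Poisson neurons at rate `f`; its coupling
matrix is drawn once per attachment (std = `weight_scale`, default 1)
and frozen. The per-synapse std is deliberately *not* normalized by √n:
the injected current variance then grows linearly with the population
size, which is what makes sample fidelity fall monotonically along both
grid axes (population size and rate). Noise current enters the output
layer's synaptic current (the same summation as the hidden drive), not
the membrane directly. Each generated sample redraws only the noise
raster, with its seed derived from `(seed, class index, sample index)` so
any single trial is reproducible in isolation. `n = 0` or `f = 0` is an
exact no-op and reproduces the deterministic reconstruction.

## Fixtures (synthetic study data)

The fixture generators emulate the structure of the two BCI paradigms at
realistic scalp-EEG magnitudes (a few µV of oscillation over a comparable
1/f-plus-white noise floor), band-limited 0.5–20 Hz by a zero-phase
4th-order Butterworth:

- **Motor imagery** — 3 s, 250 Hz, channels C3/C4, 40 trials/class. A
  10 Hz mu rhythm (6 µV, slow random envelope, random phase per trial, so
  no two trials are identical) is attenuated by the ERD depth (default
  0.8) on the channel contralateral to the imagined hand. Noise: 1/f with
  2 µV RMS plus 1 µV white.
- **SSVEP** — 2 s, 250 Hz, channel Oz, 20 trials/class, classes at 10 and
  11 Hz. The oscillation (4 µV plus a 25% first harmonic) keeps a fixed
  phase across trials — the physiological response is phase-locked to the
  flicker, which is exactly why trial averaging is a valid template
  extractor here. Noise: 1/f at 1.5 µV plus 0.75 µV white. Class
  frequencies closer than 2/duration Hz trigger a resolvability warning.

What the fixtures do **not** model: eye/muscle artifacts, inter-trial
nonstationarity beyond the random envelope/phase, volume-conduction
correlation between channels, and mu/beta co-modulation. Passing the
validation suite on fixtures therefore demonstrates the mechanics of the
method — reconstruction, biomarker-preserving diversification,
cross-classifiability — not performance on any real recording.

## Evaluation

**CSP.** Class covariances follow the trace-normalized per-trial
convention Σ_k = mean(E Eᵀ / tr E Eᵀ); trials are not mean-centered
(band-passed data is already zero-mean). Filters come from
`scipy.linalg.eigh(Σ₁, Σ₁+Σ₂)`; components are ordered by descending
eigenvalue and the top and bottom `n_components/2` (default 2+2, clipped
to the channel count) are retained. A singular composite covariance is
ridge-regularized with λ = 10⁻⁸·tr/n_channels and a logged warning.
Features are per-component log-variances, floored at the smallest positive
float before the log.

**Classifiers.** LDA (with a shrinkage fallback if the scatter is
singular), linear-kernel SVM, KNN with k = 5 (k lowered — and kept odd to
avoid binary vote ties — when fewer samples exist), and "Gaussian",
interpreted as quadratic discriminant analysis with a naive-Bayes variant
behind a flag. LDA's posteriors drive best-trial template selection, with
posterior ties broken toward the lowest trial index.

**Protocols.** validation-a trains (CSP filters included) on original
data and tests on synthetic; validation-b is the reverse. The baseline is
Monte-Carlo cross-validation: 100 independent random 95/5 splits,
resampled until both sides cover both classes. For single-channel sets,
where spatial filtering is undefined, both protocols substitute per-trial
log Welch band-power features (0.5–20 Hz) — our concrete replacement for
the underspecified SSVEP MLP. The Wilcoxon signed-rank comparison drops
zero differences, requires ≥ 5 pairs, and uses the exact null for n ≤ 25
(normal approximation above); it is backed by `scipy.stats.wilcoxon`.

**Correlation grids.** For each (population size, rate) cell the default
statistic is the Pearson correlation between the *average* of the cell's
100 synthetic trials and the template (a per-sample-correlation mean is
available as an option). The inverse trend along both axes is sharp
through the mild and moderate cells; at the harshest corner (hundreds of
noise neurons at hundreds of Hz) the curve flattens toward a plateau, and
with 100-trial averages the ordering of neighbouring extreme cells can
fall inside estimation noise.

## Problem sizes and numerical choices

The packaged study runs at a scaled network of [50, 150, 40] neurons
(reference sizes for full-scale use: MI [500, 1500, 100], SSVEP
[100, 500, 200]), 1000 training epochs, 100 synthetic samples per class
and condition, and a 3×3 perturbation grid spanning 10–220 noise neurons
× 20–800 Hz. At these sizes the complete acceptance run takes ~5 minutes
on one CPU. Welch spectra default to Hann windows with min(n, 2·f_s)
segments (0.5 Hz bin spacing at 2 s); tones separated by exactly one bin
only resolve into two maxima under the rectangular window, which
`power_spectrum(window="boxcar")` exposes. All stochastic components take
explicit integer seeds; per-object seeds derive from `SeedSequence` spawn
keys, never from global state.

## Known limitations

- Backpropagation-through-time stores full spike/potential traces, so
  memory grows as batch × steps × neurons; generation chunks samples in
  batches of 50 to bound this.
- The training loss plateaus rather than reaching zero: a binary spike
  raster at 1 ms resolution can only approximate a continuous template,
  and the residual falls with output-layer size.
- Dale's law (sign-constrained synapses) is not enforced; weights may
  change sign during training.
- The scaled network and fixture conditions demonstrate the method's
  properties; hyperparameters were not re-tuned for the full-scale
  reference sizes.
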