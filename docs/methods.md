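# Methods

This note records the model choices, numerical decisions, and known
limitations of `dmipost`. It is written for a reader who wants to know
what exactly is computed, which knobs matter, and what the test suite
does and does not demonstrate about real data.

## Problem and approach

Voxel-wise microstructure imaging estimates tissue parameters θ from a
multi-shell diffusion-MRI signal vector x by inverting a forward model
x = M(θ). The inverse problem is ill-posed: it is noisy, and for richer
models genuinely degenerate (distinct θ explain the same signal). We
estimate the full Bayesian posterior p(θ|x) by simulation-based
inference: draw (θᵢ, xᵢ) from the prior and forward model, and fit a
conditional density estimator q(θ|x) by minimizing the Monte-Carlo
approximation of E_x[KL(p(θ|x) ‖ q(θ|x))], which equals
−(1/N)·Σᵢ log q(θᵢ|xᵢ) up to a constant. A single trained estimator is
amortized over all voxels; per-voxel inference is just conditioning and
sampling.

The estimator has two jointly trained parts:

* an **embedding MLP** (three hidden layers, 256/128/64 tanh units,
  linear readout) mapping the signal vector to Nf learned features
  (default Nf = 6);
* a **conditional masked autoregressive flow**: five stacked MADE-style
  transforms with Gaussian conditionals (50 hidden units each, input
  order reversed between transforms, base distribution standard
  normal), conditioned on the embedded features. Log-densities are
  exact by the change-of-variables formula; sampling inverts the stack
  coordinate-by-coordinate.

Both are implemented directly in numpy with hand-derived analytic
gradients (verified against finite differences in the test suite) and
a flat-vector Adam optimizer, so training is fully deterministic given
a seed and runs on a single CPU.

### Parameter transform

Flow mass must live inside the uniform prior box. Parameters are mapped
by a per-coordinate logit of the box to an unbounded space and
standardized there; the flow models this space, and reported densities
include the Jacobians. Posterior draws map back through the sigmoid, so
the rejection step required by the prior box accepts essentially all
samples (the acceptance fraction is tracked and a collapse below 0.1%
raises an error recommending retraining).

### Training protocol

Adam with learning rate 1e-3, minibatch 128, 5% random validation
split, early stopping after 30 epochs without validation improvement,
best-validation weights restored. On noise-free targets the conditional
densities become extremely sharp and late-phase optimization steps
destabilize; a global gradient-norm clip (default 5) suppresses this
without changing the optimizer's settings. Desk-scale runs cap the
epoch budget (the cap is a configuration argument; the experiment
drivers default to caps that keep one full experiment within minutes on
one CPU).

## Forward models

All three models share the conventions: b-values enter in s·mm⁻² and
are converted to ms·µm⁻² internally, diffusivities are in µm²/ms,
δ and Δ in ms, and every noise-free attenuation is 1 at b = 0. The
tissue orientation is a nuisance: it is drawn uniformly on the sphere
per simulated voxel and marginalized by the estimator (the inferred
vector contains only the scalar parameters).

* **Ball&Stick** — f_in·exp(−bD_in(g·n)²) + (1−f_in)·exp(−bD_e).
* **Standard model** — Watson-dispersed sticks (f, D_a, ODI) plus an
  axially symmetric extra-neurite zeppelin (D_e∥ ≥ D_e⊥) convolved with
  the same Watson distribution (a switch keeps it aligned instead; the
  source material does not state which was used).
* **Extended-SANDI** — Watson-dispersed sticks (f_n, D_n, ODI), a
  Gaussian-phase-distribution sphere compartment for somas (f_s, C_s),
  and an isotropic extra-cellular ball (f_e = 1−f_n−f_s, D_e). The flow
  estimates six parameters; f_e is reconstructed from the simplex
  constraint.

### Watson convolution

The spherical convolution of an axially symmetric kernel exp(−c·t²)
with the Watson density exp(κ·t²)/Z is computed spectrally: both
factors are expanded in even Legendre polynomials (coefficients by
Gauss–Legendre quadrature, default 100 nodes, orders ≤ 40) and combined
through the Funk–Hecke theorem into a short Legendre series in the
angle between gradient and mean axis:

A(ψ) = Σ_l (2l+1)·I_l(κ)·J_l(c)·P_l(cos ψ) / (2·I_0(κ)).

This is deterministic, accurate to well below 1e-3 against brute-force
Monte-Carlo orientation averaging (tested), and fast enough to simulate
10⁵ dispersed-stick voxels in seconds. The ODI↔κ map is the NODDI
convention κ = 1/tan(ODI·π/2).

### Sphere compartment

C_s is the Murday–Cotts (Gaussian phase distribution) attenuation
coefficient of diffusion restricted in a sphere, per squared diffusion
wavevector in cycles (q = γgδ/2π):

C_s = (8π²/(D_s δ²)) Σ_m [α_m⁻⁴/(α_m²r_s²−2)] · T_m(δ, Δ, α_m²D_s),

with α_m·r_s the roots of x⁻¹J_{3/2}(x) = J_{5/2}(x) (equivalently the
stationary points of the spherical Bessel function j₁; the first is
2.0816) and T_m the standard pulsed-gradient time dependence. Fifty
roots change the result by <0.1% versus one hundred. With the default
protocol (δ=7 ms, Δ=24 ms, D_s=3 µm²/ms) the prior box endpoints
correspond to C_s(15 µm) = 1104.6 µm² and C_s(0.97 µm) = 0.15 µm²; the
prior uses [0.15, 1105] µm². The sphere attenuation in the SANDI signal
is exp(−q²C_s) with q² = b/(4π²(Δ−δ/3)) — the 4π² keeps the wavevector
convention consistent with C_s, without which a 15 µm soma would
implausibly suppress the b=200 s·mm⁻² shell by e⁻¹⁰.

### Priors and constrained samplers

Uniform priors: signal fractions in [0,1], diffusivities in
[0.1, 3] µm²/ms, ODI in [0.03, 0.95], C_s in [0.15, 1105] µm². The
standard model's D_e⊥ ≤ D_e∥ constraint is sampled uniformly on the
triangle via D_e∥ = 0.1 + 2.9·√u₀, D_e⊥ = 0.1 + (D_e∥−0.1)·u₁ (the
square root is what makes the triangle coverage uniform; a switch
implements the linear variant). SANDI fractions use f_n = k₂k₁,
f_s = (1−k₂)k₁, f_e = 1−k₁ with k₁, k₂ uniform — note this induces a
density ∝ 1/(f_n+f_s) on the simplex rather than a uniform one; it is
kept because it is the published sampling rule.

### Noise

Rician: independent Gaussian noise of standard deviation σ = 1/SNR on
the real and imaginary channels of the b0-normalized signal, then the
magnitude. Simulated noisy voxels are renormalized by their mean noisy
b=0 signal, exactly as measured data would be, and the b=0 columns are
dropped (253 diffusion-weighted values for the default 266-measurement
protocol).

## Posterior summaries

Per 1-D marginal of 15,000 posterior draws:

* **MAP** — argmax of a Gaussian KDE (Silverman bandwidth) on a fixed
  512-point grid over the prior range. The KDE is evaluated by binned
  convolution (histogram ⊛ Gaussian kernel, boundary-renormalized),
  which matches the exact KDE to grid resolution at a small fraction of
  the cost.
* **Uncertainty** — interquartile range as % of the prior range
  (uniform samples give 50%; a Gaussian with σ = 10% of the range gives
  13.5%).
* **Ambiguity** — KDE full width at half maximum (outermost crossings,
  linearly interpolated) as % of the prior range (a Gaussian with
  σ = 5% gives 11.8%).
* **Degeneracy** — a two-component Gaussian mixture is fitted to the
  smoothed sample density (bounded least squares on the 512-point
  binned KDE; deterministic initialization at the 25th/75th
  percentiles, half-split standard deviations, equal weights). The fit
  targets the density *curve* rather than the sample likelihood on
  purpose: a likelihood (EM) fit decomposes the heavy tail of a skewed
  or boundary-piled unimodal sample set into a narrow-plus-broad pair
  whose mixture acquires a second local maximum the posterior does not
  have. The marginal is flagged when three conditions hold: the fitted
  mixture has more than one local maximum (derivative sign changes on
  a 1000-point grid), the component means are closer than the sum of
  the component standard deviations, and the smoothed sample density
  itself shows at least two interior modes (≥5% of the peak) on the
  prior-range grid — the last confirmation grounds the decision in the
  posterior rather than in fit-parametrization artifacts. The
  closeness condition is deliberate: it passes flat, uninformative
  marginals — whose two-Gaussian decomposition is two *separated*
  halves — and fires on the narrow-mode-inside-broad-envelope shape of
  genuinely degenerate marginals. The opposite (non-overlap) reading
  is available as an argument; it additionally flags every
  uninformative marginal (for Ball&Stick, the intra-neurite
  diffusivity whenever f_in ≈ 0), which contradicts that model's
  degeneracy-free behaviour.

All measures are invariant under joint affine rescaling of samples and
prior bounds (property-tested).

## MCMC reference

The check on the amortized posteriors is an adaptive
Metropolis-within-Gibbs sampler on the Offset-Gaussian log-likelihood
−Σ(xᵢ−√(Mᵢ²+σ²))²/(2σ²) − m·log(σ√2π), with σ = 1/SNR (known by
construction in simulations). The sampled vector appends two
orientation coordinates (cos θ, φ) to the scalar parameters, since the
sampler cannot marginalize the nuisance the way the amortized estimator
does; orientation draws are discarded before comparison. Chains run
15,200 iterations with 200 burn-in and no thinning, initialized at a
multi-start L-BFGS-B maximum-likelihood estimate. Proposal widths start
at 2% of each coordinate range; their logs move ±min(0.01, 1/√batch)
every 50 iterations toward a 0.44 acceptance target (diminishing
adaptation). Reported acceptance rates are measured over the second
half of the chain; for coordinates that the data leave uninformative
the slow adaptation can leave rates above the nominal band within one
chain — the draws remain valid, only less efficient.

## Synthetic data and what the tests show

All training and test data are simulated from the priors and forward
models above; no measured data enters the package. The simulations
emulate: the 6-shell acquisition (b = 200…6000 s·mm⁻², 20/20/30/61/61/61
electrostatically spread directions, 13 b=0, δ=7 ms, Δ=24 ms), Rician
magnitude noise at SNR 50, b0 normalization, and random single-fibre
orientations. They do **not** emulate: spatial structure and partial
voluming, multi-compartment T2 differences, exchange, fibre crossings,
gradient nonlinearities, motion or eddy artifacts, or spatially varying
SNR. Passing tests therefore demonstrate correct inference under the
stated generative model, not robustness to real-data model error; the
posterior-predictive-check operation is the first diagnostic to run on
measured data.

## Scales and runtimes

Desk scale (defaults of the experiment drivers) is chosen so that one
full experiment runs in minutes on one CPU: 1–2×10⁵ training
simulations, 10³ test posteriors, 15,000 posterior draws each. The
degeneracy-count experiment trains on 2×10⁵ noise-free simulations
(epoch cap 120). Published-scale runs (10⁶ training, 10⁴ test) use the
same code paths through the same arguments. Within-model degeneracy
counts depend on estimator convergence: an undertrained flow shows
spurious narrow side-modes that inflate counts, which is why the
drivers train to the early-stopping plateau rather than a fixed small
epoch count.

## Known limitations

* The LEMONADE cumulant statistics (standard model) and the high/low-b
  expansion statistics (SANDI) are not implemented; the
  manual-statistics pathway exists only for Ball&Stick (per-shell
  direction averages), and requests for the others raise with a
  pointer to the missing method.
* Degeneracy detection is per-parameter and one-dimensional; joint
  multi-parameter degeneracy is out of scope.
* The amortized posterior marginalizes orientation; the MCMC reference
  conditions on it. For strongly anisotropic voxels at high SNR the
  two coincide in practice (tested at SNR 50), but they are not the
  same object in general.
* Sequential (multi-round) posterior refinement for a single
  observation is not implemented; the estimator is single-round and
  amortized.
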