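# dmipost

Amortized Bayesian estimation of brain-tissue microstructure from
multi-shell diffusion MRI — full voxel-wise posterior distributions,
not just point estimates, with built-in measures of how much each
estimate should be trusted.

## The problem

Microstructure imaging fits a biophysical forward model M(θ) to the
diffusion-weighted signals of each voxel to estimate histologically
meaningful parameters θ: compartment signal fractions, diffusivities,
orientation dispersion, soma size proxies. Conventional non-linear
fitting returns a single best guess and hides two crucial facts: the
estimate has uncertainty (noise, limited acquisition), and for richer
models the inverse problem is *degenerate* — several distinct parameter
combinations explain the same signal equally well.

`dmipost` estimates the full posterior p(θ|x) for three standard
models — Ball&Stick, the standard model of white matter
(Watson-dispersed sticks + anisotropic extra-neurite Gaussian), and
extended-SANDI (sticks + soma spheres + extra-cellular ball) — using
simulation-based inference: N simulated pairs (θᵢ, xᵢ) train a
conditional density estimator q(θ|x) by minimizing the Monte-Carlo
approximation of the expected Kullback–Leibler divergence,

    L(φ) = −(1/N) Σᵢ log q_φ(θᵢ | xᵢ),

where q_φ is a masked autoregressive flow (five stacked MADE
transforms) conditioned on Nf features extracted from the signal by a
jointly trained three-layer MLP. Training is amortized: one fit serves
every voxel, after which a posterior is 50,000 flow samples away. Each
1-D marginal is summarized by its MAP, an uncertainty (interquartile
range as % of the prior range), an ambiguity (full width at half
maximum as % of the prior range), and a degeneracy flag from a
two-Gaussian decomposition of the posterior. An adaptive
Metropolis-within-Gibbs sampler on the Offset-Gaussian likelihood
provides the classical Bayesian reference for validation.

The flow, the embedding network, their joint training (Adam, analytic
gradients), and all forward models are implemented in numpy/scipy and
run on a single CPU.

## Worked example

Train a Ball&Stick estimator on simulated data and inspect one voxel's
posterior:

```python
import numpy as np
from dmipost import (
    make_default_scheme, generate_training_set, train,
    EmbeddingConfig, FlowConfig, TrainConfig,
    sample_posterior, summarize_voxel, get_model,
)

scheme = make_default_scheme()            # 6 shells, 253 DW + 13 b0, δ=7, Δ=24 ms
tset = generate_training_set("ball_stick", scheme, 100_000, snr=None, seed=0)
ap = train(tset, EmbeddingConfig(n_features=6), FlowConfig(),
           TrainConfig(max_epochs=60, patience=30, seed=1))

# a fresh "observed" voxel with known ground truth
obs = generate_training_set("ball_stick", scheme, 1, snr=None, seed=99)
samples = sample_posterior(ap, obs.x[0], 15_000, np.random.default_rng(2))
summary = summarize_voxel(samples, get_model("ball_stick").prior)
for name, p in summary.parameters.items():
    print(f"{name:5s} map={p.map_estimate:6.3f} unc={p.uncertainty:5.2f}% "
          f"amb={p.ambiguity:5.2f}% degenerate={p.degenerate}")
print("truth:", np.round(obs.theta[0], 3))
```

Output from this exact script (seeds as shown):

```
f_in  map= 0.033 unc= 1.02% amb= 1.65% degenerate=False
D_in  map= 1.502 unc=24.94% amb=43.37% degenerate=False
D_e   map= 1.995 unc= 0.62% amb= 1.10% degenerate=False
truth: [0.032 2.552 2.001]
```

This voxel is a textbook case for why posteriors beat point estimates:
the generating intra-neurite fraction is 0.032, so the signal carries
almost no information about the stick diffusivity D_in. The posterior
modes for the two identifiable parameters land on the truth with ~1%
uncertainty, while D_in's 25% uncertainty and 43% ambiguity announce
that its MAP (1.50 vs a truth of 2.55) should not be trusted — a
least-squares fit would have returned the same useless number with no
warning. No marginal shows multiple distinct solutions: the Ball&Stick
model is degeneracy-free. Repeating this with `"extended_sandi"`
produces flagged voxels — richer models admit genuinely
indistinguishable parameter combinations, and the flag marks exactly
those.

A thin CLI wraps the same functionality (`dmipost simulate`, `dmipost
train`, `dmipost fit`, `dmipost experiment ...`); see `dmipost --help`.

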