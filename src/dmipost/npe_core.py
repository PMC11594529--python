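"""Amortized neural posterior estimation for microstructure parameters.

Trains the embedding MLP and the masked-autoregressive-flow density
estimator jointly by stochastic minimization of the Monte-Carlo estimate
of E[−log q(θ|x)] over simulated (θ, x) pairs — the sample form of the
KL divergence between the true and the approximated posterior. After
training, the estimator is amortized: per-voxel posteriors only require
conditioning on the observed signal and sampling the flow.

Parameters are mapped to an unbounded internal space by a logit
transform of their prior box (then standardized), which keeps flow mass
inside the box and makes posterior-sample rejection rates negligible;
log-densities include the corresponding Jacobian terms.
"""

from __future__ import annotations

import dataclasses
import pickle
from pathlib import Path

import numpy as np

from .flows import Adam, ConditionalMAF
from .forward_models import MODELS, PriorSpec, add_rician_noise, sample_orientations
from .simulation_engine import TrainingSet

__all__ = [
    "EmbeddingConfig",
    "FlowConfig",
    "TrainConfig",
    "AmortizedPosterior",
    "PPCReport",
    "train",
    "log_density",
    "sample_posterior",
    "posterior_predictive_check",
]


@dataclasses.dataclass
class EmbeddingConfig:
    """Feature-extractor settings: Nf learned features from three hidden
    layers. ``n_features=None`` defaults to the parameter count at train
    time. ``hidden=()`` disables the embedding (the flow conditions on
    the feature vector directly, e.g. for precomputed summary statistics)."""

    n_features: int | None = None
    hidden: tuple[int, ...] = (256, 128, 64)
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.hidden and len(self.hidden) != 3:
            raise ValueError("embedding uses exactly three hidden layers")
        if self.n_features is not None and self.n_features < 1:
            raise ValueError("n_features must be positive")
        if self.activation != "tanh":
            raise ValueError("only the tanh nonlinearity is implemented")


@dataclasses.dataclass
class FlowConfig:
    """Flow settings: stacked autoregressive (MADE) transforms with a
    standard-normal base; input order reversed between transforms."""

    n_transforms: int = 5
    hidden: int = 50

    def __post_init__(self) -> None:
        if self.n_transforms < 1:
            raise ValueError("need at least one transform")


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 128
    val_fraction: float = 0.05
    patience: int = 30
    max_epochs: int = 500
    seed: int = 0
    #: global gradient-norm clip; the conditional densities become very
    #: peaked on noise-free targets and unclipped steps destabilize the
    #: late phase of training
    grad_clip: float | None = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("validation fraction must lie in (0, 1)")


@dataclasses.dataclass
class AmortizedPosterior:
    """Trained embedding + flow with the transforms needed to map between
    natural parameter units and the flow's internal space."""

    net: ConditionalMAF
    param_names: tuple[str, ...]
    bounds: np.ndarray | None  # (p, 2) prior box, or None for unbounded
    z_mean: np.ndarray
    z_std: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    model_name: str
    scheme_hash: str | None
    history: dict
    last_acceptance: float = 1.0

    @property
    def prior(self) -> PriorSpec | None:
        if self.bounds is None:
            return None
        return PriorSpec(self.param_names, self.bounds[:, 0], self.bounds[:, 1])

    # -- parameter-space transforms -----------------------------------------

    def _theta_to_z(self, theta: np.ndarray) -> np.ndarray:
        if self.bounds is None:
            return theta
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        f = (theta - lo) / (hi - lo)
        f = np.clip(f, 1e-12, 1 - 1e-12)
        return np.log(f) - np.log1p(-f)

    def _z_to_theta(self, z: np.ndarray) -> np.ndarray:
        if self.bounds is None:
            return z
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return lo + (hi - lo) / (1.0 + np.exp(-z))

    def _standardize_x(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.x_mean) / self.x_std

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint (weights, configs, transforms)."""
        blob = dataclasses.asdict(self)
        blob["net"] = self.net.state()
        with open(path, "wb") as fh:
            pickle.dump(blob, fh)

    @classmethod
    def load(cls, path: str | Path) -> "AmortizedPosterior":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        blob["net"] = ConditionalMAF.from_state(blob["net"])
        blob["param_names"] = tuple(blob["param_names"])
        return cls(**blob)


def _resolve_bounds(tset: TrainingSet, bounds) -> np.ndarray | None:
    if bounds is not None:
        return np.asarray(bounds, dtype=float)
    if tset.model_name in MODELS:
        prior = MODELS[tset.model_name].prior
        return np.column_stack([prior.lower, prior.upper])
    return None


def train(
    tset: TrainingSet,
    e_cfg: EmbeddingConfig | None = None,
    f_cfg: FlowConfig | None = None,
    t_cfg: TrainConfig | None = None,
    bounds: np.ndarray | None = None,
    param_names: tuple[str, ...] | None = None,
    verbose: bool = False,
) -> AmortizedPosterior:
    """Jointly fit the embedding network and the flow on a training set.

    Minimizes the mean negative conditional log-density over minibatches
    (Adam), holds out a random validation fraction, stops when the
    validation loss has not improved for ``patience`` epochs, and returns
    the weights of the best validation epoch. Loss curves are recorded in
    ``history``.
    """
    e_cfg = e_cfg or EmbeddingConfig()
    f_cfg = f_cfg or FlowConfig()
    t_cfg = t_cfg or TrainConfig()
    if tset.n < 2:
        raise ValueError("training set too small")

    theta = np.asarray(tset.theta, dtype=float)
    x = np.asarray(tset.x, dtype=float)
    p = theta.shape[1]
    box = _resolve_bounds(tset, bounds)
    names = tuple(
        param_names
        or (MODELS[tset.model_name].param_names if tset.model_name in MODELS
            else tuple(f"theta_{i}" for i in range(p)))
    )

    ss = np.random.SeedSequence(t_cfg.seed)
    rng_init, rng_split, rng_shuffle = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    n_features = e_cfg.n_features or p
    net = ConditionalMAF(
        dim=p, x_dim=x.shape[1], n_features=n_features,
        embed_hidden=e_cfg.hidden, n_transforms=f_cfg.n_transforms,
        flow_hidden=f_cfg.hidden, rng=rng_init,
    )

    # internal coordinates: logit of the prior box, then standardized
    ap = AmortizedPosterior(
        net=net, param_names=names, bounds=box,
        z_mean=np.zeros(p), z_std=np.ones(p),
        x_mean=np.zeros(x.shape[1]), x_std=np.ones(x.shape[1]),
        model_name=tset.model_name,
        scheme_hash=tset.scheme.content_hash() if tset.scheme is not None else None,
        history={"train_loss": [], "val_loss": []},
    )
    z = ap._theta_to_z(theta)
    ap.z_mean = z.mean(axis=0)
    ap.z_std = np.maximum(z.std(axis=0), 1e-8)
    ap.x_mean = x.mean(axis=0)
    ap.x_std = np.maximum(x.std(axis=0), 1e-8)
    zs = ((z - ap.z_mean) / ap.z_std).astype(np.float32)
    xs = ((x - ap.x_mean) / ap.x_std).astype(np.float32)

    n_val = max(1, int(round(t_cfg.val_fraction * tset.n)))
    order = rng_split.permutation(tset.n)
    val_idx, trn_idx = order[:n_val], order[n_val:]
    z_val, x_val = zs[val_idx], xs[val_idx]
    z_trn, x_trn = zs[trn_idx], xs[trn_idx]

    opt = Adam(net.n_parameters, lr=t_cfg.learning_rate)
    best_val = np.inf
    best_params = net.copy_params()
    best_epoch = -1
    bad_epochs = 0
    B = t_cfg.batch_size

    def val_loss() -> float:
        out = 0.0
        for i in range(0, z_val.shape[0], 4096):
            lp = net.log_prob(z_val[i:i + 4096], x_val[i:i + 4096])
            out += float(-lp.sum())
        return out / z_val.shape[0]

    for epoch in range(t_cfg.max_epochs):
        perm = rng_shuffle.permutation(z_trn.shape[0])
        epoch_loss = 0.0
        for bi, start in enumerate(range(0, perm.size, B)):
            idx = perm[start:start + B]
            loss, grads = net.loss_and_grads(z_trn[idx], x_trn[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {bi}"
                )
            if t_cfg.grad_clip is not None:
                gn = float(np.linalg.norm(grads))
                if gn > t_cfg.grad_clip:
                    grads = grads * (t_cfg.grad_clip / gn)
            opt.step(net.flat_params, grads)
            epoch_loss += loss * idx.size
        epoch_loss /= perm.size
        vl = val_loss()
        ap.history["train_loss"].append(epoch_loss)
        ap.history["val_loss"].append(vl)
        if verbose:
            print(f"epoch {epoch:4d}  train {epoch_loss:9.4f}  val {vl:9.4f}")
        if vl < best_val - 1e-6:
            best_val = vl
            best_params = net.copy_params()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= t_cfg.patience:
                break
    net.set_params(best_params)
    ap.history["best_epoch"] = best_epoch
    ap.history["best_val_loss"] = best_val
    return ap


def log_density(ap: AmortizedPosterior, theta: np.ndarray, x: np.ndarray):
    """Exact log posterior density (nats) of ``theta`` given signal ``x``.

    Includes the change-of-variables terms of the internal logit and
    standardization transforms. Returns −inf on or outside the prior box.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    xs = ap._standardize_x(x)
    if xs.shape[0] == 1 and theta.shape[0] > 1:
        xs = np.broadcast_to(xs, (theta.shape[0], xs.shape[1]))
    out = np.full(theta.shape[0], -np.inf)
    if ap.bounds is None:
        inside = np.ones(theta.shape[0], dtype=bool)
        jac = np.zeros(theta.shape[0])
        z = theta
    else:
        lo, hi = ap.bounds[:, 0], ap.bounds[:, 1]
        inside = np.all((theta > lo) & (theta < hi), axis=1)
        z = ap._theta_to_z(theta[inside])
        # dz/dθ = (hi−lo) / ((θ−lo)(hi−θ))
        t = theta[inside]
        jac = np.sum(
            np.log(hi - lo) - np.log(t - lo) - np.log(hi - t), axis=1
        )
    if inside.any():
        zstd = (z - ap.z_mean) / ap.z_std
        lp = ap.net.log_prob(zstd, xs[inside])
        out[inside] = lp - np.sum(np.log(ap.z_std)) + jac
    return out if out.size > 1 else float(out[0])


def sample_posterior(
    ap: AmortizedPosterior,
    x: np.ndarray,
    n: int,
    rng: np.random.Generator,
    max_tries: int = 20,
) -> np.ndarray:
    """Draw ``n`` posterior samples for one observed signal by rejection:
    flow draws falling outside the prior box are redrawn. The acceptance
    fraction is stored on ``ap.last_acceptance``."""
    if n < 1:
        raise ValueError("n must be positive")
    xs = ap._standardize_x(x)[0]
    kept: list[np.ndarray] = []
    n_drawn = 0
    n_accept = 0
    need = n
    for _ in range(max_tries):
        z = ap.net.sample(xs, need, rng)
        theta = ap._z_to_theta(z * ap.z_std + ap.z_mean)
        ok = np.all(np.isfinite(theta), axis=1)
        if ap.bounds is not None:
            lo, hi = ap.bounds[:, 0], ap.bounds[:, 1]
            ok &= np.all((theta >= lo) & (theta <= hi), axis=1)
        n_drawn += need
        n_accept += int(ok.sum())
        kept.append(theta[ok])
        got = sum(k.shape[0] for k in kept)
        if got >= n:
            break
        frac = max(n_accept / n_drawn, 1e-6)
        if n_drawn >= 1000 and frac < 1e-3:
            raise RuntimeError(
                "posterior acceptance fraction below 1e-3; the flow has "
                "placed its mass outside the prior box — retrain"
            )
        need = int(np.ceil((n - got) / frac))
    samples = np.concatenate(kept)[:n]
    if samples.shape[0] < n:
        raise RuntimeError("could not draw the requested number of samples")
    ap.last_acceptance = n_accept / n_drawn
    return samples


@dataclasses.dataclass
class PPCReport:
    """Posterior predictive check: per-measurement central-interval
    coverage of an observed signal."""

    coverage: float
    inside: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def posterior_predictive_check(
    ap: AmortizedPosterior,
    x_obs: np.ndarray,
    model,
    scheme,
    n_draws: int,
    rng: np.random.Generator,
    snr: float | None = None,
    interval: float = 0.95,
) -> PPCReport:
    """Regenerate signals from posterior draws and report the fraction of
    observed diffusion-weighted measurements inside the central
    ``interval`` predictive band (orientations are redrawn uniformly, as
    in training)."""
    theta = sample_posterior(ap, x_obs, n_draws, rng)
    dirs = sample_orientations(n_draws, rng)
    sig = model.signal(theta, dirs, scheme)
    if snr is not None and np.isfinite(snr):
        sig = add_rician_noise(sig, snr, rng)
        b0 = sig[:, scheme.b0_mask].mean(axis=1)
        pred = sig[:, scheme.dw_mask] / b0[:, None]
    else:
        pred = sig[:, scheme.dw_mask]
    alpha = (1.0 - interval) / 2.0
    lower = np.quantile(pred, alpha, axis=0)
    upper = np.quantile(pred, 1.0 - alpha, axis=0)
    x_obs = np.asarray(x_obs, dtype=float).ravel()
    inside = (x_obs >= lower) & (x_obs <= upper)
    return PPCReport(float(inside.mean()), inside, lower, upper)
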