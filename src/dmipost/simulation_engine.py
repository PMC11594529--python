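"""Synthetic training/validation/test data for amortized inference.

Training sets pair prior parameter draws Θ with b0-normalized signal (or
feature) vectors X. Orientations are a marginalized nuisance: each
simulated voxel receives a random tissue orientation, so an estimator
trained on the raw signal learns rotation-marginal posteriors of the
scalar tissue parameters.

Generation is chunked with a per-chunk seed derivation (SeedSequence
spawned on the chunk index), so the first rows of a large set coincide
with a smaller set generated from the same seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .forward_models import ModelSpec, add_rician_noise, get_model, sample_orientations
from .protocol_io import AcquisitionScheme

__all__ = [
    "TrainingSet",
    "generate_training_set",
    "direction_average",
    "rotational_invariants",
    "manual_summary_statistics",
]

_CHUNK = 10_000


@dataclasses.dataclass
class TrainingSet:
    """Paired parameter draws and signal/feature vectors.

    ``theta`` is (n, p) in natural units; ``x`` is (n, d). ``snr`` is the
    Rician signal-to-noise ratio on the b0-normalized scale (None means
    noise-free). ``dirs`` keeps the nuisance orientations used.
    """

    theta: np.ndarray
    x: np.ndarray
    model_name: str
    scheme: AcquisitionScheme
    snr: float | None
    seed: int
    dirs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.theta.shape[0] != self.x.shape[0]:
            raise ValueError("theta and x must have matching row counts")

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    def save(self, prefix: str | Path) -> None:
        """Persist as <prefix>.npz plus a JSON sidecar."""
        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"), theta=self.theta, x=self.x)
        meta = {
            "model": self.model_name,
            "scheme_hash": self.scheme.content_hash(),
            "snr": self.snr,
            "seed": self.seed,
            "n": int(self.n),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    def export_theta_csv(self, path: str | Path) -> None:
        """Parameter matrix as CSV with a header row of parameter names."""
        from .forward_models import MODELS

        if self.model_name in MODELS:
            header = ",".join(MODELS[self.model_name].param_names)
        else:
            header = ",".join(f"theta_{i}" for i in range(self.theta.shape[1]))
        np.savetxt(path, self.theta, delimiter=",", header=header, comments="")


def _simulate_chunk(
    model: ModelSpec,
    scheme: AcquisitionScheme,
    n: int,
    snr: float | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = model.sample_prior(n, rng)
    dirs = sample_orientations(n, rng)
    sig = model.signal(theta, dirs, scheme)  # (n, m) incl. b=0 columns
    if snr is not None and np.isfinite(snr):
        sig = add_rician_noise(sig, snr, rng)
        # renormalize by the mean noisy b=0 signal, as for measured data
        b0 = sig[:, scheme.b0_mask].mean(axis=1)
        x = sig[:, scheme.dw_mask] / b0[:, None]
    else:
        x = sig[:, scheme.dw_mask]
    return theta, x, dirs


def generate_training_set(
    model: ModelSpec | str,
    scheme: AcquisitionScheme,
    n: int,
    snr: float | None,
    seed: int,
    keep_dirs: bool = False,
) -> TrainingSet:
    """Simulate ``n`` (θ, x) pairs from the prior and forward model.

    ``x`` holds the diffusion-weighted, b0-normalized values (Rician noise
    at ``snr`` applied to all measurements before normalization when given).
    Deterministic in ``seed``; generated in chunks of 10,000 whose seeds
    derive from (seed, chunk index).
    """
    if n < 1:
        raise ValueError("n must be positive")
    if isinstance(model, str):
        model = get_model(model)
    thetas, xs, ds = [], [], []
    for c, start in enumerate(range(0, n, _CHUNK)):
        m = min(_CHUNK, n - start)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(c,)))
        theta, x, dirs = _simulate_chunk(model, scheme, m, snr, rng)
        thetas.append(theta)
        xs.append(x.astype(np.float32))
        if keep_dirs:
            ds.append(dirs)
    return TrainingSet(
        theta=np.concatenate(thetas),
        x=np.concatenate(xs),
        model_name=model.name,
        scheme=scheme,
        snr=snr,
        seed=seed,
        dirs=np.concatenate(ds) if keep_dirs else None,
    )


def _dw_view(x: np.ndarray, scheme: AcquisitionScheme) -> tuple[np.ndarray, np.ndarray]:
    """Accept full-length (m) or diffusion-weighted-only vectors; return the
    DW values and the matching shell labels."""
    x = np.asarray(x, dtype=float)
    flat = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] == scheme.m:
        vals = x[:, scheme.dw_mask]
    elif x.shape[1] == scheme.n_dw:
        vals = x
    else:
        raise ValueError(
            f"expected {scheme.m} or {scheme.n_dw} values per voxel, got {x.shape[1]}"
        )
    labels = scheme.shell_index[scheme.dw_mask]
    return (vals[0] if flat else vals), labels


def direction_average(x: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Arithmetic mean over directions within each nonzero shell, ordered by
    ascending b (the powder average; 6 values for the default scheme)."""
    vals, labels = _dw_view(x, scheme)
    vals2 = np.atleast_2d(vals)
    out = np.column_stack(
        [vals2[:, labels == lab].mean(axis=1) for lab in np.unique(labels)]
    )
    return out[0] if np.asarray(x).ndim == 1 else out


def _real_sh_basis(dirs: np.ndarray, l_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Real symmetric spherical-harmonic design matrix for unit vectors."""
    from scipy.special import sph_harm_y

    theta = np.arccos(np.clip(dirs[:, 2], -1, 1))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    cols, orders = [], []
    for l in range(0, l_max + 1, 2):
        for mm in range(-l, l + 1):
            Y = sph_harm_y(l, abs(mm), theta, phi)
            if mm < 0:
                cols.append(np.sqrt(2) * Y.imag)
            elif mm == 0:
                cols.append(Y.real)
            else:
                cols.append(np.sqrt(2) * Y.real)
            orders.append(l)
    return np.column_stack(cols), np.asarray(orders)


def rotational_invariants(
    x: np.ndarray, scheme: AcquisitionScheme, l_max: int = 4
) -> np.ndarray:
    """Per-shell rotation-invariant spherical-harmonic power features.

    For each nonzero shell the signal is least-squares fitted with real
    even spherical harmonics up to ``l_max`` and reduced to one invariant
    per order, S_l = sqrt(Σ_m c_lm² / (4π(2l+1))); with this
    normalization S_0 equals the direction average. Output is
    shells × orders, flattened shell-major.
    """
    if l_max % 2 or l_max < 0:
        raise ValueError("l_max must be even and non-negative")
    vals, labels = _dw_view(x, scheme)
    flat = np.asarray(vals).ndim == 1
    vals2 = np.atleast_2d(vals)
    dirs_dw = scheme.directions[scheme.dw_mask]
    feats = []
    for lab in np.unique(labels):
        mask = labels == lab
        lm = min(l_max, 4 if mask.sum() >= 15 else 2)
        B, orders = _real_sh_basis(dirs_dw[mask], lm)
        coef, *_ = np.linalg.lstsq(B, vals2[:, mask].T, rcond=None)
        row = []
        for l in range(0, l_max + 1, 2):
            sel = orders == l
            if sel.any():
                power = np.sum(coef[sel] ** 2, axis=0)
                row.append(np.sqrt(power / (4 * np.pi * (2 * l + 1))))
            else:
                row.append(np.zeros(vals2.shape[0]))
        feats.append(np.stack(row, axis=1))
    out = np.concatenate(feats, axis=1)
    return out[0] if flat else out


def manual_summary_statistics(
    x: np.ndarray, scheme: AcquisitionScheme, model: ModelSpec | str
) -> np.ndarray:
    """Hand-crafted summary statistics, where a published definition exists.

    For the Ball&Stick model these are the per-shell direction averages
    (six values for the default protocol). The cumulant (LEMONADE) system
    for the standard model and the high/low-b expansion statistics for
    extended-SANDI are not implemented here.
    """
    name = model if isinstance(model, str) else model.name
    if name == "ball_stick":
        return direction_average(x, scheme)
    ref = {
        "standard_model": "the LEMONADE cumulant system",
        "extended_sandi": "the high/low-b expansion statistics",
    }.get(name, "a published summary-statistic set")
    raise NotImplementedError(
        f"manual summary statistics for {name!r} would require {ref}, "
        "which is not implemented; use the learned-feature pathway instead"
    )
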