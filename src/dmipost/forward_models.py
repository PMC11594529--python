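"""Biophysical forward models of the multi-shell diffusion-MRI signal.

Three models of increasing complexity are provided, each mapping tissue
parameters to a noise-free attenuation vector for an acquisition scheme:

* ``ball_stick`` — intra-neurite sticks (zero-radius cylinders, diffusivity
  D_in) plus isotropic extra-neurite Gaussian diffusion (D_e), weighted by
  the intra-neurite signal fraction f_in.
* ``standard_model`` — Watson-dispersed sticks (fraction f, diffusivity
  D_a, orientation dispersion index ODI) plus an axially symmetric Gaussian
  (zeppelin) extra-neurite compartment with D_e∥ ≥ D_e⊥, convolved with the
  same Watson distribution.
* ``extended_sandi`` — Watson-dispersed sticks (f_n, D_n, ODI), restricted
  diffusion in spheres (somas; fraction f_s, proxy coefficient C_s in µm²),
  and isotropic extra-cellular Gaussian diffusion (f_e = 1−f_n−f_s, D_e).

Unit conventions: b-values enter in s·mm⁻² and are converted internally to
ms·µm⁻² (1000 s·mm⁻² = 1 ms·µm⁻²); diffusivities are in µm²/ms; δ and Δ in
ms. All noise-free attenuations lie in (0, 1] with b=0 evaluating to 1.

The Watson spherical convolution is computed with a deterministic spectral
method: both the Watson density and the axially symmetric single-fibre
kernels exp(−c·t²) are expanded in even Legendre polynomials with
Gauss–Legendre quadrature for the coefficient integrals, and the convolved
attenuation follows from the Funk–Hecke theorem as a short Legendre series
in the angle between gradient and mean orientation.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, eval_legendre, jv

from .protocol_io import AcquisitionScheme

__all__ = [
    "BallStickParams",
    "StandardModelParams",
    "SandiParams",
    "PriorSpec",
    "ModelSpec",
    "MODELS",
    "get_model",
    "stick_attenuation",
    "ball_attenuation",
    "zeppelin_attenuation",
    "watson_convolved_stick",
    "odi_to_kappa",
    "sphere_Cs",
    "sphere_bessel_roots",
    "ball_stick_signal",
    "standard_model_signal",
    "sandi_signal",
    "sample_sm_diffusivities",
    "sample_simplex_fractions",
    "sample_orientations",
    "add_rician_noise",
    "powder_average_stick",
]

_B_UNIT = 1e-3  # s·mm⁻² → ms·µm⁻²
_L_EVEN = np.arange(0, 42, 2)  # Legendre orders for the Watson convolution
_DEFAULT_QUAD = 100
_MIN_QUAD = 16


# ---------------------------------------------------------------------------
# parameter containers and priors
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PriorSpec:
    """Uniform prior box over named parameters (natural units)."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (len(self.names) == self.lower.size == self.upper.size):
            raise ValueError("prior fields must share length")
        if np.any(self.lower >= self.upper):
            raise ValueError("prior lower bounds must be below upper bounds")

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return np.all((theta >= self.lower) & (theta <= self.upper), axis=1)


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValueError(f"{name} must be a unit vector")
    return v


@dataclasses.dataclass
class BallStickParams:
    f_in: float
    D_in: float
    D_e: float
    stick_dir: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_in <= 1.0:
            raise ValueError("f_in must lie in [0, 1]")
        for d in (self.D_in, self.D_e):
            if not 0.1 <= d <= 3.0:
                raise ValueError("diffusivities must lie in [0.1, 3] µm²/ms")
        self.stick_dir = _check_unit(self.stick_dir, "stick_dir")


@dataclasses.dataclass
class StandardModelParams:
    f: float
    D_a: float
    odi: float
    D_e_par: float
    D_e_perp: float
    mean_dir: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if not 0.03 <= self.odi <= 0.95:
            raise ValueError("ODI must lie in [0.03, 0.95]")
        if not 0.1 <= self.D_e_perp <= self.D_e_par <= 3.0:
            raise ValueError("need 0.1 ≤ D_e_perp ≤ D_e_par ≤ 3")
        if not 0.1 <= self.D_a <= 3.0:
            raise ValueError("D_a must lie in [0.1, 3] µm²/ms")
        self.mean_dir = _check_unit(self.mean_dir, "mean_dir")


@dataclasses.dataclass
class SandiParams:
    f_n: float
    f_s: float
    f_e: float
    D_n: float
    odi: float
    D_e: float
    C_s: float
    mean_dir: np.ndarray

    def __post_init__(self) -> None:
        fr = np.array([self.f_n, self.f_s, self.f_e])
        if np.any(fr < -1e-12) or np.any(fr > 1 + 1e-12):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if not 0.15 <= self.C_s <= 1105.0:
            raise ValueError("C_s must lie in [0.15, 1105] µm²")
        for d in (self.D_n, self.D_e):
            if not 0.1 <= d <= 3.0:
                raise ValueError("diffusivities must lie in [0.1, 3] µm²/ms")
        if not 0.03 <= self.odi <= 0.95:
            raise ValueError("ODI must lie in [0.03, 0.95]")
        self.mean_dir = _check_unit(self.mean_dir, "mean_dir")


# ---------------------------------------------------------------------------
# elementary compartment attenuations
# ---------------------------------------------------------------------------


def stick_attenuation(b, g, n, D):
    """exp(−b·D·(g·n)²) for a zero-radius cylinder along ``n``.

    ``b`` in s·mm⁻², ``D`` in µm²/ms, ``g``/``n`` unit 3-vectors.
    """
    g = np.asarray(g, dtype=float)
    n = np.asarray(n, dtype=float)
    proj = np.sum(g * n, axis=-1)
    return np.exp(-np.asarray(b) * _B_UNIT * D * proj**2)


def ball_attenuation(b, D):
    """Isotropic Gaussian attenuation exp(−b·D)."""
    return np.exp(-np.asarray(b) * _B_UNIT * D)


def zeppelin_attenuation(b, g, mean_dir, D_par, D_perp):
    """Axially symmetric Gaussian attenuation.

    exp(−b·(D_perp + (D_par − D_perp)(g·mean_dir)²)), with D_perp ≤ D_par.
    """
    if np.any(np.asarray(D_perp) > np.asarray(D_par) + 1e-12):
        raise ValueError("zeppelin requires D_perp ≤ D_par")
    g = np.asarray(g, dtype=float)
    u = np.asarray(mean_dir, dtype=float)
    proj2 = np.sum(g * u, axis=-1) ** 2
    return np.exp(-np.asarray(b) * _B_UNIT * (D_perp + (D_par - D_perp) * proj2))


def powder_average_stick(b, D):
    """Closed-form direction average of a stick: √(π/(4bD))·erf(√(bD)).

    ``b`` in s·mm⁻². Returns 1 where b·D = 0.
    """
    bd = np.asarray(b, dtype=float) * _B_UNIT * D
    bd = np.atleast_1d(bd)
    out = np.ones_like(bd)
    nz = bd > 0
    out[nz] = np.sqrt(np.pi / (4 * bd[nz])) * erf(np.sqrt(bd[nz]))
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Watson orientation dispersion (spectral convolution)
# ---------------------------------------------------------------------------


def odi_to_kappa(odi):
    """NODDI convention κ = 1/tan(ODI·π/2); ODI→0 is no dispersion."""
    return 1.0 / np.tan(np.asarray(odi, dtype=float) * np.pi / 2.0)


@lru_cache(maxsize=8)
def _quad_tables(order: int):
    t, w = np.polynomial.legendre.leggauss(order)
    P = np.stack([eval_legendre(l, t) for l in _L_EVEN])  # (L, order)
    return t, w, P


def _watson_weights(kappa: np.ndarray, order: int) -> np.ndarray:
    """Per-row Legendre weights w_l = (2l+1)·I_l / (2·I_0) of the Watson
    density about its mean axis, I_l = ∫ exp(κt²) P_l(t) dt."""
    t, w, P = _quad_tables(order)
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    # subtract max exponent per row for overflow safety at high κ
    expo = kappa[:, None] * t[None, :] ** 2
    expo -= expo.max(axis=1, keepdims=True)
    E = np.exp(expo) * w[None, :]
    I = E @ P.T  # (n, L)
    return (2 * _L_EVEN + 1) * I / (2.0 * I[:, :1])


def _kernel_coeffs(c: np.ndarray, order: int) -> np.ndarray:
    """J_l(c) = ∫ exp(−c·t²) P_l(t) dt for an array of exponents c ≥ 0."""
    t, w, P = _quad_tables(order)
    c = np.asarray(c, dtype=float)
    E = np.exp(-c[..., None] * t**2) * w
    return E @ P.T  # (..., L)


def watson_convolved_stick(b, g, mean_dir, D, odi, quadrature_order: int = _DEFAULT_QUAD):
    """Stick attenuation convolved with a Watson orientation distribution.

    Evaluates Σ_l w_l(κ)·J_l(bD)·P_l(cos ψ) over even l, where ψ is the
    angle between the gradient ``g`` and the Watson mean axis. ``b`` in
    s·mm⁻². Result lies in (0, 1].
    """
    if quadrature_order < _MIN_QUAD:
        raise ValueError(f"quadrature order must be ≥ {_MIN_QUAD}")
    if not 0.0 < odi < 1.0:
        raise ValueError("ODI must lie in (0, 1)")
    g = np.atleast_2d(np.asarray(g, dtype=float))
    u = _check_unit(mean_dir, "mean_dir")
    b = np.broadcast_to(np.asarray(b, dtype=float), (g.shape[0],))
    wl = _watson_weights(odi_to_kappa(odi), quadrature_order)[0]  # (L,)
    J = _kernel_coeffs(b * _B_UNIT * D, quadrature_order)  # (m, L)
    cpsi = g @ u
    A = np.zeros(g.shape[0])
    for k, l in enumerate(_L_EVEN):
        A += wl[k] * J[:, k] * eval_legendre(l, cpsi)
    A = np.clip(A, 1e-12, None)
    return A if A.size > 1 else float(A[0])


# ---------------------------------------------------------------------------
# restricted diffusion in spheres
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4)
def sphere_bessel_roots(n_roots: int = 50) -> np.ndarray:
    """First ``n_roots`` positive roots x_m of x⁻¹·J_{3/2}(x) = J_{5/2}(x).

    These are the dimensionless eigenvalues of diffusion restricted in a
    sphere (x = α·r_s); the first is ≈ 2.0816.
    """

    def f(x):
        return jv(1.5, x) / x - jv(2.5, x)

    roots = []
    xs = np.arange(1.0, (n_roots + 3) * np.pi, 0.02)
    vals = f(xs)
    sign_change = np.where(np.diff(np.signbit(vals)))[0]
    for i in sign_change:
        try:
            r = brentq(f, xs[i], xs[i + 1], xtol=1e-12)
        except ValueError as exc:  # pragma: no cover - bracketing is robust
            raise RuntimeError(f"root {len(roots) + 1} did not converge") from exc
        roots.append(r)
        if len(roots) == n_roots:
            break
    if len(roots) < n_roots:  # pragma: no cover
        raise RuntimeError(f"only found {len(roots)} of {n_roots} roots")
    return np.asarray(roots)


def sphere_Cs(r_s: float, D_s: float, delta_small: float, delta_big: float,
              n_roots: int = 50) -> float:
    """Sphere-restriction proxy coefficient C_s in µm².

    Gaussian-phase-distribution (Murday–Cotts) attenuation coefficient of
    diffusion restricted in a sphere of radius ``r_s`` (µm) with intrinsic
    diffusivity ``D_s`` (µm²/ms), for pulsed gradients of duration δ and
    separation Δ (ms), per squared diffusion wavevector expressed in
    cycles (q = γgδ/2π), so the powder sphere attenuation is
    exp(−q²·C_s) with q² = b / (4π²·(Δ − δ/3)). Monotone increasing in
    r_s; C_s(15 µm, 3 µm²/ms, 7 ms, 24 ms) ≈ 1105 µm².
    """
    if r_s <= 0 or D_s <= 0:
        raise ValueError("r_s and D_s must be positive")
    if not delta_small < delta_big:
        raise ValueError("gradient duration must be below separation")
    if n_roots < 10:
        raise ValueError("need at least 10 roots")
    alpha = sphere_bessel_roots(n_roots) / r_s  # 1/µm
    a2D = alpha**2 * D_s  # 1/ms
    d, D = delta_small, delta_big
    time_term = 2 * d - (
        2.0
        + np.exp(-a2D * (D - d))
        - 2.0 * np.exp(-a2D * d)
        - 2.0 * np.exp(-a2D * D)
        + np.exp(-a2D * (D + d))
    ) / a2D
    terms = alpha ** (-4) / (alpha**2 * r_s**2 - 2.0) * time_term
    return float(8.0 * np.pi**2 / (D_s * d**2) * np.sum(terms))


def _sphere_attenuation(b, C_s, delta_small, delta_big):
    """exp(−q²·C_s) with q² = b / (4π²·(Δ − δ/3)) in cycles²·µm⁻²,
    matching the wavevector convention of :func:`sphere_Cs`."""
    q2 = np.asarray(b, dtype=float) * _B_UNIT / (
        4.0 * np.pi**2 * (delta_big - delta_small / 3.0)
    )
    return np.exp(-q2 * np.asarray(C_s))


# ---------------------------------------------------------------------------
# batched signal generators
# ---------------------------------------------------------------------------


def _shell_pos(scheme: AcquisitionScheme) -> tuple[np.ndarray, np.ndarray]:
    """Unique shell b-values (incl. b=0) and per-measurement positions."""
    labels, pos = np.unique(scheme.shell_index, return_inverse=True)
    b_shell = np.array([scheme.b_values[scheme.shell_index == s].mean()
                        for s in labels])
    return b_shell, pos


def _watson_pair_batch(
    scheme: AcquisitionScheme,
    dirs: np.ndarray,
    kappa: np.ndarray,
    c_stick: np.ndarray,
    c_zep: np.ndarray | None,
    order: int = _DEFAULT_QUAD,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Watson-convolved attenuations for stick (and optionally zeppelin
    anisotropic part) kernels, batched over voxels.

    ``c_stick``/``c_zep`` are per-voxel exponent scales in ms·µm⁻²·µm²/ms
    (i.e. the attenuation kernels are exp(−c·b̃·t²) with b̃ per shell).
    """
    n = dirs.shape[0]
    b_shell, pos = _shell_pos(scheme)
    bt = b_shell * _B_UNIT  # (S,)
    wl = _watson_weights(kappa, order)  # (n, L)
    J1 = _kernel_coeffs(c_stick[:, None] * bt[None, :], order)  # (n, S, L)
    J2 = _kernel_coeffs(c_zep[:, None] * bt[None, :], order) if c_zep is not None else None
    cpsi = dirs @ scheme.directions.T  # (n, m)
    A1 = np.zeros((n, scheme.m))
    A2 = np.zeros((n, scheme.m)) if c_zep is not None else None
    for k, l in enumerate(_L_EVEN):
        Pl = eval_legendre(l, cpsi)
        A1 += (wl[:, k : k + 1] * J1[:, pos, k]) * Pl
        if A2 is not None:
            A2 += (wl[:, k : k + 1] * J2[:, pos, k]) * Pl
    np.clip(A1, 1e-12, None, out=A1)
    if A2 is not None:
        np.clip(A2, 1e-12, None, out=A2)
    return A1, A2


def _ball_stick_batch(theta: np.ndarray, dirs: np.ndarray,
                      scheme: AcquisitionScheme) -> np.ndarray:
    f, Din, De = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3]
    bt = scheme.b_ms_um2[None, :]
    proj2 = (dirs @ scheme.directions.T) ** 2
    stick = np.exp(-bt * Din * proj2)
    ball = np.exp(-bt * De)
    return f * stick + (1 - f) * ball


def _standard_model_batch(theta: np.ndarray, dirs: np.ndarray,
                          scheme: AcquisitionScheme,
                          convolve_extra: bool = True) -> np.ndarray:
    f, Da, odi, Dpar, Dperp = (theta[:, i] for i in range(5))
    kappa = odi_to_kappa(odi)
    A_stick, A_zep_aniso = _watson_pair_batch(
        scheme, dirs, kappa, Da, (Dpar - Dperp) if convolve_extra else None
    )
    bt = scheme.b_ms_um2[None, :]
    if convolve_extra:
        A_zep = np.exp(-bt * Dperp[:, None]) * A_zep_aniso
    else:
        proj2 = (dirs @ scheme.directions.T) ** 2
        A_zep = np.exp(-bt * (Dperp[:, None] + (Dpar - Dperp)[:, None] * proj2))
    return f[:, None] * A_stick + (1 - f)[:, None] * A_zep


def _sandi_batch(theta: np.ndarray, dirs: np.ndarray,
                 scheme: AcquisitionScheme) -> np.ndarray:
    fn, fs, Dn, De, Cs, odi = (theta[:, i] for i in range(6))
    fe = 1.0 - fn - fs
    A_stick, _ = _watson_pair_batch(scheme, dirs, odi_to_kappa(odi), Dn, None)
    bt = scheme.b_ms_um2[None, :]
    A_sphere = _sphere_attenuation(
        scheme.b_values[None, :], Cs[:, None], scheme.delta_small, scheme.delta_big
    )
    A_ball = np.exp(-bt * De[:, None])
    return fn[:, None] * A_stick + fs[:, None] * A_sphere + fe[:, None] * A_ball


def ball_stick_signal(params: BallStickParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free signal vector (one entry per measurement, b=0 gives 1)."""
    theta = np.array([[params.f_in, params.D_in, params.D_e]])
    return _ball_stick_batch(theta, params.stick_dir[None, :], scheme)[0]


def standard_model_signal(params: StandardModelParams, scheme: AcquisitionScheme,
                          convolve_extra: bool = True) -> np.ndarray:
    """Noise-free Watson-dispersed stick + zeppelin signal vector.

    By default the extra-neurite zeppelin is convolved with the same Watson
    distribution as the sticks; ``convolve_extra=False`` keeps it aligned
    with the mean orientation instead.
    """
    theta = np.array([[params.f, params.D_a, params.odi,
                       params.D_e_par, params.D_e_perp]])
    return _standard_model_batch(theta, params.mean_dir[None, :], scheme,
                                 convolve_extra=convolve_extra)[0]


def sandi_signal(params: SandiParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free three-compartment (sticks + spheres + ball) signal vector."""
    theta = np.array([[params.f_n, params.f_s, params.D_n,
                       params.D_e, params.C_s, params.odi]])
    return _sandi_batch(theta, params.mean_dir[None, :], scheme)[0]


# ---------------------------------------------------------------------------
# constrained prior samplers
# ---------------------------------------------------------------------------


def sample_sm_diffusivities(u0, u1, sqrt_u0: bool = True):
    """Map unit-square variates to extra-neurite (D_e∥, D_e⊥) with D_e⊥ ≤ D_e∥.

    With ``sqrt_u0`` (default) D_e∥ = 0.1 + 2.9·√u0, which makes the pair
    uniform on the triangle {0.1 ≤ D_e⊥ ≤ D_e∥ ≤ 3}; ``sqrt_u0=False``
    applies the linear reading D_e∥ = 0.1 + 2.9·u0 instead.
    """
    u0 = np.asarray(u0, dtype=float)
    u1 = np.asarray(u1, dtype=float)
    t = np.sqrt(u0) if sqrt_u0 else u0
    D_par = 0.1 + (3.0 - 0.1) * t
    D_perp = 0.1 + (D_par - 0.1) * u1
    return D_par, D_perp


def sample_simplex_fractions(k1, k2):
    """Map unit-square variates to (f_n, f_s, f_e) on the unit simplex:
    f_n = k2·k1, f_s = (1−k2)·k1, f_e = 1−k1."""
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    return k2 * k1, (1 - k2) * k1, 1 - k1


def sample_orientations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n directions uniform on the unit sphere."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def add_rician_noise(signal: np.ndarray, snr: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the signal with Gaussian noise (σ = 1/snr on the
    b0-normalized scale) on the real and imaginary channels."""
    if not snr > 0:
        raise ValueError("snr must be positive")
    signal = np.asarray(signal, dtype=float)
    if not np.isfinite(snr):
        return signal.copy()
    sigma = 1.0 / snr
    eps_r = rng.normal(0.0, sigma, size=signal.shape)
    eps_i = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + eps_r) ** 2 + eps_i**2)


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ModelSpec:
    """A forward model: named parameters, prior box + constraint sampler,
    batched signal generator, and constraint predicate.

    The inferred parameter vector excludes the tissue orientation, which is
    a nuisance marginalized by randomizing it in the training simulations.
    """

    name: str
    prior: PriorSpec
    sample_prior_fn: Callable[[int, np.random.Generator], np.ndarray]
    signal_fn: Callable[[np.ndarray, np.ndarray, AcquisitionScheme], np.ndarray]
    constraint_fn: Callable[[np.ndarray], np.ndarray] | None = None

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.prior.names

    @property
    def n_params(self) -> int:
        return len(self.prior.names)

    def sample_prior(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n parameter rows honouring the prior box and constraints."""
        return self.sample_prior_fn(n, rng)

    def signal(self, theta: np.ndarray, dirs: np.ndarray,
               scheme: AcquisitionScheme, chunk: int = 4096) -> np.ndarray:
        """Noise-free signals (n, m) for parameter rows and orientations."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        out = np.empty((theta.shape[0], scheme.m))
        for i in range(0, theta.shape[0], chunk):
            sl = slice(i, i + chunk)
            out[sl] = self.signal_fn(theta[sl], dirs[sl], scheme)
        return out

    def satisfies_constraints(self, theta: np.ndarray) -> np.ndarray:
        ok = self.prior.contains(theta)
        if self.constraint_fn is not None:
            ok &= self.constraint_fn(np.atleast_2d(theta))
        return ok


def _bs_prior(n: int, rng: np.random.Generator) -> np.ndarray:
    return np.column_stack([
        rng.uniform(0, 1, n),
        rng.uniform(0.1, 3, n),
        rng.uniform(0.1, 3, n),
    ])


def _sm_prior(n: int, rng: np.random.Generator) -> np.ndarray:
    Dpar, Dperp = sample_sm_diffusivities(rng.uniform(0, 1, n), rng.uniform(0, 1, n))
    return np.column_stack([
        rng.uniform(0, 1, n),
        rng.uniform(0.1, 3, n),
        rng.uniform(0.03, 0.95, n),
        Dpar,
        Dperp,
    ])


def _sandi_prior(n: int, rng: np.random.Generator) -> np.ndarray:
    fn, fs, _fe = sample_simplex_fractions(rng.uniform(0, 1, n), rng.uniform(0, 1, n))
    return np.column_stack([
        fn,
        fs,
        rng.uniform(0.1, 3, n),
        rng.uniform(0.1, 3, n),
        rng.uniform(0.15, 1105.0, n),
        rng.uniform(0.03, 0.95, n),
    ])


MODELS: dict[str, ModelSpec] = {
    "ball_stick": ModelSpec(
        name="ball_stick",
        prior=PriorSpec(("f_in", "D_in", "D_e"),
                        [0.0, 0.1, 0.1], [1.0, 3.0, 3.0]),
        sample_prior_fn=_bs_prior,
        signal_fn=_ball_stick_batch,
    ),
    "standard_model": ModelSpec(
        name="standard_model",
        prior=PriorSpec(("f", "D_a", "ODI", "D_e_par", "D_e_perp"),
                        [0.0, 0.1, 0.03, 0.1, 0.1],
                        [1.0, 3.0, 0.95, 3.0, 3.0]),
        sample_prior_fn=_sm_prior,
        signal_fn=_standard_model_batch,
        constraint_fn=lambda t: t[:, 4] <= t[:, 3] + 1e-12,
    ),
    "extended_sandi": ModelSpec(
        name="extended_sandi",
        prior=PriorSpec(("f_n", "f_s", "D_n", "D_e", "C_s", "ODI"),
                        [0.0, 0.0, 0.1, 0.1, 0.15, 0.03],
                        [1.0, 1.0, 3.0, 3.0, 1105.0, 0.95]),
        sample_prior_fn=_sandi_prior,
        signal_fn=_sandi_batch,
        constraint_fn=lambda t: t[:, 0] + t[:, 1] <= 1.0 + 1e-12,
    ),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODELS)}"
        ) from None
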