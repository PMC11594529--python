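"""Acquisition schemes and signal matrices for multi-shell diffusion MRI.

The measurement protocol is described by per-measurement b-values
(s·mm⁻²), unit gradient directions, and the gradient pulse duration
``delta_small`` (δ, ms) and separation ``delta_big`` (Δ, ms).
Measurements are grouped into shells by clustering b-values within a
tolerance; b=0 measurements carry shell label 0.

Signals are handled voxel-wise as rows of a matrix, normalized by each
voxel's mean b=0 signal; after normalization the b=0 columns are dropped,
so the inference input for the default protocol has 138 values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "SignalMatrix",
    "read_scheme",
    "write_scheme",
    "make_default_scheme",
    "normalize_signal",
    "load_nifti_signals",
    "save_parameter_map",
]

#: default shell-clustering tolerance, s·mm⁻²; separates the default
#: protocol's shells (200/500/1200/2400/4000/6000) unambiguously
DEFAULT_SHELL_TOL = 50.0

# default protocol: b-values (s·mm⁻²) and directions per shell, plus 13 b=0
DEFAULT_BVALS = (200.0, 500.0, 1200.0, 2400.0, 4000.0, 6000.0)
DEFAULT_NDIRS = (20, 20, 30, 61, 61, 61)
DEFAULT_N_B0 = 13
DEFAULT_DELTA_SMALL = 7.0
DEFAULT_DELTA_BIG = 24.0


@dataclasses.dataclass(frozen=True)
class AcquisitionScheme:
    """Immutable multi-shell diffusion acquisition protocol.

    Attributes
    ----------
    b_values : (m,) array, s·mm⁻²
    directions : (m, 3) array of unit vectors (arbitrary for b=0)
    delta_small : gradient duration δ in ms
    delta_big : gradient separation Δ in ms
    shell_index : (m,) int array; 0 labels b=0 measurements
    """

    b_values: np.ndarray
    directions: np.ndarray
    delta_small: float
    delta_big: float
    shell_index: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        s = np.asarray(self.shell_index, dtype=int)
        if b.ndim != 1 or g.shape != (b.size, 3) or s.shape != b.shape:
            raise ValueError("per-measurement fields must share length m")
        if not np.all(np.isfinite(b)) or not np.all(np.isfinite(g)):
            raise ValueError("non-finite entries in scheme")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if not self.delta_small < self.delta_big:
            raise ValueError("gradient duration must be below separation")
        nonzero = s > 0
        norms = np.linalg.norm(g[nonzero], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)
        object.__setattr__(self, "shell_index", s)

    # -- derived quantities -------------------------------------------------

    @property
    def m(self) -> int:
        """Total number of measurements."""
        return self.b_values.size

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.shell_index == 0))

    @property
    def b0_mask(self) -> np.ndarray:
        return self.shell_index == 0

    @property
    def dw_mask(self) -> np.ndarray:
        """Mask of diffusion-weighted (b>0) measurements."""
        return self.shell_index > 0

    @property
    def n_dw(self) -> int:
        return int(np.sum(self.dw_mask))

    @property
    def shells(self) -> np.ndarray:
        """Mean b-value of each nonzero shell, ascending (s·mm⁻²)."""
        out = []
        for lab in np.unique(self.shell_index[self.shell_index > 0]):
            out.append(self.b_values[self.shell_index == lab].mean())
        return np.asarray(sorted(out))

    @property
    def b_ms_um2(self) -> np.ndarray:
        """b-values in ms·µm⁻² (1000 s·mm⁻² = 1 ms·µm⁻²)."""
        return self.b_values / 1000.0

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.round(self.b_values, 6).tobytes())
        h.update(np.round(self.directions, 6).tobytes())
        h.update(np.float64([self.delta_small, self.delta_big]).tobytes())
        return h.hexdigest()[:16]


@dataclasses.dataclass
class SignalMatrix:
    """b0-normalized diffusion-weighted signals, voxels × measurements."""

    values: np.ndarray
    scheme: AcquisitionScheme
    rejected: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(0, dtype=int)
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != self.scheme.n_dw:
            raise ValueError(
                "signal matrix must have one column per diffusion-weighted "
                f"measurement ({self.scheme.n_dw})"
            )
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("signal values must be finite and non-negative")
        self.values = v


def _assign_shells(b: np.ndarray, shell_tol: float) -> np.ndarray:
    """Cluster b-values into shells within ``shell_tol``; label 0 is b<tol."""
    shell = np.zeros(b.size, dtype=int)
    remaining = np.where(b >= shell_tol)[0]
    # greedy clustering on sorted b-values; shells labelled in ascending b
    centers: list[float] = []
    members: list[list[int]] = []
    for i in remaining[np.argsort(b[remaining], kind="stable")]:
        if centers and abs(b[i] - centers[-1]) <= shell_tol:
            members[-1].append(i)
            centers[-1] = float(np.mean(b[members[-1]]))
        else:
            centers.append(float(b[i]))
            members.append([i])
    for lab, idx in enumerate(members, start=1):
        shell[idx] = lab
    return shell


def read_scheme(
    bval_path: str | Path,
    bvec_path: str | Path,
    delta_small: float,
    delta_big: float,
    shell_tol: float = DEFAULT_SHELL_TOL,
) -> AcquisitionScheme:
    """Read an FSL-style .bval/.bvec pair into an :class:`AcquisitionScheme`.

    b-vectors may be 3×m or m×3 whitespace text (auto-detected by shape);
    directions are renormalized to unit length. b < ``shell_tol`` is
    treated as b=0.
    """
    b = np.loadtxt(bval_path, dtype=float).ravel()
    g = np.loadtxt(bvec_path, dtype=float)
    if g.ndim != 2:
        g = np.atleast_2d(g)
    if g.shape[0] == 3 and g.shape[1] != 3:
        g = g.T
    elif g.shape[1] != 3:
        if g.shape[0] == 3:
            g = g.T
        else:
            raise ValueError("b-vector file must be 3×m or m×3")
    if g.shape[0] != b.size:
        raise ValueError(
            f"bval/bvec length mismatch: {b.size} b-values, {g.shape[0]} vectors"
        )
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(g))):
        raise ValueError("non-finite entries in bval/bvec files")
    shell = _assign_shells(b, shell_tol)
    norms = np.linalg.norm(g, axis=1)
    if np.any((shell > 0) & (norms < 1e-12)):
        raise ValueError("zero-norm direction on a diffusion-weighted measurement")
    g = g.copy()
    nz = norms > 1e-12
    g[nz] /= norms[nz, None]
    g[~nz] = (1.0, 0.0, 0.0)  # placeholder direction for b=0
    return AcquisitionScheme(b, g, float(delta_small), float(delta_big), shell)


def write_scheme(
    scheme: AcquisitionScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write ``scheme`` as an FSL-style .bval/.bvec pair (3×m b-vectors)."""
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.6f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.6f")


def _repulsion_directions(n: int, rng: np.random.Generator, n_iter: int = 300) -> np.ndarray:
    """Antipodally symmetric electrostatic-repulsion placement of n directions."""
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.1
    for _ in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]
            d2 = np.sum(diff**2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            d2[d2 < 1e-12] = 1e-12
            force += np.sum(diff / (d2**1.5)[..., None], axis=1)
        # project onto tangent plane and take a small normalized step
        force -= np.sum(force * x, axis=1, keepdims=True) * x
        fn = np.linalg.norm(force, axis=1, keepdims=True)
        fn[fn < 1e-12] = 1e-12
        x = x + step * force / fn
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        step *= 0.985
    return x


def make_default_scheme() -> AcquisitionScheme:
    """Build the default 6-shell protocol.

    Shells at b = 200/500/1200/2400/4000/6000 s·mm⁻² with 20/20/30/61/61/61
    directions placed by deterministic electrostatic repulsion (seed 0),
    13 b=0 measurements, δ = 7 ms, Δ = 24 ms (266 measurements in total).
    """
    rng = np.random.default_rng(0)
    b_list = [np.zeros(DEFAULT_N_B0)]
    g_list = [np.tile((1.0, 0.0, 0.0), (DEFAULT_N_B0, 1))]
    shell_list = [np.zeros(DEFAULT_N_B0, dtype=int)]
    for lab, (bval, ndir) in enumerate(zip(DEFAULT_BVALS, DEFAULT_NDIRS), start=1):
        b_list.append(np.full(ndir, bval))
        g_list.append(_repulsion_directions(ndir, rng))
        shell_list.append(np.full(ndir, lab, dtype=int))
    return AcquisitionScheme(
        np.concatenate(b_list),
        np.vstack(g_list),
        DEFAULT_DELTA_SMALL,
        DEFAULT_DELTA_BIG,
        np.concatenate(shell_list),
    )


def normalize_signal(raw: np.ndarray, scheme: AcquisitionScheme) -> SignalMatrix:
    """Normalize raw signals by each voxel's mean b=0 signal.

    Parameters
    ----------
    raw : (n_voxels, m) array matching ``scheme``; a single voxel may be
        passed as a 1-D array.

    Returns
    -------
    SignalMatrix with b=0 columns dropped. Voxels whose mean b=0 signal is
    not positive are excluded and recorded in ``rejected`` (row indices).
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[1] != scheme.m:
        raise ValueError(f"expected {scheme.m} columns, got {raw.shape[1]}")
    if scheme.n_b0 == 0:
        raise ValueError("scheme has no b=0 measurement to normalize by")
    b0_mean = raw[:, scheme.b0_mask].mean(axis=1)
    good = b0_mean > 0
    rejected = np.where(~good)[0]
    values = raw[good][:, scheme.dw_mask] / b0_mean[good, None]
    return SignalMatrix(values=np.clip(values, 0.0, None), scheme=scheme,
                        rejected=rejected)


# -- thin volumetric adapter (voxel grid only, no spatial processing) --------


def load_nifti_signals(path: str | Path, mask: np.ndarray | None = None):
    """Load a 4-D NIfTI volume into a (n_voxels, m) matrix.

    Returns ``(signals, index, shape, affine)`` where ``index`` holds the
    flat voxel indices retained (all voxels, or ``mask``'s nonzero ones).
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D volume")
    flat = data.reshape(-1, data.shape[-1])
    if mask is not None:
        index = np.flatnonzero(np.asarray(mask).reshape(-1))
    else:
        index = np.arange(flat.shape[0])
    return flat[index], index, data.shape[:3], img.affine


def save_parameter_map(
    path: str | Path,
    values: np.ndarray,
    index: np.ndarray,
    shape: tuple[int, int, int],
    affine: np.ndarray,
    fill: float = 0.0,
) -> None:
    """Write per-voxel values back onto the 3-D grid as a NIfTI volume."""
    import nibabel as nib

    vol = np.full(int(np.prod(shape)), fill, dtype=float)
    vol[index] = values
    nib.save(nib.Nifti1Image(vol.reshape(shape), affine), str(path))
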