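"""Conditional masked autoregressive flow with a joint embedding network.

The conditional density estimator q(z | x) is a stack of MADE-style
autoregressive transforms with Gaussian conditionals: block k maps
z → u = (z − μ(z_<, c))·exp(−α(z_<, c)) with μ, α produced by a masked
one-hidden-layer network conditioned on a context vector c, and the base
distribution is a standard normal. The context is the output of a small
MLP (the embedding network) applied to the signal vector; both are
trained together by minimizing the negative mean conditional
log-density with Adam. Input order is reversed between successive
blocks.

Everything here is plain numpy with analytic gradients: forward passes
cache intermediates and the backward pass accumulates parameter
gradients exactly, so training is deterministic given a seed. All
parameters live in one flat float32 vector (the per-tensor dict holds
views into it), which keeps the optimizer a handful of vectorized
operations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConditionalMAF", "Adam"]

_LOG2PI = float(np.log(2.0 * np.pi))
_ALPHA_CLAMP = 6.0  # soft bound on the log-scale outputs
_DTYPE = np.float32


def _made_masks(dim: int, hidden: int) -> tuple[np.ndarray, np.ndarray]:
    """Input→hidden and hidden→output masks enforcing strict
    autoregressive dependence (output i depends on inputs < i)."""
    d_in = np.arange(1, dim + 1)
    if dim > 1:
        d_hid = 1 + np.arange(hidden) % (dim - 1)
    else:
        d_hid = np.zeros(hidden, dtype=int)
    m1 = (d_hid[None, :] >= d_in[:, None]).astype(_DTYPE)  # (dim, hidden)
    m2 = (d_in[None, :] > d_hid[:, None]).astype(_DTYPE)  # (hidden, dim)
    return m1, m2


class Adam:
    """Adam over a flat parameter vector."""

    def __init__(self, n_params: int, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n_params, dtype=_DTYPE)
        self.v = np.zeros(n_params, dtype=_DTYPE)
        self.t = 0

    def step(self, flat_params: np.ndarray, flat_grads: np.ndarray) -> None:
        self.t += 1
        self.m += (1 - self.b1) * (flat_grads - self.m)
        self.v += (1 - self.b2) * (flat_grads**2 - self.v)
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        flat_params -= self.lr * (self.m / c1) / (np.sqrt(self.v / c2) + self.eps)


class _FlatStore:
    """A flat vector plus named views with fixed shapes."""

    def __init__(self) -> None:
        self.shapes: dict[str, tuple[int, ...]] = {}
        self.flat: np.ndarray | None = None
        self.views: dict[str, np.ndarray] = {}

    def declare(self, name: str, shape: tuple[int, ...]) -> None:
        self.shapes[name] = shape

    def allocate(self) -> None:
        total = sum(int(np.prod(s)) for s in self.shapes.values())
        self.flat = np.zeros(total, dtype=_DTYPE)
        off = 0
        for name, shape in self.shapes.items():
            size = int(np.prod(shape))
            self.views[name] = self.flat[off:off + size].reshape(shape)
            off += size

    def __getitem__(self, name: str) -> np.ndarray:
        return self.views[name]

    def __setitem__(self, name: str, value: np.ndarray) -> None:
        self.views[name][...] = value


class ConditionalMAF:
    """Masked autoregressive flow conditioned on an embedded signal.

    Parameters
    ----------
    dim : dimensionality of the modelled variable z.
    x_dim : dimensionality of the raw conditioning vector.
    n_features : size of the embedding output fed to every block.
    embed_hidden : hidden widths of the embedding MLP; an empty tuple
        means the flow conditions on the (standardized) signal directly.
    n_transforms, flow_hidden : number of stacked MADE blocks and their
        hidden width.
    """

    def __init__(self, dim: int, x_dim: int, n_features: int,
                 embed_hidden: tuple[int, ...] = (256, 128, 64),
                 n_transforms: int = 5, flow_hidden: int = 50,
                 rng: np.random.Generator | None = None):
        if n_transforms < 1:
            raise ValueError("need at least one transform")
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.x_dim = x_dim
        self.embed_hidden = tuple(embed_hidden)
        self.n_features = n_features if self.embed_hidden else x_dim
        self.K = n_transforms
        self.H = flow_hidden
        self.M1, self.M2 = _made_masks(dim, flow_hidden)
        # alternate input orderings between blocks (reversal)
        self.perms = [
            np.arange(dim) if k % 2 == 0 else np.arange(dim)[::-1].copy()
            for k in range(n_transforms)
        ]
        self._store = _FlatStore()
        self._gstore = _FlatStore()
        self._declare_params()
        self._store.allocate()
        self._gstore.allocate()
        self._init_params(rng)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self._store.views

    @property
    def flat_params(self) -> np.ndarray:
        return self._store.flat

    @property
    def n_parameters(self) -> int:
        return self._store.flat.size

    # -- initialization -----------------------------------------------------

    def _declare_params(self) -> None:
        def lin(name, n_in, n_out):
            self._store.declare(f"{name}_W", (n_in, n_out))
            self._store.declare(f"{name}_b", (n_out,))

        if self.embed_hidden:
            sizes = (self.x_dim, *self.embed_hidden, self.n_features)
            for j in range(len(sizes) - 1):
                lin(f"emb{j}", sizes[j], sizes[j + 1])
        ctx = self.n_features
        for k in range(self.K):
            lin(f"f{k}_in", self.dim, self.H)
            lin(f"f{k}_ctx", ctx, self.H)
            lin(f"f{k}_m", self.H, self.dim)
            lin(f"f{k}_a", self.H, self.dim)
            self._store.declare(f"f{k}_Cm", (ctx, self.dim))
            self._store.declare(f"f{k}_Ca", (ctx, self.dim))
        self._gstore.shapes = dict(self._store.shapes)

    def _init_params(self, rng: np.random.Generator) -> None:
        p = self.params

        def fill(name, scale):
            w = p[name]
            w[...] = rng.normal(0, scale / np.sqrt(max(w.shape[0], 1)),
                                w.shape)

        if self.embed_hidden:
            for j in range(len(self.embed_hidden) + 1):
                fill(f"emb{j}_W", 1.0)
        for k in range(self.K):
            fill(f"f{k}_in_W", 1.0)
            fill(f"f{k}_ctx_W", 1.0)
            # near-identity start: small output weights so u ≈ z initially
            fill(f"f{k}_m_W", 0.01)
            fill(f"f{k}_a_W", 0.01)
            fill(f"f{k}_Cm", 0.01)
            fill(f"f{k}_Ca", 0.01)

    def copy_params(self) -> np.ndarray:
        return self._store.flat.copy()

    def set_params(self, flat: np.ndarray) -> None:
        self._store.flat[...] = flat

    # -- embedding ----------------------------------------------------------

    def embed(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Map standardized signals to the learned feature space."""
        x = np.asarray(x, dtype=_DTYPE)
        if not self.embed_hidden:
            return x
        p = self.params
        a = x
        n_lin = len(self.embed_hidden) + 1
        for j in range(n_lin):
            s = a @ p[f"emb{j}_W"] + p[f"emb{j}_b"]
            anew = np.tanh(s) if j < n_lin - 1 else s  # linear readout
            if cache is not None:
                cache.append((a, anew, j < n_lin - 1))
            a = anew
        return a

    def _embed_backward(self, cache: list, g_out: np.ndarray,
                        grads: _FlatStore) -> None:
        p = self.params
        g = g_out
        for j in reversed(range(len(cache))):
            a_in, a_out, nonlin = cache[j]
            g_s = g * (1 - a_out**2) if nonlin else g
            grads[f"emb{j}_W"] += a_in.T @ g_s
            grads[f"emb{j}_b"] += g_s.sum(axis=0)
            if j > 0:
                g = g_s @ p[f"emb{j}_W"].T

    # -- flow forward/backward ---------------------------------------------

    def _block_forward(self, k: int, z: np.ndarray, c: np.ndarray,
                       want_cache: bool):
        p = self.params
        zb = z[:, self.perms[k]]
        pre1 = zb @ (p[f"f{k}_in_W"] * self.M1) + c @ p[f"f{k}_ctx_W"] \
            + p[f"f{k}_in_b"] + p[f"f{k}_ctx_b"]
        h = np.tanh(pre1)
        mu = h @ (p[f"f{k}_m_W"] * self.M2) + c @ p[f"f{k}_Cm"] + p[f"f{k}_m_b"]
        araw = h @ (p[f"f{k}_a_W"] * self.M2) + c @ p[f"f{k}_Ca"] + p[f"f{k}_a_b"]
        th = np.tanh(araw / _ALPHA_CLAMP)
        a = _ALPHA_CLAMP * th
        u = (zb - mu) * np.exp(-a)
        cache = (zb, h, mu, th, a, u) if want_cache else None
        return u, a, cache

    def log_prob(self, z: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Per-row log q(z | x); inputs are in standardized coordinates."""
        z = np.asarray(z, dtype=_DTYPE)
        c = self.embed(x)
        cur = z
        logdet = np.zeros(z.shape[0], dtype=np.float64)
        for k in range(self.K):
            cur, a, _ = self._block_forward(k, cur, c, want_cache=False)
            logdet -= a.sum(axis=1, dtype=np.float64)
        return (
            -0.5 * (cur.astype(np.float64) ** 2).sum(axis=1)
            - 0.5 * self.dim * _LOG2PI
            + logdet
        )

    def loss_and_grads(self, z: np.ndarray, x: np.ndarray):
        """Mean negative log-density over the batch, with its gradient as
        a flat vector aligned with ``flat_params``."""
        z = np.asarray(z, dtype=_DTYPE)
        B = z.shape[0]
        p = self.params
        emb_cache: list = []
        c = self.embed(x, cache=emb_cache)
        cur = z
        caches = []
        nll = np.full(B, 0.5 * self.dim * _LOG2PI)
        for k in range(self.K):
            cur, a, cache = self._block_forward(k, cur, c, want_cache=True)
            caches.append(cache)
            nll += a.sum(axis=1, dtype=np.float64)
        nll += 0.5 * (cur.astype(np.float64) ** 2).sum(axis=1)
        loss = float(nll.mean())

        grads = self._gstore
        grads.flat.fill(0.0)
        g_u = cur.copy()  # d(0.5||u||²)/du for the final block output
        g_c = np.zeros_like(c)
        for k in reversed(range(self.K)):
            zb, h, mu, th, a, u = caches[k]
            e = np.exp(-a)
            g_zb = g_u * e
            g_m = -g_zb
            g_a = 1.0 - g_u * u  # +1 from the log-det term of the loss
            g_araw = g_a * (1.0 - th**2)
            grads[f"f{k}_m_W"] += (h.T @ g_m) * self.M2
            grads[f"f{k}_Cm"] += c.T @ g_m
            grads[f"f{k}_m_b"] += g_m.sum(axis=0)
            grads[f"f{k}_a_W"] += (h.T @ g_araw) * self.M2
            grads[f"f{k}_Ca"] += c.T @ g_araw
            grads[f"f{k}_a_b"] += g_araw.sum(axis=0)
            g_h = g_m @ (p[f"f{k}_m_W"] * self.M2).T \
                + g_araw @ (p[f"f{k}_a_W"] * self.M2).T
            g_pre1 = g_h * (1.0 - h**2)
            grads[f"f{k}_in_W"] += (zb.T @ g_pre1) * self.M1
            grads[f"f{k}_ctx_W"] += c.T @ g_pre1
            g_pre1_sum = g_pre1.sum(axis=0)
            grads[f"f{k}_in_b"] += g_pre1_sum
            grads[f"f{k}_ctx_b"] += g_pre1_sum
            g_zb_tot = g_zb + g_pre1 @ (p[f"f{k}_in_W"] * self.M1).T
            g_c += g_pre1 @ p[f"f{k}_ctx_W"].T + g_m @ p[f"f{k}_Cm"].T \
                + g_araw @ p[f"f{k}_Ca"].T
            g_prev = np.empty_like(g_zb_tot)
            g_prev[:, self.perms[k]] = g_zb_tot
            g_u = g_prev
        if self.embed_hidden:
            self._embed_backward(emb_cache, g_c, grads)
        grads.flat /= B
        return loss, grads.flat

    # -- sampling (inverse pass) ---------------------------------------------

    def sample(self, x: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n flow samples (standardized coordinates) conditioned on a
        single signal vector ``x`` of shape (x_dim,)."""
        c1 = self.embed(np.atleast_2d(x))
        c = np.broadcast_to(c1, (n, c1.shape[1]))
        u = rng.standard_normal((n, self.dim)).astype(_DTYPE)
        return self._inverse(u, c)

    def _inverse(self, u: np.ndarray, c: np.ndarray) -> np.ndarray:
        p = self.params
        u = np.asarray(u, dtype=_DTYPE)
        for k in reversed(range(self.K)):
            W1 = p[f"f{k}_in_W"] * self.M1
            ctxW = c @ p[f"f{k}_ctx_W"] + p[f"f{k}_in_b"] + p[f"f{k}_ctx_b"]
            ctx_m = c @ p[f"f{k}_Cm"] + p[f"f{k}_m_b"]
            ctx_a = c @ p[f"f{k}_Ca"] + p[f"f{k}_a_b"]
            W2m = p[f"f{k}_m_W"] * self.M2
            W2a = p[f"f{k}_a_W"] * self.M2
            zb = np.zeros_like(u)
            for i in range(self.dim):
                h = np.tanh(zb @ W1 + ctxW)
                mu = h @ W2m[:, i] + ctx_m[:, i]
                araw = h @ W2a[:, i] + ctx_a[:, i]
                a = _ALPHA_CLAMP * np.tanh(araw / _ALPHA_CLAMP)
                zb[:, i] = u[:, i] * np.exp(a) + mu
            z = np.empty_like(zb)
            z[:, self.perms[k]] = zb
            u = z
        return u

    # -- (de)serialization ---------------------------------------------------

    def state(self) -> dict:
        return {
            "dim": self.dim,
            "x_dim": self.x_dim,
            "n_features": self.n_features if self.embed_hidden else None,
            "embed_hidden": self.embed_hidden,
            "n_transforms": self.K,
            "flow_hidden": self.H,
            "flat_params": self.copy_params(),
        }

    @classmethod
    def from_state(cls, state: dict) -> "ConditionalMAF":
        net = cls(
            state["dim"], state["x_dim"],
            state["n_features"] or state["x_dim"],
            tuple(state["embed_hidden"]), state["n_transforms"],
            state["flow_hidden"],
        )
        net.set_params(state["flat_params"])
        return net
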