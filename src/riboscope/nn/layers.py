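"""Neural-network building blocks on top of the autodiff tensors.

Layers hold named :class:`Parameter` objects; ``named_parameters()`` walks a
module tree so checkpoints are flat ``name -> array`` mappings.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .autodiff import Parameter, Tensor


class Module:
    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        params = self.named_parameters(prefix=prefix)
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]} ...")
        from . import autodiff

        for name, p in params.items():
            arr = np.asarray(state[name], dtype=autodiff.DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} vs model {p.data.shape}"
                )
            p.data = arr.copy()

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(width))
        self.beta = Parameter(np.zeros(width))
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self._eps) ** 0.5) * self.gamma + self.beta


_REL_OFFSET_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _rel_offsets(L: int, window: int) -> np.ndarray:
    key = (L, window)
    if key not in _REL_OFFSET_CACHE:
        if len(_REL_OFFSET_CACHE) > 64:
            _REL_OFFSET_CACHE.clear()
        idx = np.arange(L)
        _REL_OFFSET_CACHE[key] = np.clip(idx[None, :] - idx[:, None], -window, window) + window
    return _REL_OFFSET_CACHE[key]


def _gather_rel_bias(bias: Parameter, offsets: np.ndarray) -> Tensor:
    """bias (n_heads, n_offsets) gathered to (n_heads, L, L) attention bias.

    The backward pass scatters with ``bincount`` per head, which is far
    faster than generic fancy-index accumulation on the L x L grid.
    """
    nh, n_off = bias.data.shape
    out_data = bias.data[:, offsets]
    flat = offsets.ravel()

    def backward(g: np.ndarray) -> None:
        if not bias.requires_grad:
            return
        grad = np.stack(
            [np.bincount(flat, weights=g[h].ravel(), minlength=n_off) for h in range(nh)]
        )
        bias._accum(grad.astype(g.dtype))

    return Tensor._make(out_data, (bias,), backward)


def _dropout(x: Tensor, p: float, rng: Optional[np.random.Generator]) -> Tensor:
    if p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    """Self-attention over (batch, length, width) inputs.

    ``kind="exact"`` materializes the full attention matrix.
    ``kind="kernel"`` uses the positive-random-feature softmax-kernel
    approximation (Performer-style FAVOR+), which avoids the quadratic
    attention matrix; its random projection is fixed at construction so
    forward passes are deterministic.
    """

    def __init__(
        self,
        width: int,
        n_heads: int,
        rng: np.random.Generator,
        kind: str = "exact",
        n_features: int = 64,
        relative_window: int = 0,
    ):
        if width % n_heads:
            raise ValueError("width must be divisible by n_heads")
        if kind not in ("exact", "kernel"):
            raise ValueError(f"unknown attention kind {kind!r}")
        if relative_window and kind == "kernel":
            raise ValueError("relative position bias requires exact attention")
        self.kind = kind
        self.n_heads = n_heads
        self.d_head = width // n_heads
        self.wq = Dense(width, width, rng)
        self.wk = Dense(width, width, rng)
        self.wv = Dense(width, width, rng)
        self.wo = Dense(width, width, rng)
        self.relative_window = relative_window
        if relative_window:
            # Learned additive attention bias per clipped relative offset,
            # initialized with a local, 3-periodic prior: ribosome footprint
            # counts carry triplet periodicity, so codon-stride neighbours
            # start out slightly favoured. Training reshapes this freely.
            offs = np.arange(-relative_window, relative_window + 1)
            prior = np.exp(-np.abs(offs) / 12.0) * (
                0.5 + np.where(offs % 3 == 0, 0.5, 0.0)
            )
            self.rel_bias = Parameter(np.tile(prior, (n_heads, 1)))
        if kind == "kernel":
            # orthogonal random features per head, frozen
            feats = []
            for _ in range(n_heads):
                blocks = []
                remaining = n_features
                while remaining > 0:
                    q, _ = np.linalg.qr(rng.normal(size=(self.d_head, self.d_head)))
                    norms = np.sqrt(
                        rng.chisquare(self.d_head, size=min(remaining, self.d_head))
                    )
                    blocks.append(q[:, : len(norms)] * norms)
                    remaining -= len(norms)
                feats.append(np.concatenate(blocks, axis=1))
            self.omega = np.stack(feats)  # (n_heads, d_head, n_features); constant
        else:
            self.omega = None

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        # (B, L, width) -> (B, n_heads, L, d_head)
        return x.reshape(B, L, self.n_heads, self.d_head).swapaxes(1, 2)

    def __call__(self, x: Tensor, valid: np.ndarray) -> Tensor:
        B, L, width = x.shape
        q = self._split(self.wq(x), B, L)
        k = self._split(self.wk(x), B, L)
        v = self._split(self.wv(x), B, L)
        if self.kind == "exact":
            scores = (q * (1.0 / np.sqrt(self.d_head))) @ k.swapaxes(-1, -2)
            if not valid.all():
                scores = scores + Tensor(np.where(valid[:, None, None, :], 0.0, -1e9))
            if self.relative_window:
                scores = scores + _gather_rel_bias(self.rel_bias, _rel_offsets(L, self.relative_window))
            attn = scores.softmax(axis=-1)
            out = attn @ v
        else:
            out = self._kernel_attention(q, k, v, valid)
        out = out.swapaxes(1, 2).reshape(B, L, width)
        return self.wo(out)

    def _kernel_attention(self, q: Tensor, k: Tensor, v: Tensor, valid: np.ndarray) -> Tensor:
        scale = self.d_head**-0.25
        q = q * scale
        k = k * scale
        omega = Tensor(self.omega[None])  # (1, nh, d_head, m)
        m = self.omega.shape[-1]

        def features(x: Tensor, stab: float) -> Tensor:
            proj = x @ omega  # (B, nh, L, m)
            sq = (x * x).sum(axis=-1, keepdims=True) * 0.5
            return (proj - sq - stab).exp() * (m**-0.5)

        stab = float(max(np.max(q.data @ self.omega[None]), np.max(k.data @ self.omega[None]), 0.0))
        phi_q = features(q, stab)
        phi_k = features(k, stab) * Tensor(valid[:, None, :, None].astype(float))
        kv = phi_k.swapaxes(-1, -2) @ v  # (B, nh, m, d_head)
        num = phi_q @ kv
        denom = (phi_q * phi_k.sum(axis=2, keepdims=True)).sum(axis=-1, keepdims=True)
        return num / (denom + 1e-9)


class LocalConv(Module):
    """Same-padded 1-D convolution over (batch, length, channels) tensors.

    Implemented as a dedicated autodiff op: the forward gathers shifted
    views of the zero-padded input and contracts them with the kernel; the
    backward convolves the upstream gradient with the flipped kernel.
    """

    def __init__(self, n_in: int, n_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        scale = np.sqrt(2.0 / (kernel * n_in + n_out))
        self.W = Parameter(rng.normal(0.0, scale, size=(kernel, n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        W = self.W
        K = self.kernel // 2
        B, L, _ = x.shape
        xp = np.pad(x.data, ((0, 0), (K, K), (0, 0)))
        out_data = np.zeros((B, L, W.data.shape[2]), dtype=x.data.dtype)
        for k in range(self.kernel):
            out_data += xp[:, k : k + L] @ W.data[k]

        def backward(g: np.ndarray) -> None:
            if W.requires_grad:
                gw = np.empty_like(W.data)
                for k in range(self.kernel):
                    gw[k] = np.tensordot(xp[:, k : k + L], g, axes=([0, 1], [0, 1]))
                W._accum(gw)
            if x.requires_grad:
                gp = np.pad(g, ((0, 0), (K, K), (0, 0)))
                gx = np.zeros_like(x.data)
                for k in range(self.kernel):
                    gx += gp[:, self.kernel - 1 - k : self.kernel - 1 - k + L] @ W.data[k].swapaxes(0, 1)
                x._accum(gx)

        return Tensor._make(out_data, (x, W), backward) + self.b


class FeedForward(Module):
    def __init__(self, width: int, hidden: int, rng: np.random.Generator):
        self.w1 = Dense(width, hidden, rng)
        self.w2 = Dense(hidden, width, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.w2(self.w1(x).gelu())


class TransformerBlock(Module):
    """Pre-norm transformer block: x + MHA(LN(x)); x + FF(LN(x))."""

    def __init__(
        self,
        width: int,
        n_heads: int,
        rng: np.random.Generator,
        attention_kind: str = "exact",
        ff_mult: int = 2,
        n_features: int = 64,
        relative_window: int = 0,
    ):
        kind = "kernel" if attention_kind in ("kernel", "kernel-approximate") else "exact"
        self.ln1 = LayerNorm(width)
        self.attn = MultiHeadSelfAttention(width, n_heads, rng, kind=kind,
                                           n_features=n_features,
                                           relative_window=relative_window)
        self.ln2 = LayerNorm(width)
        self.ff = FeedForward(width, ff_mult * width, rng)

    def __call__(
        self,
        x: Tensor,
        valid: np.ndarray,
        dropout: float = 0.0,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        x = x + _dropout(self.attn(self.ln1(x), valid), dropout, rng)
        x = x + _dropout(self.ff(self.ln2(x)), dropout, rng)
        return x


class Adam:
    def __init__(
        self,
        params: dict[str, Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
            p._grad_owned = False

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
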