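"""Layers for the point network, composed from autodiff primitives.

Convolutions are expressed as shifted-slice + matmul compositions (small
kernels, small images), which keeps the autodiff primitive set tiny while
remaining fast enough for CPU training at the problem sizes used here.
All feature maps are channels-last (H, W, C) or (B, H, W, C).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, add, gelu, layer_norm, matmul, mul, reshape, softmax, transpose, tslice

__all__ = ["conv2x2_s2", "conv1x1", "depthwise3x3", "multi_head_attention", "Adam"]


def conv2x2_s2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 convolution with stride 2 on (B, H, W, Cin); w is (4, Cin, Cout)."""
    bsz, h, wd, cin = x.shape
    cout = w.shape[-1]
    out = None
    for i, (dy, dx) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        sl = tslice(x, (slice(None), slice(dy, None, 2), slice(dx, None, 2), slice(None)))
        flat = reshape(sl, (bsz * (h // 2) * (wd // 2), cin))  # single GEMM per tap
        term = matmul(flat, tslice(w, i))
        out = term if out is None else add(out, term)
    out = reshape(out, (bsz, h // 2, wd // 2, cout))
    return add(out, b)


def conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Pointwise convolution: (..., Cin) @ (Cin, Cout) + bias."""
    return add(matmul(x, w), b)


def _pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the two spatial axes of (H, W, C)."""
    widths = ((pad, pad), (pad, pad), (0, 0))
    out_data = np.pad(x.data, widths)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g[pad:-pad, pad:-pad, :])

    return Tensor(out_data, parents=(x,), backward=bwd)


def depthwise3x3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Depthwise 3x3 convolution, same padding, on (H, W, C); w is (3, 3, C)."""
    h, wd = x.shape[0], x.shape[1]
    xp = _pad2d(x, 1)
    out = None
    for dy in range(3):
        for dx in range(3):
            sl = tslice(xp, (slice(dy, dy + h), slice(dx, dx + wd), slice(None)))
            term = mul(sl, tslice(w, (dy, dx)))
            out = term if out is None else add(out, term)
    return add(out, b)


def multi_head_attention(x: Tensor, p: dict, n_heads: int, identity_attention: bool = False) -> Tensor:
    """Standard multi-head self-attention on (N, d) token embeddings.

    ``identity_attention`` is a diagnostic hook replacing the whole mechanism
    with the identity map, used to verify residual algebra in tests.
    """
    if identity_attention:
        return x
    n, d = x.shape
    dh = d // n_heads
    q = add(matmul(x, p["wq"]), p["bq"])
    k = add(matmul(x, p["wk"]), p["bk"])
    v = add(matmul(x, p["wv"]), p["bv"])

    def split(t):  # (N, d) -> (heads, N, dh)
        return transpose(reshape(t, (n, n_heads, dh)), (1, 0, 2))

    q, k, v = split(q), split(k), split(v)
    logits = mul(matmul(q, transpose(k, (0, 2, 1))), Tensor(1.0 / np.sqrt(dh)))
    attn = softmax(logits, axis=-1)
    out = matmul(attn, v)  # (heads, N, dh)
    out = reshape(transpose(out, (1, 0, 2)), (n, d))
    return add(matmul(out, p["wo"]), p["bo"])


def local_ffn(x: Tensor, p: dict, grid: int) -> Tensor:
    """Locality-preserving feed-forward: 1x1 expand -> 3x3 depthwise -> 1x1 project.

    Tokens (N, d) are reshaped to their (sqrt(N), sqrt(N), d) spatial layout so
    the depthwise convolution mixes spatially adjacent patches.
    """
    n, d = x.shape
    xs = reshape(x, (grid, grid, d))
    h = gelu(conv1x1(xs, p["w_exp"], p["b_exp"]))
    h = gelu(depthwise3x3(h, p["w_dw"], p["b_dw"]))
    h = conv1x1(h, p["w_proj"], p["b_proj"])
    return reshape(h, (n, d))


def encoder_block(
    x: Tensor,
    p: dict,
    n_heads: int,
    grid: int,
    use_layernorm: bool = True,
    identity_attention: bool = False,
    zero_ffn: bool = False,
) -> Tensor:
    """Pre-norm locality-preserving encoder block: x + MHSA, then x + localFFN."""
    a_in = layer_norm(x, p["ln1_g"], p["ln1_b"]) if use_layernorm else x
    x = add(x, multi_head_attention(a_in, p, n_heads, identity_attention))
    if zero_ffn:
        return x
    f_in = layer_norm(x, p["ln2_g"], p["ln2_b"]) if use_layernorm else x
    return add(x, local_ffn(f_in, p, grid))


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
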