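"""A small 1-D U-Net regressor in pure numpy, with manual backprop and Adam.

Scope is deliberately narrow: fixed kernel size 3, stride-2 average pooling,
nearest-neighbour upsampling, ReLU activations, skip concatenation, global
average pooling and a linear head emitting one scalar per input window.
Everything is float32 and single-threaded-deterministic given the seed.
Gradients are exact (verified against finite differences in the test suite),
not approximated.

Internally activations are stored channel-first as (C, N, L) so every
convolution is a single (C_out, 3*C_in) x (3*C_in, N*L) matrix product; the
public forward/backward API uses the conventional (N, C, L).
"""

from __future__ import annotations

import numpy as np

_F = np.float32


class Conv1d:
    """k=3 same-padding convolution on (C, N, L) activations.

    Weight layout (C_out, 3*C_in), tap-major: columns are
    [tap0 x C_in, tap1 x C_in, tap2 x C_in].
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 3))
        self.w = (rng.standard_normal((c_out, c_in * 3)) * scale).astype(_F)
        self.b = np.zeros(c_out, dtype=_F)
        self.c_in = c_in

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, n, length = x.shape
        xp = np.zeros((c, n, length + 2), dtype=x.dtype)
        xp[:, :, 1:-1] = x
        cols = np.concatenate([xp[:, :, k:k + length] for k in range(3)], axis=0)
        self._cols = cols.reshape(3 * c, n * length)
        self._shape = (n, length)
        out = self.w @ self._cols + self.b[:, None]
        return out.reshape(-1, n, length)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c_out, n, length = grad.shape
        g2 = grad.reshape(c_out, n * length)
        self.dw = g2 @ self._cols.T
        self.db = g2.sum(axis=1)
        dcols = (self.w.T @ g2).reshape(3 * self.c_in, n, length)
        dxp = np.zeros((self.c_in, n, length + 2), dtype=grad.dtype)
        for k in range(3):
            dxp[:, :, k:k + length] += dcols[k * self.c_in:(k + 1) * self.c_in]
        return dxp[:, :, 1:-1]


def _relu_fwd(x):
    mask = x > 0
    return x * mask, mask


def _pool2_fwd(x):
    """Stride-2 average pooling over the time axis; odd trailing frame dropped."""
    length = x.shape[2] - (x.shape[2] % 2)
    xt = x[:, :, :length]
    return 0.5 * (xt[:, :, 0::2] + xt[:, :, 1::2]), x.shape[2]


def _pool2_bwd(grad, orig_len):
    c, n, lp = grad.shape
    dx = np.zeros((c, n, orig_len), dtype=grad.dtype)
    g = 0.5 * grad
    dx[:, :, 0:2 * lp:2] = g
    dx[:, :, 1:2 * lp:2] = g
    return dx


def _upsample_fwd(x, target_len):
    up = np.repeat(x, 2, axis=2)
    if up.shape[2] < target_len:  # odd skip length lost one frame at pooling
        pad = np.repeat(up[:, :, -1:], target_len - up.shape[2], axis=2)
        up = np.concatenate([up, pad], axis=2)
    return up[:, :, :target_len]


def _upsample_bwd(grad, source_len):
    c, n, length = grad.shape
    if length % 2 == 1:
        grad = np.concatenate([grad, np.zeros((c, n, 1), dtype=grad.dtype)], axis=2)
    g = grad.reshape(c, n, -1, 2).sum(axis=3)
    if g.shape[2] > source_len:  # fold edge-padding grads back onto the last frame
        extra = g[:, :, source_len:].sum(axis=2)
        g = g[:, :, :source_len].copy()
        g[:, :, -1] += extra
    return g


class UNet1d:
    """Encoder-decoder over the time axis with skip connections.

    ``depth`` counts encoder levels including the bottleneck; depth 3 means
    two poolings. Input (N, C_in, L) -> one scalar per sample via global
    average pooling and a linear head.
    """

    def __init__(self, in_channels: int, depth: int = 3, base_channels: int = 16,
                 input_length: int | None = None, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if input_length is not None and input_length < 2 ** (depth - 1):
            raise ValueError(
                f"input length {input_length} too short for depth {depth} "
                f"(needs >= {2 ** (depth - 1)})"
            )
        rng = np.random.default_rng(seed)
        self.depth = depth
        chans = [base_channels * 2 ** i for i in range(depth)]
        self.enc = []
        c = in_channels
        for i in range(depth):
            self.enc.append(Conv1d(c, chans[i], rng))
            c = chans[i]
        self.dec = []
        for i in range(depth - 2, -1, -1):
            self.dec.append(Conv1d(chans[i + 1] + chans[i], chans[i], rng))
        self.head_w = (rng.standard_normal(chans[0]) / np.sqrt(chans[0])).astype(_F)
        self.head_b = np.zeros(1, dtype=_F)

    # ---- parameter access -------------------------------------------------
    def parameters(self):
        out = []
        for conv in self.enc + self.dec:
            out.extend([conv.w, conv.b])
        out.extend([self.head_w, self.head_b])
        return out

    def gradients(self):
        out = []
        for conv in self.enc + self.dec:
            out.extend([conv.dw, conv.db])
        out.extend([self.dhead_w, self.dhead_b])
        return out

    def set_parameters(self, values):
        for p, v in zip(self.parameters(), values):
            p[...] = v

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # ---- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_F)
        if x.ndim != 3:
            raise ValueError("input must be (N, C, L)")
        if x.shape[2] < 2 ** (self.depth - 1):
            raise ValueError("input length too short for configured depth")
        h = np.ascontiguousarray(x.transpose(1, 0, 2))  # (C, N, L)
        self._skips, self._enc_masks, self._pool_lens = [], [], []
        for i, conv in enumerate(self.enc):
            h, mask = _relu_fwd(conv.forward(h))
            self._enc_masks.append(mask)
            if i < self.depth - 1:
                self._skips.append(h)
                h, orig = _pool2_fwd(h)
                self._pool_lens.append(orig)
        self._dec_masks, self._up_src_lens, self._cat_splits = [], [], []
        for conv, skip in zip(self.dec, reversed(self._skips)):
            self._up_src_lens.append(h.shape[2])
            up = _upsample_fwd(h, skip.shape[2])
            self._cat_splits.append(up.shape[0])
            h, mask = _relu_fwd(conv.forward(np.concatenate([up, skip], axis=0)))
            self._dec_masks.append(mask)
        self._gap_in_len = h.shape[2]
        feat = h.mean(axis=2)  # (C, N)
        self._feat = feat
        return self.head_w @ feat + self.head_b[0]

    def backward(self, grad_out: np.ndarray) -> None:
        """Accumulate gradients for a scalar-per-sample output; call after forward."""
        grad_out = grad_out.astype(_F)
        self.dhead_w = self._feat @ grad_out
        self.dhead_b = np.array([grad_out.sum()], dtype=_F)
        dfeat = self.head_w[:, None] * grad_out[None, :]  # (C, N)
        dh = np.repeat(dfeat[:, :, None], self._gap_in_len, axis=2) / _F(self._gap_in_len)

        dskips = [None] * len(self._skips)
        for j in range(len(self.dec) - 1, -1, -1):
            conv = self.dec[j]
            dh = dh * self._dec_masks[j]
            dcat = conv.backward(dh)
            split = self._cat_splits[j]
            dup, dskip = dcat[:split], dcat[split:]
            skip_idx = len(self._skips) - 1 - j
            dskips[skip_idx] = dskip
            dh = _upsample_bwd(dup, self._up_src_lens[j])

        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                dh = _pool2_bwd(dh, self._pool_lens[i])
                dh = dh + dskips[i]
            dh = dh * self._enc_masks[i]
            dh = self.enc[i].backward(dh)


class Adam:
    """Standard Adam; operates in place on a model's parameter arrays."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
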