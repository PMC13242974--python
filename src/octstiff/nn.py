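"""Minimal NumPy convolutional network engine used by the segmentation module.

Implements exactly the pieces a 2-D U-Net needs — 3x3/1x1 convolutions via
im2col, ReLU, 2x2 max pooling, 2x nearest-neighbour upsampling, channel
concatenation, a sigmoid head with BCE / soft-Dice losses, and Adam — with
hand-written backward passes. All layers are deterministic given the RNG used
for initialisation; gradients are validated against finite differences in the
test suite.

Array convention: activations are ``(batch, channels, height, width)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "UNet", "Adam", "bce_dice_loss"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patches with 'same' zero padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, H, W, C, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    """Adjoint of _im2col: scatter (B*H*W, C*k*k) back to (B, C, H, W)."""
    b, c, h, w = shape
    p = k // 2
    d = dcols.reshape(b, h, w, c, k, k)
    dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, p : p + h, p : p + w]


class Conv2d:
    """k x k convolution, stride 1, 'same' zero padding, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = in_ch * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        bsz, _, h, w = x.shape
        cols = _im2col(x, self.k)
        self._cols, self._xshape = cols, x.shape
        out = cols @ self.w.T + self.b
        return out.reshape(bsz, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        bsz, _, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.dw = dflat.T @ self._cols
        self.db = dflat.sum(axis=0)
        dcols = dflat @ self.w
        return _col2im(dcols, self._xshape, self.k)

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _maxpool_forward(x):
    b, c, h, w = x.shape
    xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(b, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dout, idx, in_shape):
    b, c, h, w = in_shape
    d = np.zeros((b, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(d, idx[..., None], dout[..., None], axis=-1)
    d = d.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return d.reshape(b, c, h, w)


def _upsample_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample_backward(dout):
    b, c, h, w = dout.shape
    return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """Symmetric encoder-decoder with skip concatenations and a 1-channel head.

    ``depth`` encoder levels of (conv-ReLU-conv-ReLU, 2x2 maxpool), channels
    doubling from ``base_channels``; a two-conv bottleneck; a mirrored decoder
    (2x nearest upsample, 3x3 up-conv, skip concat, conv-ReLU-conv-ReLU);
    final 1x1 convolution producing one logit map congruent with the input.
    """

    def __init__(self, depth: int = 4, base_channels: int = 16, seed: int = 0,
                 dtype=np.float32):
        if depth < 1 or base_channels < 1:
            raise ValueError("depth and base_channels must be positive")
        self.depth = depth
        self.base_channels = base_channels
        self.dtype = dtype
        rng = np.random.default_rng(seed)

        self.enc: list[tuple[Conv2d, Conv2d]] = []
        ch = 1
        for lvl in range(depth):
            out = base_channels * (2 ** lvl)
            self.enc.append((Conv2d(ch, out, 3, rng, dtype),
                             Conv2d(out, out, 3, rng, dtype)))
            ch = out
        bott = base_channels * (2 ** depth)
        self.bottleneck = (Conv2d(ch, bott, 3, rng, dtype),
                           Conv2d(bott, bott, 3, rng, dtype))
        self.dec: list[tuple[Conv2d, Conv2d, Conv2d]] = []
        ch = bott
        for lvl in reversed(range(depth)):
            out = base_channels * (2 ** lvl)
            # up-conv after upsample, then two convs on the concatenated map
            self.dec.append((Conv2d(ch, out, 3, rng, dtype),
                             Conv2d(2 * out, out, 3, rng, dtype),
                             Conv2d(out, out, 3, rng, dtype)))
            ch = out
        self.head = Conv2d(ch, 1, 1, rng, dtype)
        self._cache: list | None = None

    # -- plumbing -----------------------------------------------------------
    def layers(self):
        for a, b in self.enc:
            yield a
            yield b
        yield self.bottleneck[0]
        yield self.bottleneck[1]
        for a, b, c in self.dec:
            yield a
            yield b
            yield c
        yield self.head

    def n_parameters(self) -> int:
        return sum(l.w.size + l.b.size for l in self.layers())

    def check_input(self, hw: tuple) -> None:
        div = 2 ** self.depth
        if hw[0] % div or hw[1] % div:
            raise ValueError(
                f"input size {hw} not divisible by 2^depth = {div}")

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Input (B, 1, H, W) -> logits (B, 1, H, W); caches for backward."""
        self.check_input(x.shape[2:])
        x = x.astype(self.dtype, copy=False)
        cache = []
        skips = []
        for c1, c2 in self.enc:
            a, m1 = _relu_forward(c1.forward(x))
            s, m2 = _relu_forward(c2.forward(a))
            skips.append(s)
            x, idx = _maxpool_forward(s)
            cache.append((m1, m2, idx, s.shape))
        a, mb1 = _relu_forward(self.bottleneck[0].forward(x))
        x, mb2 = _relu_forward(self.bottleneck[1].forward(a))
        dec_cache = []
        for (cu, c1, c2), skip in zip(self.dec, reversed(skips)):
            up = _upsample_forward(x)
            u, mu = _relu_forward(cu.forward(up))
            cat = np.concatenate([skip, u], axis=1)
            a, m1 = _relu_forward(c1.forward(cat))
            x, m2 = _relu_forward(c2.forward(a))
            dec_cache.append((mu, m1, m2, skip.shape[1]))
        logits = self.head.forward(x)
        self._cache = (cache, (mb1, mb2), dec_cache)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        enc_cache, (mb1, mb2), dec_cache = self._cache
        dx = self.head.backward(dlogits.astype(self.dtype, copy=False))
        dskips = []
        for (cu, c1, c2), (mu, m1, m2, n_skip) in zip(reversed(self.dec),
                                                      reversed(dec_cache)):
            dx = c1.backward(c2.backward(dx * m2) * m1)
            dskip, du = dx[:, :n_skip], dx[:, n_skip:]
            dskips.append(dskip)
            dx = _upsample_backward(cu.backward(du * mu))
        dx = self.bottleneck[0].backward(self.bottleneck[1].backward(dx * mb2) * mb1)
        for (c1, c2), (m1, m2, idx, sshape), dskip in zip(
                reversed(self.enc), reversed(enc_cache), reversed(dskips)):
            ds = _maxpool_backward(dx, idx, sshape) + dskip
            dx = c1.backward(c2.backward(ds * m2) * m1)

    # -- inference ----------------------------------------------------------
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities, no caching side effects kept."""
        from scipy.special import expit

        logits = self.forward(x)
        self._cache = None
        return expit(logits)

    # -- (de)serialisation --------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        out = []
        for l in self.layers():
            out.append(l.w.copy())
            out.append(l.b.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for l in self.layers():
            l.w = next(it).astype(self.dtype).reshape(l.w.shape)
            l.b = next(it).astype(self.dtype).reshape(l.b.shape)


def bce_dice_loss(logits: np.ndarray, target: np.ndarray, mode: str = "bce+dice",
                  eps: float = 1e-7):
    """Binary cross-entropy and/or soft-Dice loss on logits.

    Returns ``(loss, dlogits)``. BCE is computed in a numerically stable form
    from logits; the soft Dice term is 1 - 2*sum(p*y)/(sum(p)+sum(y)+eps).
    """
    z = logits.astype(np.float64)
    y = target.astype(np.float64)
    n = z.size
    p = 1.0 / (1.0 + np.exp(-z))
    loss = 0.0
    dp = np.zeros_like(p)
    dz = np.zeros_like(z)
    if mode in ("bce", "bce+dice"):
        # log(1+e^z) - y*z, stable via logaddexp
        loss += float(np.mean(np.logaddexp(0.0, z) - y * z))
        dz += (p - y) / n
    if mode in ("dice", "bce+dice"):
        inter = float((p * y).sum())
        denom = float(p.sum() + y.sum()) + eps
        loss += 1.0 - 2.0 * inter / denom
        dp = -2.0 * (y * denom - inter) / denom ** 2
        dz += dp * p * (1.0 - p)
    if mode not in ("bce", "dice", "bce+dice"):
        raise ValueError(f"unknown loss mode {mode!r}")
    return loss, dz.astype(logits.dtype)


class Adam:
    """Adam optimiser over a model's (param, grad) pairs."""

    def __init__(self, model: UNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = [(np.zeros_like(p), np.zeros_like(p))
                      for layer in model.layers() for p, _ in layer.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        pairs = [pg for layer in self.model.layers() for pg in layer.params]
        for (p, g), (m, v) in zip(pairs, self.state):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
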