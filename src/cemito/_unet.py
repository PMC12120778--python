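"""A NumPy 2D symmetric U-Net with explicit forward/backward passes.

Architecture: an encoder of ``depth`` levels (feature widths doubling per
level), three 3x3 non-strided same convolutions per step, each followed by
instance normalization and ReLU; 2x2 max pooling between encoder levels;
decoder steps of nearest-neighbor x2 upsampling followed by a 2x2
non-strided convolution, concatenation with the same-level encoder output,
and another conv step; a final 3x3 same convolution with logistic
squashing produces a per-pixel foreground probability.

Implementation notes: convolutions are evaluated as one GEMM per kernel
offset (tensordot over channels), float32 throughout, single image per
step (instance normalization makes batching unnecessary). Gradients are
accumulated on each layer's ``grads`` and consumed by the Adam trainer.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded convolution; kernel 3 pads (1,1), kernel 2 pads (0,1)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        if k == 3:
            self.pad = (1, 1)
        elif k == 2:
            self.pad = (0, 1)
        else:
            raise ValueError("kernel must be 2 or 3")

    def forward(self, x: np.ndarray) -> np.ndarray:
        p0, p1 = self.pad
        xp = np.pad(x, ((0, 0), (p0, p1), (p0, p1)))
        self._xp = xp
        _, H, W = x.shape
        cout = self.W.shape[0]
        y = np.empty((cout, H, W), dtype=np.float32)
        y[:] = self.b[:, None, None]
        for ki in range(self.k):
            for kj in range(self.k):
                y += np.tensordot(self.W[:, :, ki, kj],
                                  xp[:, ki:ki + H, kj:kj + W], axes=([1], [0]))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        _, H, W = dy.shape
        dxp = np.zeros_like(xp)
        dW, db = self.grads
        db += dy.sum(axis=(1, 2))
        for ki in range(self.k):
            for kj in range(self.k):
                patch = xp[:, ki:ki + H, kj:kj + W]
                dW[:, :, ki, kj] += np.tensordot(dy, patch, axes=([1, 2], [1, 2]))
                dxp[:, ki:ki + H, kj:kj + W] += np.tensordot(
                    self.W[:, :, ki, kj], dy, axes=([0], [0]))
        p0, p1 = self.pad
        Hx = xp.shape[1] - p0 - p1
        Wx = xp.shape[2] - p0 - p1
        return dxp[:, p0:p0 + Hx, p0:p0 + Wx]


class InstanceNorm(Layer):
    """Per-channel normalization over the spatial extent, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.g = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.params = [self.g, self.beta]
        self.grads = [np.zeros_like(self.g), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._xhat, self._ivar = xhat, ivar
        return (self.g[:, None, None] * xhat + self.beta[:, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._xhat, self._ivar
        N = dy.shape[1] * dy.shape[2]
        dg, dbeta = self.grads
        dg += (dy * xhat).sum(axis=(1, 2))
        dbeta += dy.sum(axis=(1, 2))
        dxhat = dy * self.g[:, None, None]
        term = (dxhat - dxhat.mean(axis=(1, 2), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(1, 2), keepdims=True))
        return (term * ivar).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        C, H, W = x.shape
        xr = x.reshape(C, H // 2, 2, W // 2, 2).transpose(0, 1, 3, 2, 4)
        xr = xr.reshape(C, H // 2, W // 2, 4)
        self._arg = np.argmax(xr, axis=3)
        self._shape = (C, H, W)
        return np.take_along_axis(xr, self._arg[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, H, W = self._shape
        dr = np.zeros((C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dr, self._arg[..., None], dy[..., None], axis=3)
        dr = dr.reshape(C, H // 2, W // 2, 2, 2).transpose(0, 1, 3, 2, 4)
        return dr.reshape(C, H, W)


class UpsampleNN2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, H, W = dy.shape
        return dy.reshape(C, H // 2, 2, W // 2, 2).sum(axis=(2, 4)).astype(np.float32)


class ConvStep:
    """convs_per_step x (conv 3x3 -> instance norm -> ReLU)."""

    def __init__(self, cin: int, cout: int, n_convs: int, rng: np.random.Generator):
        self.layers: list[Layer] = []
        c = cin
        for _ in range(n_convs):
            self.layers += [Conv2d(c, cout, 3, rng), InstanceNorm(cout), ReLU()]
            c = cout

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNet:
    """Symmetric U-Net over single-channel 2D images."""

    def __init__(self, depth: int, features: tuple[int, ...], convs_per_step: int,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.features = features
        self.down_steps = []
        cin = 1
        for lvl in range(depth):
            self.down_steps.append(ConvStep(cin, features[lvl], convs_per_step, rng))
            cin = features[lvl]
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.up_samplers, self.up_convs, self.up_steps = [], [], []
        for lvl in range(depth - 2, -1, -1):
            self.up_samplers.append(UpsampleNN2())
            self.up_convs.append(Conv2d(features[lvl + 1], features[lvl], 2, rng))
            self.up_steps.append(
                ConvStep(2 * features[lvl], features[lvl], convs_per_step, rng))
        self.head = Conv2d(features[0], 1, 3, rng)

    # -- parameter plumbing -------------------------------------------------
    def _all_layers(self) -> list[Layer]:
        layers: list[Layer] = []
        for step in self.down_steps:
            layers += step.layers
        layers += self.up_convs
        for step in self.up_steps:
            layers += step.layers
        layers.append(self.head)
        return layers

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._all_layers() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._all_layers() for g in layer.grads]

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- passes --------------------------------------------------------------
    def _pad_to_grid(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        m = 2 ** (self.depth - 1)
        H, W = x.shape[-2:]
        ph = (-H) % m
        pw = (-W) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        return x, (H, W)

    def forward_logits(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        x, (H, W) = self._pad_to_grid(x)
        self._crop = (H, W)
        self._pad_shape = x.shape[-2:]
        skips = []
        for lvl in range(self.depth - 1):
            x = self.down_steps[lvl].forward(x)
            skips.append(x)
            x = self.pools[lvl].forward(x)
        x = self.down_steps[-1].forward(x)
        self._skip_channels = []
        for k, lvl in enumerate(range(self.depth - 2, -1, -1)):
            x = self.up_samplers[k].forward(x)
            x = self.up_convs[k].forward(x)
            skip = skips[lvl]
            x = np.concatenate([skip, x], axis=0)
            self._skip_channels.append(skip.shape[0])
            x = self.up_steps[k].forward(x)
        logits = self.head.forward(x)[0]
        return logits[:H, :W]

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Probability map in [0, 1], same spatial shape as the input."""
        z = self.forward_logits(image)
        return 1.0 / (1.0 + np.exp(-z.astype(np.float64)))

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient on the (cropped) logits into all params.

        The encoder output at each level feeds both the skip concatenation
        and the pooled deeper path, so its gradient is the sum of the two;
        the decoder is walked first to collect the skip gradients.
        """
        Hp, Wp = self._pad_shape
        H, W = self._crop
        dz = np.zeros((1, Hp, Wp), dtype=np.float32)
        dz[0, :H, :W] = dlogits
        dx = self.head.backward(dz)
        dskips: dict[int, np.ndarray] = {}
        for k in range(len(self.up_steps) - 1, -1, -1):
            dx = self.up_steps[k].backward(dx)
            nskip = self._skip_channels[k]
            lvl = self.depth - 2 - k
            dskips[lvl] = dx[:nskip]
            dup = self.up_convs[k].backward(dx[nskip:])
            dx = self.up_samplers[k].backward(dup)
        dx = self.down_steps[-1].backward(dx)
        for lvl in range(self.depth - 2, -1, -1):
            dx = self.pools[lvl].backward(dx)
            dx = self.down_steps[lvl].backward(dx + dskips[lvl])
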