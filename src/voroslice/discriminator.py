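"""Fully convolutional patch discriminator.

The realism critic is the truncated feature stack of a VGG19 network: the
first 11 modules (conv3x3/LeakyReLU pairs with 2x2 max-pooling after each of
the first two blocks, ending at the first block-3 convolution), followed by a
1x1 scoring convolution to one channel and a sigmoid.  Counting receptive
fields through the stack gives a 24x24-pixel field of view, so every entry of
the output map scores one local 24x24 patch of the input section.

Modifications to plain VGG19: LeakyReLU (slope 0.2) instead of ReLU, spectral
normalization on every convolution (Lipschitz control for stable adversarial
gradients), and no zero padding — generated sections are periodic and get
cyclic padding, measured sections get no padding at all.

Implemented directly on NumPy arrays in NCHW layout with explicit backward
passes, so gradients reach both the convolution weights (discriminator
training) and the input image (seed-point optimization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "DiscriminatorConfig",
    "Discriminator",
    "build_discriminator",
    "score",
    "receptive_field",
]


# ---------------------------------------------------------------------------
# layers


class _Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray, need_param_grad: bool) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []


class Conv2d(_Layer):
    """k x k valid convolution, optional cyclic padding and spectral norm.

    The raw weight is stored unnormalized; the effective weight used in the
    forward pass is ``W / sigma`` where ``sigma`` is the largest singular
    value of the (out_channels, in_channels*k*k) weight matrix, estimated by
    one power-iteration step per training forward pass (u, v persist across
    calls).  In evaluation mode u and v are frozen, keeping the forward
    deterministic.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        spectral_norm: bool = True,
        dtype=np.float32,
    ):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.W = (rng.normal(size=(c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)).astype(
            dtype
        )
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.spectral_norm = spectral_norm
        if spectral_norm:
            u = rng.normal(size=c_out)
            self.u = (u / np.linalg.norm(u)).astype(dtype)
            v = rng.normal(size=fan_in)
            self.v = (v / np.linalg.norm(v)).astype(dtype)
            for _ in range(10):  # warm-start u, v so sigma is accurate at init
                self._sigma(train=True)
        self.padding = "none"
        self._cache = None

    # -- spectral normalization ------------------------------------------------
    def _sigma(self, train: bool) -> float:
        M = self.W.reshape(self.c_out, -1)
        if self.spectral_norm and train:
            v = M.T @ self.u
            self.v = v / (np.linalg.norm(v) + 1e-12)
            u = M @ self.v
            self.u = u / (np.linalg.norm(u) + 1e-12)
        if not self.spectral_norm:
            return 1.0
        return float(self.u @ M @ self.v)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.k
        pad = k // 2 if (self.padding == "periodic" and k > 1) else 0
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="wrap")
        N, C, H, W = x.shape
        if H < k or W < k:
            raise ValueError(
                f"input {H}x{W} smaller than kernel {k}x{k} with no padding"
            )
        sigma = self._sigma(train)
        Wbar = (self.W / sigma).reshape(self.c_out, -1).T  # (C*k*k, c_out)
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,H',W',k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            -1, C * k * k
        )
        Hp, Wp = H - k + 1, W - k + 1
        y = cols @ Wbar + self.b
        self._cache = (cols, (N, C, H, W), Wbar, sigma, pad)
        return y.reshape(N, Hp, Wp, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray, need_param_grad: bool) -> np.ndarray:
        cols, (N, C, H, W), Wbar, sigma, pad = self._cache
        k = self.k
        Hp, Wp = H - k + 1, W - k + 1
        dmat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        if need_param_grad:
            dWbar = (cols.T @ dmat).T.reshape(self.W.shape)  # grad wrt W/sigma
            if self.spectral_norm:
                Mbar = self.W.reshape(self.c_out, -1) / sigma
                dWm = dWbar.reshape(self.c_out, -1)
                coef = float(np.sum(dWm * Mbar))
                dWm = (dWm - coef * np.outer(self.u, self.v)) / sigma
                self.dW += dWm.reshape(self.W.shape)
            else:
                self.dW += dWbar
            self.db += dmat.sum(axis=0)
        dcols = dmat @ Wbar.T
        dcols = dcols.reshape(N, Hp, Wp, C, k, k)
        dx = np.zeros((N, C, H, W), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + Hp, j : j + Wp] += dcols[..., i, j].transpose(
                    0, 3, 1, 2
                )
        if pad:
            # fold cyclic-pad contributions back into the interior
            dx[:, :, :, pad : 2 * pad] += dx[:, :, :, -pad:]
            dx[:, :, :, -2 * pad : -pad] += dx[:, :, :, :pad]
            dx = dx[:, :, :, pad:-pad]
            dx[:, :, pad : 2 * pad, :] += dx[:, :, -pad:, :]
            dx[:, :, -2 * pad : -pad, :] += dx[:, :, :pad, :]
            dx = dx[:, :, pad:-pad, :]
        return dx

    def params(self) -> list[dict]:
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]

    def effective_weight(self) -> np.ndarray:
        """Spectrally normalized weight actually used in the forward pass."""
        return self.W / self._sigma(train=False)


class LeakyReLU(_Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha
        self._mask = None

    def forward(self, x, train):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy, need_param_grad):
        return np.where(self._mask, dy, self.alpha * dy)


class MaxPool2d(_Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train):
        N, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :, : 2 * H2, : 2 * W2]
        x4 = xc.reshape(N, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, H2, W2, 4
        )
        idx = np.argmax(x4, axis=-1)
        y = np.take_along_axis(x4, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (N, C, H, W))
        return y

    def backward(self, dy, need_param_grad):
        idx, (N, C, H, W) = self._cache
        H2, W2 = H // 2, W // 2
        d4 = np.zeros((N, C, H2, W2, 4), dtype=dy.dtype)
        np.put_along_axis(d4, idx[..., None], dy[..., None], axis=-1)
        dxc = d4.reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, 2 * H2, 2 * W2
        )
        if 2 * H2 == H and 2 * W2 == W:
            return dxc
        dx = np.zeros((N, C, H, W), dtype=dy.dtype)
        dx[:, :, : 2 * H2, : 2 * W2] = dxc
        return dx


class Sigmoid(_Layer):
    def __init__(self):
        self._y = None

    def forward(self, x, train):
        # numerically safe logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._y = out
        return out

    def backward(self, dy, need_param_grad):
        return dy * self._y * (1.0 - self._y)


# ---------------------------------------------------------------------------
# network


@dataclass
class DiscriminatorConfig:
    """Architecture of the truncated-VGG patch discriminator.

    ``blocks`` lists the convolution widths per block; a 2x2 max-pool follows
    every block except the last.  The default reproduces the first 11 VGG19
    feature modules; with the 1x1 scoring head this yields a 24x24 receptive
    field.
    """

    blocks: tuple = ((64, 64), (128, 128), (256,))
    alpha: float = 0.2
    spectral_norm: bool = True
    in_channels: int = 3
    dtype: object = np.float32

    def layer_spec(self) -> list[tuple]:
        """Layer sequence as (kind, *args) tuples, scoring head included."""
        spec: list[tuple] = []
        c = self.in_channels
        for bi, widths in enumerate(self.blocks):
            for w in widths:
                spec.append(("conv", c, w, 3))
                spec.append(("lrelu",))
                c = w
            if bi < len(self.blocks) - 1:
                spec.append(("pool",))
        spec.pop()  # the truncation ends at the last conv, no activation
        spec.append(("conv", c, 1, 1))  # scoring head
        spec.append(("sigmoid",))
        return spec


def receptive_field(config: DiscriminatorConfig | None = None) -> int:
    """Field of view (pixels per side) of one output score, by layer arithmetic."""
    config = config or DiscriminatorConfig()
    r, j = 1, 1
    for layer in config.layer_spec():
        if layer[0] == "conv":
            r += (layer[3] - 1) * j
        elif layer[0] == "pool":
            r += j
            j *= 2
    return r


class Discriminator:
    """Patch discriminator: RGB section in, [0,1] patch-score map out."""

    def __init__(self, config: DiscriminatorConfig, rng_seed: int = 0):
        self.config = config
        rng = np.random.default_rng(rng_seed)
        self.layers: list[_Layer] = []
        for spec in config.layer_spec():
            kind = spec[0]
            if kind == "conv":
                _, c_in, c_out, k = spec
                self.layers.append(
                    Conv2d(
                        c_in,
                        c_out,
                        k,
                        rng,
                        spectral_norm=config.spectral_norm,
                        dtype=config.dtype,
                    )
                )
            elif kind == "lrelu":
                self.layers.append(LeakyReLU(config.alpha))
            elif kind == "pool":
                self.layers.append(MaxPool2d())
            elif kind == "sigmoid":
                self.layers.append(Sigmoid())

    @property
    def receptive_field(self) -> int:
        return receptive_field(self.config)

    def forward(
        self, x: np.ndarray, padding: str = "none", train: bool = False
    ) -> np.ndarray:
        """Score a batch ``(N, 3, H, W)`` -> ``(N, 1, h', w')``.

        ``padding="periodic"`` wraps every convolution cyclically (use for
        sections of periodic tessellations; output is h/4 x w/4);
        ``padding="none"`` uses valid convolutions only (measured, aperiodic
        sections; requires h, w >= receptive field).
        """
        if padding not in ("none", "periodic"):
            raise ValueError(f"unknown padding mode {padding!r}")
        if padding == "none" and min(x.shape[2], x.shape[3]) < self.receptive_field:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} smaller than the "
                f"{self.receptive_field}x{self.receptive_field} field of view"
            )
        h = np.asarray(x, dtype=self.config.dtype)
        for layer in self.layers:
            if isinstance(layer, Conv2d):
                layer.padding = padding
            h = layer.forward(h, train)
        return h

    def backward(self, dscore: np.ndarray, need_param_grad: bool = True) -> np.ndarray:
        """Backpropagate ``dL/d(score map)``; returns ``dL/d(input image)``.

        Parameter gradients accumulate into each convolution's ``dW``/``db``
        when requested.
        """
        d = np.asarray(dscore, dtype=self.config.dtype)
        for layer in reversed(self.layers):
            d = layer.backward(d, need_param_grad)
        return d

    def zero_grad(self) -> None:
        for layer in self.layers:
            for p in layer.params():
                p["grad"][...] = 0.0

    def parameters(self) -> list[dict]:
        return [p for layer in self.layers for p in layer.params()]

    def architecture(self) -> dict:
        """JSON-serializable architecture description (audit sidecar)."""
        return {
            "blocks": [list(b) for b in self.config.blocks],
            "alpha": self.config.alpha,
            "spectral_norm": self.config.spectral_norm,
            "receptive_field": self.receptive_field,
            "layers": [
                {
                    "kind": type(l).__name__,
                    **(
                        {"in": l.c_in, "out": l.c_out, "k": l.k}
                        if isinstance(l, Conv2d)
                        else {}
                    ),
                }
                for l in self.layers
            ],
        }

    def save(self, path) -> None:
        """Checkpoint weights (and spectral-norm state) as an .npz file."""
        arrays = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Conv2d):
                arrays[f"W{i}"] = layer.W
                arrays[f"b{i}"] = layer.b
                if layer.spectral_norm:
                    arrays[f"u{i}"] = layer.u
                    arrays[f"v{i}"] = layer.v
        np.savez(path, **arrays)

    def load(self, path) -> None:
        data = np.load(path)
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Conv2d):
                layer.W = data[f"W{i}"].astype(self.config.dtype)
                layer.b = data[f"b{i}"].astype(self.config.dtype)
                layer.dW = np.zeros_like(layer.W)
                layer.db = np.zeros_like(layer.b)
                if layer.spectral_norm:
                    layer.u = data[f"u{i}"].astype(self.config.dtype)
                    layer.v = data[f"v{i}"].astype(self.config.dtype)


def build_discriminator(
    config: DiscriminatorConfig | None = None, rng_seed: int = 0
) -> Discriminator:
    """Construct a randomly initialized (reproducible) patch discriminator."""
    return Discriminator(config or DiscriminatorConfig(), rng_seed)


def score(
    discriminator: Discriminator, image: np.ndarray, padding: str = "none"
) -> np.ndarray:
    """Patch-score map of a single ``(H, W, 3)`` RGB section, values in (0, 1)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got {img.shape}")
    x = img.transpose(2, 0, 1)[None]
    out = discriminator.forward(x, padding=padding, train=False)
    return out[0, 0]
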